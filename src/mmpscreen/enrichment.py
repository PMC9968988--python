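"""Enrichment statistics: exact hypergeometric tests with BH FDR control.

The question throughout is over-representation: is a target annotated among
the hit compounds more often than drawing the same number of compounds at
random from the assayed universe would explain?  The exact one-sided
(enrichment-direction) hypergeometric tail is used rather than a two-sided
Fisher test, and Benjamini–Hochberg q-values are computed separately within
each hypothesis family (targets; categories).

``category_overrepresentation`` is the same machinery applied to a
user-supplied target -> category map (a protein-class or pathway
annotation), standing in for database-backed GO/KEGG lookups whose results
depend on database version.

``frequency_comparison`` contrasts per-target frequencies among hits and
non-hits with a Spearman rank correlation plus standardized residuals from
the rank-regression line; targets with large positive residuals are
unusually frequent among hits relative to their non-hit frequency, which is
robust to the heavy-tailed frequency distribution of promiscuous targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import StatisticError, ValidationError
from .screen_io import TargetAnnotationTable, TargetRankingTable

__all__ = [
    "hypergeom_tail",
    "bh_adjust",
    "target_enrichment",
    "rank_targets",
    "category_overrepresentation",
    "frequency_comparison",
    "FrequencyComparison",
]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    N compounds in the universe, K annotated, n drawn (the hits), k of the
    draws annotated.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    # sf(k-1) = P[X >= k]; scipy evaluates the tail in log space internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def _enrichment_frame(
    counts: pd.DataFrame, n: int, N: int, id_col: str
) -> pd.DataFrame:
    """Attach one-sided hypergeometric p and BH q to a (id, k, K) frame."""
    out = counts.copy()
    out["n"] = n
    out["N"] = N
    out["p"] = [hypergeom_tail(k, K, n, N) for k, K in zip(out["k"], out["K"])]
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    out = out.sort_values(["p", id_col], kind="mergesort").reset_index(drop=True)
    return out


def target_enrichment(
    annotations: TargetAnnotationTable,
    hits: Iterable[str],
    nonhits: Iterable[str],
) -> pd.DataFrame:
    """Per-target over-representation among hits vs the assayed universe.

    ``annotations`` should already be potency-filtered.  The universe is
    hits ∪ nonhits (the assayed compounds); per target, K counts annotated
    universe compounds and k annotated hits.  Returns a frame
    (target_id, k, K, n, N, p, q) sorted by p then target id.
    """
    hits = {str(c) for c in hits}
    nonhits = {str(c) for c in nonhits}
    if hits & nonhits:
        raise ValidationError(f"hits and nonhits overlap: {sorted(hits & nonhits)[:5]}")
    if not hits:
        raise StatisticError("empty hit set: enrichment is undefined")
    universe = hits | nonhits
    df = annotations.df
    sub = df[df["compound_id"].isin(universe)]
    K = sub.groupby("target_id")["compound_id"].nunique()
    k = (
        sub[sub["compound_id"].isin(hits)]
        .groupby("target_id")["compound_id"]
        .nunique()
        .reindex(K.index, fill_value=0)
    )
    counts = pd.DataFrame({"target_id": K.index, "k": k.to_numpy(), "K": K.to_numpy()})
    return _enrichment_frame(counts, n=len(hits), N=len(universe), id_col="target_id")


def rank_targets(
    filtered: TargetAnnotationTable,
    hits: Iterable[str],
    nonhits: Iterable[str] | None = None,
    min_frequency: int = 1,
) -> TargetRankingTable:
    """Merge frequency, potency, primary counts and enrichment into one ranking.

    Sorted by hit frequency descending, then q ascending (NaN last), then
    target id — the deconvolution cascade's headline ordering.  When
    ``nonhits`` is None the enrichment columns are absent.
    """
    from .deconvolution import (  # local import to avoid a module cycle
        mean_potency,
        primary_target_counts,
        target_frequency,
    )

    hits = {str(c) for c in hits}
    freq = target_frequency(filtered, hits, min_frequency=min_frequency)
    prim = primary_target_counts(filtered, hits).set_index("target_id")["primary_count"]
    rows = []
    if nonhits is not None and hits:
        enr = target_enrichment(filtered, hits, set(nonhits)).set_index("target_id")
    else:
        enr = None
    for tgt, hf in zip(freq["target_id"], freq["hit_frequency"]):
        mp = mean_potency(filtered, tgt, hits)
        if enr is not None and tgt in enr.index:
            nonhit_freq = int(enr.loc[tgt, "K"] - enr.loc[tgt, "k"])
            p, q = float(enr.loc[tgt, "p"]), float(enr.loc[tgt, "q"])
        else:
            nonhit_freq, p, q = 0, np.nan, np.nan
        rows.append(
            {
                "target_id": tgt,
                "hit_frequency": int(hf),
                "mean_pic50": np.nan if mp is None else mp,
                "primary_count": int(prim.get(tgt, 0)),
                "nonhit_frequency": nonhit_freq,
                "p_enrich": p,
                "q_enrich": q,
            }
        )
    df = pd.DataFrame(rows, columns=list(TargetRankingTable.columns))
    if len(df):
        df = df.sort_values(
            ["hit_frequency", "q_enrich", "target_id"],
            ascending=[False, True, True],
            na_position="last",
            kind="mergesort",
        ).reset_index(drop=True)
    return TargetRankingTable(df)


def _as_category_frame(category_map) -> pd.DataFrame:
    if isinstance(category_map, pd.DataFrame):
        return category_map[["target_id", "category_id"]]
    rows = []
    for tgt, cats in dict(category_map).items():
        if isinstance(cats, str):
            cats = [cats]
        for c in cats:
            rows.append({"target_id": str(tgt), "category_id": str(c)})
    return pd.DataFrame(rows, columns=["target_id", "category_id"])


def category_overrepresentation(
    item_set: Iterable[str],
    category_map: Mapping[str, Iterable[str]] | pd.DataFrame,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Category over-representation of ``item_set`` against ``universe``.

    ``category_map`` maps target -> category id(s) (mapping or a frame with
    target_id/category_id columns).  Returns (category_id, k, K, n, N, p, q).
    """
    item_set = {str(t) for t in item_set}
    universe = {str(t) for t in universe}
    if not item_set:
        raise StatisticError("empty item set: overrepresentation is undefined")
    offenders = item_set - universe
    if offenders:
        raise ValidationError(f"items not in universe: {sorted(offenders)}")
    cm = _as_category_frame(category_map)
    cm = cm[cm["target_id"].isin(universe)].drop_duplicates()
    K = cm.groupby("category_id")["target_id"].nunique()
    k = (
        cm[cm["target_id"].isin(item_set)]
        .groupby("category_id")["target_id"]
        .nunique()
        .reindex(K.index, fill_value=0)
    )
    counts = pd.DataFrame({"category_id": K.index, "k": k.to_numpy(), "K": K.to_numpy()})
    return _enrichment_frame(counts, n=len(item_set), N=len(universe), id_col="category_id")


@dataclass(frozen=True)
class FrequencyComparison:
    """Spearman rho plus per-target rank-regression residuals."""

    rho: float
    residuals: pd.DataFrame  # target_id, hit_rank, nonhit_rank, residual, std_residual


def frequency_comparison(
    hit_freq: Mapping[str, int] | pd.Series,
    nonhit_freq: Mapping[str, int] | pd.Series,
) -> FrequencyComparison:
    """Compare per-target frequencies among hits and non-hits.

    Over the union of targets (missing counts taken as 0): Spearman rank
    correlation, plus standardized residuals of hit rank regressed on
    non-hit rank.  Large positive residuals flag targets unusually frequent
    among hits relative to non-hits.
    """
    hit_freq = pd.Series(dict(hit_freq), dtype=float)
    nonhit_freq = pd.Series(dict(nonhit_freq), dtype=float)
    targets = sorted(set(hit_freq.index) | set(nonhit_freq.index))
    if len(targets) < 3:
        raise StatisticError("need at least 3 targets for a rank comparison")
    h = hit_freq.reindex(targets, fill_value=0.0).to_numpy()
    nh = nonhit_freq.reindex(targets, fill_value=0.0).to_numpy()
    hr = stats.rankdata(h)
    nhr = stats.rankdata(nh)
    if np.ptp(hr) == 0 or np.ptp(nhr) == 0:
        # constant ranks: correlation undefined; report 0 association
        rho = 0.0 if not np.array_equal(hr, nhr) else 1.0
    else:
        rho = float(stats.spearmanr(h, nh).statistic)
    # least-squares line through the rank-rank scatter
    if np.ptp(nhr) == 0:
        pred = np.full_like(hr, hr.mean())
    else:
        slope, intercept = np.polyfit(nhr, hr, deg=1)
        pred = intercept + slope * nhr
    resid = hr - pred
    # an (numerically) exact fit means no target deviates from the trend
    tiny = 1e-9 * max(1.0, float(np.max(np.abs(hr))))
    resid[np.abs(resid) < tiny] = 0.0
    scale = float(np.std(resid, ddof=min(2, len(resid) - 1)))
    std_resid = resid / scale if scale > tiny else np.zeros_like(resid)
    out = pd.DataFrame(
        {
            "target_id": targets,
            "hit_rank": hr,
            "nonhit_rank": nhr,
            "residual": resid,
            "std_residual": std_resid,
        }
    ).sort_values(["std_residual", "target_id"], ascending=[False, True], kind="mergesort")
    return FrequencyComparison(rho=rho, residuals=out.reset_index(drop=True))
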