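"""Target deconvolution: the potency-filter / frequency-ranking cascade.

From the annotated targets of the hit compounds, infer which protein most
plausibly drives the phenotype: drop annotations whose pIC50 means the
target cannot have been meaningfully engaged at the 1 µM screening
concentration (pIC50 < 6 implies IC50 > 1 µM, i.e. under half occupancy),
then rank the surviving targets by how many distinct hit compounds are
annotated against them, their average pIC50 (specificity), and how often
they are a compound's declared primary target.  Off-target uniqueness —
targets a compound hits that none of a comparator set does — supports
explaining divergent behaviour of one inhibitor in a chemically related
series.

All rankings break ties deterministically: by the statistic, then by
lexicographic target id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, UnknownCompoundError
from .screen_io import TargetAnnotationTable, normalize_target

__all__ = [
    "DeconvolutionConfig",
    "PotencyFilterReport",
    "filter_by_potency",
    "unique_targets",
    "target_frequency",
    "mean_potency",
    "primary_target_counts",
    "potency_matrix",
    "unique_offtargets",
]


@dataclass(frozen=True)
class DeconvolutionConfig:
    """Cascade parameters: inclusive pIC50 cut and minimum hit frequency."""

    pic50_min: float = 6.0
    min_frequency: int = 6

    def __post_init__(self):
        if not np.isfinite(self.pic50_min):
            raise ConfigError("pic50_min must be finite")
        if self.min_frequency < 1:
            raise ConfigError("min_frequency must be >= 1")


@dataclass(frozen=True)
class PotencyFilterReport:
    n_input: int
    n_retained: int
    n_below_threshold: int
    n_missing_pic50: int


def filter_by_potency(
    annotations: TargetAnnotationTable, pic50_min: float
) -> tuple[TargetAnnotationTable, PotencyFilterReport]:
    """Keep records with pIC50 present and >= pic50_min (inclusive).

    Records lacking a pIC50 cannot pass a potency cut and are dropped; the
    report counts them separately from the below-threshold drops so the run
    log can state both.
    """
    df = annotations.df
    present = df["pic50"].notna()
    keep = present & (df["pic50"] >= pic50_min)
    report = PotencyFilterReport(
        n_input=len(df),
        n_retained=int(keep.sum()),
        n_below_threshold=int((present & ~keep).sum()),
        n_missing_pic50=int((~present).sum()),
    )
    return TargetAnnotationTable(df[keep]), report


def unique_targets(
    annotations: TargetAnnotationTable, compounds: Iterable[str]
) -> set[str]:
    """Union of target ids annotated on the given compounds."""
    compounds = {str(c) for c in compounds}
    df = annotations.df
    return set(df.loc[df["compound_id"].isin(compounds), "target_id"])


def target_frequency(
    filtered: TargetAnnotationTable,
    hits: Iterable[str],
    min_frequency: int = 1,
) -> pd.DataFrame:
    """Distinct-hit-compound count per target, kept at count >= min_frequency.

    Returns a frame (target_id, hit_frequency) sorted by count descending
    then target id ascending.
    """
    hits = {str(c) for c in hits}
    df = filtered.df
    sub = df[df["compound_id"].isin(hits)]
    counts = (
        sub.groupby("target_id")["compound_id"].nunique().rename("hit_frequency")
    )
    counts = counts[counts >= min_frequency]
    out = counts.reset_index()
    out = out.sort_values(
        ["hit_frequency", "target_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def mean_potency(
    annotations: TargetAnnotationTable, target: str, compounds: Iterable[str]
) -> float | None:
    """Arithmetic mean pIC50 of a target's records among the given compounds.

    Absent (None) when the target has no pIC50-bearing record there.
    """
    target = normalize_target(target)
    compounds = {str(c) for c in compounds}
    df = annotations.df
    vals = df.loc[
        (df["target_id"] == target) & df["compound_id"].isin(compounds), "pic50"
    ].dropna()
    if vals.empty:
        return None
    return float(vals.mean())


def primary_target_counts(
    annotations: TargetAnnotationTable, hits: Iterable[str]
) -> pd.DataFrame:
    """Count hit compounds whose primary annotation names each target.

    Compounds without a primary flag contribute nothing.  Frame of
    (target_id, primary_count), sorted count desc then target id.
    """
    hits = {str(c) for c in hits}
    df = annotations.df
    sub = df[df["is_primary"] & df["compound_id"].isin(hits)]
    counts = sub.groupby("target_id")["compound_id"].nunique().rename("primary_count")
    out = counts.reset_index()
    out = out.sort_values(
        ["primary_count", "target_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def potency_matrix(
    annotations: TargetAnnotationTable,
    targets: Sequence[str],
    compounds: Sequence[str],
) -> pd.DataFrame:
    """|targets| x |compounds| pIC50 matrix, NaN where unannotated.

    Row and column order follow the given lists (target symbols are
    canonicalized for lookup and as row labels).
    """
    targets = [normalize_target(t) for t in targets]
    compounds = [str(c) for c in compounds]
    df = annotations.df
    sub = df[df["target_id"].isin(targets) & df["compound_id"].isin(compounds)]
    mat = sub.pivot_table(
        index="target_id", columns="compound_id", values="pic50", aggfunc="max"
    )
    return mat.reindex(index=targets, columns=compounds)


def unique_offtargets(
    annotations: TargetAnnotationTable,
    compound: str,
    comparators: Iterable[str],
    pic50_min: float = 6.0,
) -> set[str]:
    """Targets of ``compound`` that no comparator shares, after potency filtering.

    Both sides are filtered at ``pic50_min`` first, so a target the compound
    hits potently but a comparator only weakly still counts as unique to the
    comparator-filtered view.
    """
    compound = str(compound)
    comparators = {str(c) for c in comparators}
    if compound in comparators:
        raise ConfigError(f"compound {compound!r} cannot be its own comparator")
    if compound not in annotations.compounds():
        raise UnknownCompoundError(f"compound {compound!r} not in annotation table")
    filtered, _ = filter_by_potency(annotations, pic50_min)
    own = unique_targets(filtered, {compound})
    others = unique_targets(filtered, comparators)
    return own - others
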