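"""Synthetic screen generator: annotated libraries with planted causal targets.

Emulates a single-concentration phenotypic screen of an annotated
small-molecule library against a protease-activity (MMP) fluorescence
readout.  Each compound carries a handful of decoy target annotations with
pIC50 potencies drawn from a truncated normal on the pIC50 scale; a chosen
fraction of compounds is additionally annotated against one of the planted
"causal" targets.  Engaging a causal target at the screening concentration
(1 µM) reduces the fluorescent signal according to a single-hit occupancy
model with a shared maximal effect (Emax); nothing else does.  A seeded
fraction of compounds is toxic: their wells report unreliable fluorescence
and low viability, mirroring the cell atrophy / detachment that removes
compounds from a live-cell screen before the activity assay.

Noise is multiplicative log-normal (fluorescence is scale-noisy and must
stay positive).  All randomness flows from one root seed through
deterministically derived per-stage child streams, so the library and the
plate are each reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .screen_io import PlateReadout, TargetAnnotationTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "occupancy",
    "generate_library",
    "simulate_plate",
    "make_category_map",
    "DEFAULT_UNIVERSE",
]

#: Default target universe: 200 decoy targets plus the planted causal target.
DEFAULT_UNIVERSE: tuple[str, ...] = tuple(f"T{i:03d}" for i in range(1, 201)) + ("GSK3B",)

_PIC50_LO, _PIC50_HI = 3.0, 11.0
_SCREEN_CONC_M = 1e-6


def occupancy(pic50, conc_molar: float):
    """Fractional target occupancy C / (C + IC50) at concentration ``conc_molar``.

    ``pic50`` is -log10(IC50 in molar); accepts scalars or arrays.  Strictly
    increasing in pIC50 and in concentration; equals 0.5 when the
    concentration equals the IC50 (pIC50 = 6 at 1 µM).
    """
    if not conc_molar > 0:
        raise ConfigError(f"concentration must be positive, got {conc_molar}")
    pic50 = np.asarray(pic50, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** (-pic50) / conc_molar)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic screen.

    Defaults mirror a 1,022-compound screen at 1 µM with duplicate technical
    replicates, a corrected-line control at ~40% of the disease baseline
    signal, a reference-drug control at ~45%, and a ~71% toxicity triage
    rate.  Decoy annotations centre near the informativeness boundary
    (pIC50 6 = 1 µM IC50); causal-target annotations are potent
    (pIC50 ~ N(8, 0.7)) so occupancy at 1 µM is near-complete.
    """

    n_compounds: int = 1022
    target_universe: tuple[str, ...] = DEFAULT_UNIVERSE
    mean_targets_per_compound: float = 5.0
    pic50_mean: float = 6.0
    pic50_sd: float = 1.2
    causal_targets: frozenset[str] = frozenset({"GSK3B"})
    causal_annotation_rate: float = 0.05
    causal_pic50_mean: float = 8.0
    causal_pic50_sd: float = 0.7
    emax: float = 0.8
    toxicity_rate: float = 0.714
    mfs_baseline: float = 1000.0
    corr_fraction: float = 0.40
    refdrug_fraction: float = 0.45
    noise_cv: float = 0.1
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 1:
            raise ConfigError("n_compounds must be >= 1")
        if not self.target_universe:
            raise ConfigError("target_universe is empty")
        if not set(self.causal_targets) <= set(self.target_universe):
            raise ConfigError("causal_targets must be a subset of target_universe")
        if not self.mean_targets_per_compound > 0:
            raise ConfigError("mean_targets_per_compound must be > 0")
        for name in ("causal_annotation_rate", "emax", "toxicity_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not self.mfs_baseline > 0:
            raise ConfigError("mfs_baseline must be > 0")
        for name in ("corr_fraction", "refdrug_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SyntheticTruth:
    """Hidden ground truth kept for recovery scoring.

    ``expected_reduction`` is the noiseless fractional MMP-signal reduction
    (0 for compounds with no causal annotation); ``toxic`` marks compounds
    triaged before the activity assay.
    """

    causal_targets: frozenset[str]
    df: pd.DataFrame  # compound_id, expected_reduction, toxic

    def expected_reduction(self) -> pd.Series:
        return self.df.set_index("compound_id")["expected_reduction"]

    def toxic_compounds(self) -> set[str]:
        return set(self.df.loc[self.df["toxic"], "compound_id"])

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()


def _rng(seed: int, stage: int) -> np.random.Generator:
    # per-stage child streams: library=1, plate=2
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _truncnorm(rng, mean: float, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, _PIC50_LO, _PIC50_HI))
    a = (_PIC50_LO - mean) / sd
    b = (_PIC50_HI - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_library(config: SyntheticConfig) -> tuple[TargetAnnotationTable, SyntheticTruth]:
    """Generate an annotated compound library plus its hidden truth.

    Per compound: a Poisson(mean_targets_per_compound) number of distinct
    decoy targets (minimum 1) with truncated-normal pIC50s in [3, 11]; with
    probability ``causal_annotation_rate`` one additional causal-target
    annotation; the single highest-pIC50 annotation is flagged primary.
    Toxicity is Bernoulli(toxicity_rate), independent of annotation.
    """
    rng = _rng(config.seed, 1)
    decoy_pool = np.array(
        sorted(set(config.target_universe) - set(config.causal_targets)), dtype=object
    )
    causal_pool = np.array(sorted(config.causal_targets), dtype=object)
    if len(decoy_pool) == 0:
        raise ConfigError("target_universe contains no non-causal decoy targets")

    n = config.n_compounds
    width = max(4, len(str(n)))
    compound_ids = [f"C{i:0{width}d}" for i in range(1, n + 1)]

    n_decoys = np.maximum(1, rng.poisson(config.mean_targets_per_compound, size=n))
    n_decoys = np.minimum(n_decoys, len(decoy_pool))
    decoy_choices = [
        rng.choice(len(decoy_pool), size=int(k), replace=False) for k in n_decoys
    ]
    decoy_pic50 = _truncnorm(rng, config.pic50_mean, config.pic50_sd, int(n_decoys.sum()))

    has_causal = rng.random(n) < config.causal_annotation_rate
    causal_idx = rng.integers(0, len(causal_pool), size=n)
    causal_pic50 = _truncnorm(
        rng, config.causal_pic50_mean, config.causal_pic50_sd, n
    )

    toxic = rng.random(n) < config.toxicity_rate

    records: list[dict] = []
    expected = np.zeros(n)
    pos = 0
    for i, cid in enumerate(compound_ids):
        k = int(n_decoys[i])
        tgts = list(decoy_pool[decoy_choices[i]])
        pics = list(decoy_pic50[pos : pos + k])
        pos += k
        if has_causal[i]:
            tgts.append(causal_pool[causal_idx[i]])
            pics.append(float(causal_pic50[i]))
            expected[i] = config.emax * occupancy(pics[-1], _SCREEN_CONC_M)
        # primary flag: the most potent annotation (lexicographic tie-break)
        order = sorted(range(len(tgts)), key=lambda j: (-pics[j], str(tgts[j])))
        primary_j = order[0]
        for j, (t, p) in enumerate(zip(tgts, pics)):
            records.append(
                {
                    "compound_id": cid,
                    "target_id": t,
                    "pic50": float(p),
                    "is_primary": j == primary_j,
                }
            )

    table, _ = TargetAnnotationTable.from_records(records)
    truth = SyntheticTruth(
        causal_targets=frozenset(config.causal_targets),
        df=pd.DataFrame(
            {
                "compound_id": compound_ids,
                "expected_reduction": expected,
                "toxic": toxic,
            }
        ),
    )
    return table, truth


def _noise(rng, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_plate(
    annotations: TargetAnnotationTable,
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> PlateReadout:
    """Simulate the plate readout for a generated library.

    Non-toxic treated wells fluoresce at
    ``mfs_baseline x (1 - expected_reduction)`` times log-normal noise, with
    viability drawn high; toxic wells report low viability and fluorescence
    from a wide uniform (the readout is meaningless once cells detach).
    Control wells sit at the baseline, corr_fraction and refdrug_fraction
    levels with the same noise model, ``n_replicates`` wells per condition.
    """
    missing = set(truth.df["compound_id"]) ^ annotations.compounds()
    extra = annotations.compounds() - set(truth.df["compound_id"])
    if extra:
        raise ConfigError(f"truth does not cover compounds: {sorted(extra)[:5]}")
    rng = _rng(config.seed, 2)
    rep = config.n_replicates
    base = config.mfs_baseline

    rows: list[dict] = []
    control_levels = [
        ("MFS_DMSO", base),
        ("CORR", config.corr_fraction * base),
        ("REFERENCE_DRUG", config.refdrug_fraction * base),
    ]
    ctrl_noise = _noise(rng, config.noise_cv, len(control_levels) * rep)
    for ci, (role, level) in enumerate(control_levels):
        for r in range(1, rep + 1):
            rows.append(
                {
                    "well_id": f"{role}_r{r}",
                    "role": role,
                    "compound_id": None,
                    "replicate": r,
                    "fluorescence": level * ctrl_noise[ci * rep + (r - 1)],
                    "viability": np.nan,
                }
            )

    tdf = truth.df
    n = len(tdf)
    noise = _noise(rng, config.noise_cv, n * rep).reshape(n, rep)
    toxic = tdf["toxic"].to_numpy()
    red = tdf["expected_reduction"].to_numpy()
    toxic_fluor = rng.uniform(0.0, 2.0 * base, size=(n, rep))
    viab = np.where(
        toxic[:, None],
        rng.uniform(0.05, 0.45, size=(n, rep)),
        rng.uniform(0.70, 1.00, size=(n, rep)),
    )
    fluor = np.where(
        toxic[:, None], toxic_fluor, base * (1.0 - red)[:, None] * noise
    )
    for i, cid in enumerate(tdf["compound_id"]):
        for r in range(1, rep + 1):
            rows.append(
                {
                    "well_id": f"{cid}_r{r}",
                    "role": "TREATED",
                    "compound_id": cid,
                    "replicate": r,
                    "fluorescence": float(fluor[i, r - 1]),
                    "viability": float(viab[i, r - 1]),
                }
            )
    return PlateReadout(pd.DataFrame(rows))


_CATEGORIES = ("KINASE", "GPCR", "ION_CHANNEL", "PROTEASE")


def make_category_map(
    targets: Iterable[str], causal_targets: Iterable[str] = ()
) -> pd.DataFrame:
    """Deterministic toy target->category map for overrepresentation tests.

    Assigns categories cyclically over the sorted target list; causal
    targets are forced into KINASE (the planted signal's category), mirroring
    a protein-class annotation such as a GO molecular-function slim.
    """
    targets = sorted(set(targets))
    causal = {str(t) for t in causal_targets}
    rows = []
    for i, t in enumerate(targets):
        cat = "KINASE" if t in causal else _CATEGORIES[i % len(_CATEGORIES)]
        rows.append(
            {"target_id": t, "category_id": cat, "category_name": cat.title().replace("_", " ")}
        )
    return pd.DataFrame(rows, columns=["target_id", "category_id", "category_name"])
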