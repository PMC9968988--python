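"""Toxicity triage, control normalization and hit calling.

A screened compound first passes viability triage (cells that atrophy or
detach cannot be assayed for secreted MMP activity); surviving compounds get
a normalized activity — mean treated fluorescence over replicates divided by
the mean untreated disease-line (MFS_DMSO) fluorescence — and are called
hits when that activity falls to the level of the healthy-control band.

The default rule anchors the threshold on the control wells: the isogenic
corrected line (CORR) and the reference drug (losartan role), taking
``max(mean + k_sd * SD)`` over the reference roles on the normalized scale.
A compound whose activity is at or below that band has reduced MMP activity
to control-comparable levels.  A fixed-fraction rule is available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingControlError
from .screen_io import HitCallTable, PlateReadout

__all__ = ["HitCallConfig", "ControlSummary", "flag_toxicity", "normalize_activity", "call_hits"]

CONTROL_BAND = "control_band"
FIXED_FRACTION = "fixed_fraction"


@dataclass(frozen=True)
class HitCallConfig:
    """Parameters of triage and hit calling.

    viability_min: compounds with mean viability below this are TOXIC.
    threshold_rule: 'control_band' (default) or 'fixed_fraction'.
    k_sd: width of the control band in control SDs (default 2).
    fixed_fraction: activity cut for the fixed rule (required there).
    reference_roles: which control roles anchor the band (default both).
    """

    viability_min: float = 0.5
    threshold_rule: str = CONTROL_BAND
    k_sd: float = 2.0
    fixed_fraction: float | None = None
    reference_roles: tuple[str, ...] = ("CORR", "REFERENCE_DRUG")

    def __post_init__(self):
        if not 0.0 <= self.viability_min <= 1.0:
            raise ConfigError("viability_min must lie in [0, 1]")
        if self.threshold_rule not in (CONTROL_BAND, FIXED_FRACTION):
            raise ConfigError(f"unknown threshold_rule {self.threshold_rule!r}")
        if self.k_sd < 0:
            raise ConfigError("k_sd must be >= 0")
        if self.threshold_rule == FIXED_FRACTION:
            if self.fixed_fraction is None or not 0.0 < self.fixed_fraction < 1.0:
                raise ConfigError("fixed_fraction must be set in (0, 1)")
        bad = set(self.reference_roles) - {"CORR", "REFERENCE_DRUG"}
        if bad:
            raise ConfigError(f"invalid reference roles: {sorted(bad)}")
        if not self.reference_roles:
            raise ConfigError("at least one reference role is required")


@dataclass(frozen=True)
class ControlSummary:
    """Mean/SD of a control role on the normalized (fraction-of-baseline) scale."""

    mean: float
    sd: float | None  # absent when n = 1
    n: int


def flag_toxicity(
    plate: PlateReadout,
    config: HitCallConfig = HitCallConfig(),
    external_toxic: Iterable[str] = (),
) -> set[str]:
    """Compounds failing viability triage.

    A compound is toxic iff its mean well viability (where viability was
    recorded) falls below ``viability_min``, or it carries an explicit
    external toxic flag.  Compounds with no viability data and no flag are
    assayed — absence of evidence does not triage.
    """
    df = plate.df
    treated = df[df["role"] == "TREATED"]
    by_cmpd = treated.groupby("compound_id")["viability"].mean()
    toxic = {str(c) for c, v in by_cmpd.items() if pd.notna(v) and v < config.viability_min}
    toxic |= {str(c) for c in external_toxic} & plate.treated_compounds()
    return toxic


def normalize_activity(
    plate: PlateReadout,
) -> tuple[pd.Series, dict[str, ControlSummary]]:
    """Normalize per-compound activity against the MFS_DMSO baseline.

    activity(c) = mean treated fluorescence over replicates / mean MFS_DMSO
    fluorescence.  Also returns mean/SD summaries (sample SD, absent at
    n = 1) for every control role present, on the same normalized scale.
    """
    df = plate.df
    baseline_wells = df.loc[df["role"] == "MFS_DMSO", "fluorescence"]
    if baseline_wells.empty:
        raise MissingControlError("no MFS_DMSO wells on the plate")
    baseline = float(baseline_wells.mean())
    if baseline <= 0:
        raise MissingControlError("MFS_DMSO baseline fluorescence is not positive")

    treated = df[df["role"] == "TREATED"]
    activity = treated.groupby("compound_id")["fluorescence"].mean() / baseline
    activity.index = activity.index.astype(str)
    activity = activity.sort_index()

    summaries: dict[str, ControlSummary] = {}
    for role in ("MFS_DMSO", "CORR", "REFERENCE_DRUG"):
        wells = df.loc[df["role"] == role, "fluorescence"] / baseline
        if wells.empty:
            continue
        sd = float(wells.std(ddof=1)) if len(wells) > 1 else None
        summaries[role] = ControlSummary(mean=float(wells.mean()), sd=sd, n=len(wells))
    return activity, summaries


def control_band_threshold(
    summaries: Mapping[str, ControlSummary], config: HitCallConfig
) -> float:
    """max over reference roles of (mean + k_sd * SD); SD taken as 0 at n = 1."""
    cands = [
        s.mean + config.k_sd * (s.sd if s.sd is not None else 0.0)
        for role, s in summaries.items()
        if role in config.reference_roles
    ]
    if not cands:
        raise MissingControlError(
            f"no reference-control wells for roles {config.reference_roles}"
        )
    return max(cands)


def call_hits(
    activity: pd.Series,
    summaries: Mapping[str, ControlSummary],
    toxic: set[str],
    config: HitCallConfig = HitCallConfig(),
) -> HitCallTable:
    """Call hits among assayed compounds; toxic compounds are never called.

    Under the control-band rule a compound is a HIT iff it is assayed and
    its activity is at or below the band threshold (inclusive, so boundary
    compounds are called deterministically).  The threshold used is attached
    to the returned table as ``.threshold``.
    """
    if config.threshold_rule == CONTROL_BAND:
        threshold = control_band_threshold(summaries, config)
    else:
        threshold = float(config.fixed_fraction)

    rows = []
    for cid, act in activity.items():
        cid = str(cid)
        if cid in toxic:
            rows.append(
                {"compound_id": cid, "status": "TOXIC", "activity": np.nan, "call": None}
            )
        else:
            rows.append(
                {
                    "compound_id": cid,
                    "status": "ASSAYED",
                    "activity": float(act),
                    "call": "HIT" if act <= threshold else "NONHIT",
                }
            )
    df = pd.DataFrame(rows, columns=["compound_id", "status", "activity", "call"])
    return HitCallTable(df, threshold=threshold)
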