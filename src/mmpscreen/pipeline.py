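"""End-to-end pipeline: simulate → triage → call hits → deconvolve → enrich.

``run_pipeline`` drives the whole cascade from a single config (a YAML
mapping or a path to one), writes every stage artifact as TSV plus a JSON
run manifest, and logs before/after counts for every filter to stderr.
Manifests contain the config snapshot, input digests, the seed and the
per-stage funnel counts, and are byte-stable across reruns with the same
inputs — diffing two manifests answers "did anything change".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .deconvolution import DeconvolutionConfig, filter_by_potency, potency_matrix, unique_targets
from .enrichment import category_overrepresentation, rank_targets
from .errors import ConfigError, ScreenError
from .hit_calling import HitCallConfig, call_hits, flag_toxicity, normalize_activity
from .screen_io import (
    HitCallTable,
    PlateReadout,
    TargetAnnotationTable,
    read_annotations,
    read_plate,
    write_table,
)
from .synthetic import SyntheticConfig, generate_library, make_category_map, simulate_plate

__all__ = ["RunManifest", "load_config", "run_pipeline", "report"]

log = logging.getLogger("mmpscreen")

MANIFEST_NAME = "manifest.json"


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    seed: int | None
    config: dict
    input_digests: dict[str, str]
    threshold: float | None
    counts: dict[str, int]

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "input_digests": self.input_digests,
            "threshold": self.threshold,
            "counts": self.counts,
        }
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        return cls(
            version=d["version"],
            seed=d["seed"],
            config=d["config"],
            input_digests=d["input_digests"],
            threshold=d["threshold"],
            counts=d["counts"],
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    """Load a pipeline config (YAML mapping) from disk."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return data


def _build_synthetic_config(section: Mapping[str, Any], seed: int | None) -> SyntheticConfig:
    kwargs = dict(section)
    for key in ("target_universe",):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "causal_targets" in kwargs:
        kwargs["causal_targets"] = frozenset(kwargs["causal_targets"])
    try:
        cfg = SyntheticConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid simulate section: {exc}") from None
    if seed is not None:
        cfg = cfg.with_seed(seed)
    return cfg


def _provenance(config_digest: str) -> list[str]:
    return [f"mmpscreen {__version__} config={config_digest}"]


def run_pipeline(
    config: Mapping[str, Any] | str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Run the full screen-analysis cascade and write all artifacts to outdir.

    The config either requests a synthetic screen (``simulate:`` section) or
    points at existing annotation and plate files (``inputs:`` section with
    ``annotations``, ``plate`` and optionally ``toxic_flags``, a one-id-per-
    line triage list).  ``seed`` overrides the config seed for simulation.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    config = dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.get("seed")

    config_digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    comments = _provenance(config_digest)
    input_digests: dict[str, str] = {}
    external_toxic: set[str] = set()

    # --- stage 1: obtain annotations + plate -----------------------------
    if "simulate" in config:
        sim_cfg = _build_synthetic_config(config.get("simulate") or {}, seed)
        seed = sim_cfg.seed
        log.info("simulate: %d compounds, %d targets, seed %d",
                 sim_cfg.n_compounds, len(sim_cfg.target_universe), sim_cfg.seed)
        annotations, truth = generate_library(sim_cfg)
        plate = simulate_plate(annotations, truth, sim_cfg)
        write_table(annotations, outdir / "annotations.tsv", comments)
        write_table(truth, outdir / "truth.tsv", comments)
        write_table(plate, outdir / "plate.tsv", comments)
        universe_targets = sorted(sim_cfg.target_universe)
    elif "inputs" in config:
        inputs = config["inputs"]
        ann_path = Path(inputs["annotations"])
        plate_path = Path(inputs["plate"])
        for p in (ann_path, plate_path):
            if not p.exists():
                raise ConfigError(f"input file not found: {p}")
        input_digests[str(ann_path)] = _sha256(ann_path)
        input_digests[str(plate_path)] = _sha256(plate_path)
        annotations, load_report = read_annotations(ann_path)
        log.info("annotations: %d records (%d without pIC50, %d duplicates collapsed)",
                 load_report.n_records, load_report.n_missing_pic50,
                 load_report.n_duplicates_collapsed)
        plate = read_plate(plate_path)
        if inputs.get("toxic_flags"):
            flags_path = Path(inputs["toxic_flags"])
            if not flags_path.exists():
                raise ConfigError(f"input file not found: {flags_path}")
            input_digests[str(flags_path)] = _sha256(flags_path)
            external_toxic = {
                line.strip()
                for line in flags_path.read_text().splitlines()
                if line.strip() and not line.startswith("#")
            }
        universe_targets = sorted(annotations.targets())
    else:
        raise ConfigError("config needs a 'simulate' or an 'inputs' section")

    # --- stage 2: triage and hit calling ----------------------------------
    hc_cfg = HitCallConfig(**(config.get("hit_calling") or {}))
    toxic = flag_toxicity(plate, hc_cfg, external_toxic=external_toxic)
    activity, summaries = normalize_activity(plate)
    hit_table = call_hits(activity, summaries, toxic, hc_cfg)
    n_screened = len(plate.treated_compounds())
    hits, nonhits = hit_table.hits(), hit_table.nonhits()
    log.info("triage: %d screened -> %d toxic, %d assayed",
             n_screened, len(hit_table.toxic()), len(hit_table.assayed()))
    log.info("hit calling: threshold %.4f -> %d hits, %d non-hits",
             hit_table.threshold, len(hits), len(nonhits))
    write_table(hit_table, outdir / "hits.tsv", comments)

    # --- stage 3: deconvolution -------------------------------------------
    dc_cfg = DeconvolutionConfig(**(config.get("deconvolution") or {}))
    pre_filter_targets = unique_targets(annotations, hits)
    filtered, filt_report = filter_by_potency(annotations, dc_cfg.pic50_min)
    post_filter_targets = unique_targets(filtered, hits)
    log.info(
        "potency filter (pIC50 >= %.2f): %d -> %d records "
        "(%d below threshold, %d without pIC50); unique hit targets %d -> %d",
        dc_cfg.pic50_min, filt_report.n_input, filt_report.n_retained,
        filt_report.n_below_threshold, filt_report.n_missing_pic50,
        len(pre_filter_targets), len(post_filter_targets),
    )
    ranking = rank_targets(filtered, hits, nonhits, min_frequency=1)
    write_table(ranking, outdir / "ranking.tsv", comments)
    high_freq = ranking.df[ranking.df["hit_frequency"] >= dc_cfg.min_frequency]
    log.info("frequency filter (>= %d hits): %d high-frequency targets",
             dc_cfg.min_frequency, len(high_freq))

    matrix = potency_matrix(filtered, list(high_freq["target_id"]), sorted(hits))
    matrix_path = outdir / "matrix.tsv"
    header = "\n".join(f"# {c}" for c in comments)
    matrix_path.write_text(
        header + "\n" + matrix.to_csv(sep="\t", na_rep="", index_label="target_id"),
        encoding="utf-8",
    )

    # --- stage 4: enrichment ----------------------------------------------
    enr_section = config.get("enrichment") or {}
    if enr_section.get("categories") == "synthetic":
        cat_map = make_category_map(universe_targets, causal_targets=())
    elif enr_section.get("categories"):
        cat_path: Path = Path(enr_section["categories"])
        if not cat_path.exists():
            raise ConfigError(f"category map not found: {cat_path}")
        input_digests[str(cat_path)] = _sha256(cat_path)
        cat_map = pd.read_csv(cat_path, sep="\t", comment="#")
    else:
        cat_map = None
    if cat_map is not None and len(post_filter_targets) and hits:
        universe = set(cat_map["target_id"]) | set(unique_targets(filtered, hits | nonhits))
        cat_result = category_overrepresentation(
            post_filter_targets, cat_map, universe
        )
        cat_out = outdir / "enrich_categories.tsv"
        cat_out.write_text(
            header + "\n" + cat_result.to_csv(sep="\t", index=False), encoding="utf-8"
        )
        log.info("category overrepresentation: %d categories tested", len(cat_result))

    # --- manifest ----------------------------------------------------------
    counts = {
        "n_compounds_screened": n_screened,
        "n_toxic": len(hit_table.toxic()),
        "n_assayed": len(hit_table.assayed()),
        "n_hits": len(hits),
        "n_nonhits": len(nonhits),
        "unique_targets_prefilter": len(pre_filter_targets),
        "unique_targets_postfilter": len(post_filter_targets),
        "n_high_frequency_targets": int(len(high_freq)),
        "annotation_records": filt_report.n_input,
        "annotation_records_potency_filtered": filt_report.n_retained,
    }
    manifest = RunManifest(
        version=__version__,
        seed=seed,
        config=config,
        input_digests=input_digests,
        threshold=hit_table.threshold,
        counts=counts,
    )
    (outdir / MANIFEST_NAME).write_text(manifest.to_json(), encoding="utf-8")
    return manifest


def report(
    run_dir: str | Path,
    top_n: int = 15,
    offtarget_compound: str | None = None,
    offtarget_comparators: list[str] | None = None,
    pic50_min: float | None = None,
) -> str:
    """Human-readable summary of a completed run directory.

    Funnel table (screened → assayed → hits with percentages), top-N target
    ranking, and optionally an off-target uniqueness section comparing one
    compound against a comparator list on the run's annotations.
    """
    from .deconvolution import unique_offtargets
    from .screen_io import read_ranking

    run_dir = Path(run_dir)
    manifest_path = run_dir / MANIFEST_NAME
    if not manifest_path.exists():
        raise ScreenError(f"incomplete run: {manifest_path} missing")
    manifest = RunManifest.from_json(manifest_path.read_text())
    c = manifest.counts

    def pct(a: int, b: int) -> str:
        return f"{100.0 * a / b:.1f}%" if b else "n/a"

    lines = [
        f"mmpscreen {manifest.version} run report",
        "",
        "Screening funnel",
        f"  compounds screened   {c['n_compounds_screened']}",
        f"  toxic / triaged      {c['n_toxic']} ({pct(c['n_toxic'], c['n_compounds_screened'])})",
        f"  assayed              {c['n_assayed']} ({pct(c['n_assayed'], c['n_compounds_screened'])})",
        f"  hits                 {c['n_hits']} ({pct(c['n_hits'], c['n_assayed'])} of assayed)",
        f"  hit threshold        {manifest.threshold:.4f} (normalized activity)"
        if manifest.threshold is not None
        else "  hit threshold        n/a",
        "",
        "Target deconvolution",
        f"  unique targets (pre-filter)   {c['unique_targets_prefilter']}",
        f"  unique targets (pIC50 filter) {c['unique_targets_postfilter']}",
        f"  high-frequency targets        {c['n_high_frequency_targets']}",
        "",
    ]
    if c["n_hits"] == 0:
        lines.append("No hits were called; target deconvolution was not performed.")
    else:
        ranking = read_ranking(run_dir / "ranking.tsv")
        lines.append(f"Top {min(top_n, len(ranking.df))} targets "
                     "(hit frequency, mean pIC50, primary count, q)")
        for row in ranking.df.head(top_n).itertuples(index=False):
            mean_p = "-" if pd.isna(row.mean_pic50) else f"{row.mean_pic50:.2f}"
            q = "-" if pd.isna(row.q_enrich) else f"{row.q_enrich:.3g}"
            lines.append(
                f"  {row.target_id:<12} {row.hit_frequency:>4} {mean_p:>8} "
                f"{row.primary_count:>4} {q:>10}"
            )
    if offtarget_compound:
        annotations, _ = read_annotations(run_dir / "annotations.tsv")
        cut = pic50_min if pic50_min is not None else 6.0
        uniq = unique_offtargets(
            annotations, offtarget_compound, offtarget_comparators or [], cut
        )
        lines += [
            "",
            f"Unique off-targets of {offtarget_compound} vs "
            f"{', '.join(offtarget_comparators or [])} (pIC50 >= {cut:g})",
            f"  {len(uniq)} unique target(s): {', '.join(sorted(uniq)) or '(none)'}",
        ]
    return "\n".join(lines) + "\n"
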