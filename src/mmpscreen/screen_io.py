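"""Domain tables and strict TSV readers/writers for the screen pipeline.

The pipeline moves four tabular artifacts around:

* :class:`TargetAnnotationTable` — sparse (compound, target) -> pIC50 records
  with a primary-target flag, the substrate of target deconvolution;
* :class:`PlateReadout` — per-well fluorescence with a control role and a
  replicate index, the substrate of hit calling;
* :class:`HitCallTable` — per-compound triage status and hit call;
* :class:`TargetRankingTable` — per-target frequency / potency / enrichment.

All files are tab-separated UTF-8 with a header row and '.' decimals; lines
starting with '#' are provenance comments and are skipped on read.  Absent
values are written as empty cells and read back as absent, so every table
round-trips exactly through :func:`write_table`.

Target symbols are normalized to the uppercase gene-symbol convention, with
a small Greek-letter transliteration map so that e.g. "GSK3β" and "GSK3B"
collapse to the same key; set operations across annotation tables require
canonical keys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "Dialect",
    "LoadReport",
    "TargetAnnotationTable",
    "PlateReadout",
    "HitCallTable",
    "TargetRankingTable",
    "normalize_target",
    "read_annotations",
    "read_annotations_excel",
    "read_plate",
    "read_hit_calls",
    "read_ranking",
    "write_table",
]

PLATE_ROLES = ("TREATED", "MFS_DMSO", "CORR", "REFERENCE_DRUG")

# Greek letters seen in gene-symbol suffixes (both cases; applied after upper()).
_GREEK_MAP = str.maketrans(
    {
        "Α": "A", "α": "A",
        "Β": "B", "β": "B",
        "Γ": "G", "γ": "G",
        "Δ": "D", "δ": "D",
        "Ε": "E", "ε": "E",
        "Κ": "K", "κ": "K",
        "Μ": "M", "μ": "M",
        "Ω": "O", "ω": "O",
    }
)

_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}
_FALSE_STRINGS = {"false", "0", "no", "n", "f", ""}


def normalize_target(symbol: str) -> str:
    """Canonicalize a target symbol: trim, uppercase, transliterate Greek."""
    return str(symbol).strip().upper().translate(_GREEK_MAP)


def _parse_bool(value: object, row: int, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ParseError(f"row {row}: cannot parse boolean {column}={value!r}")


def _parse_float(value: object, row: int, column: str) -> float:
    """Parse a float cell; empty -> NaN; garbage -> ParseError with row number."""
    if value is None:
        return math.nan
    if isinstance(value, (int, float, np.floating, np.integer)):
        return float(value)
    text = str(value).strip()
    if text == "":
        return math.nan
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"row {row}: non-numeric {column}={value!r}") from None


@dataclass(frozen=True)
class Dialect:
    """Column names and separator for annotation-shaped files.

    The layout of deposited supplementary workbooks varies, so every column
    name is configurable; defaults match the pipeline's own TSV schema.
    """

    sep: str = "\t"
    compound_col: str = "compound_id"
    target_col: str = "target_id"
    pic50_col: str = "pic50"
    primary_col: str = "is_primary"


@dataclass(frozen=True)
class LoadReport:
    """What the annotation loader did: counts for the log and for filters."""

    n_rows_read: int
    n_records: int
    n_missing_pic50: int
    n_duplicates_collapsed: int


class TargetAnnotationTable:
    """Normalized sparse compound x target annotation table.

    Invariants enforced on construction:

    * (compound_id, target_id) pairs unique (duplicates collapsed upstream);
    * pIC50 finite and > 0 wherever present (absent pIC50 is allowed);
    * at most one ``is_primary`` record per compound.

    Rows are kept sorted by (compound_id, target_id) so the normalized table
    is independent of input row order.
    """

    columns = ("compound_id", "target_id", "pic50", "is_primary")

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, list(self.columns)].copy()
        df["compound_id"] = df["compound_id"].astype(str)
        df["target_id"] = df["target_id"].astype(str)
        df["pic50"] = df["pic50"].astype(float)
        df["is_primary"] = df["is_primary"].astype(bool)
        df = df.sort_values(["compound_id", "target_id"], kind="mergesort")
        df = df.reset_index(drop=True)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if df.duplicated(["compound_id", "target_id"]).any():
            dup = df[df.duplicated(["compound_id", "target_id"])].iloc[0]
            raise ValidationError(
                f"duplicate annotation ({dup.compound_id}, {dup.target_id})"
            )
        present = df["pic50"].notna()
        bad = present & (~np.isfinite(df["pic50"]) | (df["pic50"] <= 0))
        if bad.any():
            row = df[bad].iloc[0]
            raise ValidationError(
                f"pIC50 must be finite and > 0: ({row.compound_id}, "
                f"{row.target_id}) has {row.pic50}"
            )
        primaries = df[df["is_primary"]].groupby("compound_id").size()
        conflicts = primaries[primaries > 1]
        if len(conflicts):
            raise ValidationError(
                "conflicting primary-target flags for compound(s): "
                + ", ".join(conflicts.index[:5])
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[Mapping[str, object]],
        keep: str = "max_pic50",
    ) -> tuple["TargetAnnotationTable", LoadReport]:
        """Normalize raw records into a table, collapsing duplicates.

        Duplicate (compound, target) records keep the maximum pIC50 — the
        most potent annotation is the conservative choice for a >=-threshold
        potency filter — and OR their primary flags.
        """
        if keep != "max_pic50":
            raise ValueError(f"unknown duplicate policy {keep!r}")
        rows = []
        for i, rec in enumerate(records, start=1):
            rows.append(
                {
                    "compound_id": str(rec["compound_id"]).strip(),
                    "target_id": normalize_target(str(rec["target_id"])),
                    "pic50": _parse_float(rec.get("pic50"), i, "pic50"),
                    "is_primary": _parse_bool(rec.get("is_primary", False), i, "is_primary"),
                }
            )
        n_read = len(rows)
        df = pd.DataFrame(
            rows, columns=["compound_id", "target_id", "pic50", "is_primary"]
        )
        if len(df):
            df = (
                df.groupby(["compound_id", "target_id"], as_index=False)
                .agg(pic50=("pic50", "max"), is_primary=("is_primary", "any"))
            )
        table = cls(df)
        report = LoadReport(
            n_rows_read=n_read,
            n_records=len(table.df),
            n_missing_pic50=int(table.df["pic50"].isna().sum()),
            n_duplicates_collapsed=n_read - len(table.df),
        )
        return table, report

    # -- queries -----------------------------------------------------------
    def compounds(self) -> set[str]:
        return set(self.df["compound_id"])

    def targets(self) -> set[str]:
        return set(self.df["target_id"])

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetAnnotationTable):
            return NotImplemented
        return self.df.equals(other.df)

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()


class PlateReadout:
    """Per-well plate-reader table: fluorescence plus role and replicate.

    Roles: TREATED (a compound well), MFS_DMSO (untreated disease baseline),
    CORR (isogenic corrected line), REFERENCE_DRUG (losartan-role control).
    """

    columns = ("well_id", "role", "compound_id", "replicate", "fluorescence", "viability")

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, list(self.columns)].copy()
        df["well_id"] = df["well_id"].astype(str)
        df["role"] = df["role"].astype(str)
        df["compound_id"] = df["compound_id"].astype(object)
        df["replicate"] = df["replicate"].astype(int)
        df["fluorescence"] = df["fluorescence"].astype(float)
        df["viability"] = df["viability"].astype(float)
        df = df.reset_index(drop=True)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        bad_role = ~df["role"].isin(PLATE_ROLES)
        if bad_role.any():
            raise ValidationError(f"unknown role {df.loc[bad_role, 'role'].iloc[0]!r}")
        treated = df["role"] == "TREATED"
        missing_cmpd = treated & df["compound_id"].isna()
        if missing_cmpd.any():
            well = df.loc[missing_cmpd, "well_id"].iloc[0]
            raise ValidationError(f"TREATED well {well!r} lacks a compound_id")
        stray = ~treated & df["compound_id"].notna()
        if stray.any():
            well = df.loc[stray, "well_id"].iloc[0]
            raise ValidationError(f"control well {well!r} carries a compound_id")
        if (df["fluorescence"] < 0).any():
            well = df.loc[df["fluorescence"] < 0, "well_id"].iloc[0]
            raise ValidationError(f"negative fluorescence in well {well!r}")
        viab = df["viability"].dropna()
        if ((viab < 0) | (viab > 1)).any():
            raise ValidationError("viability outside [0, 1]")
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate indices must be positive")
        group = df["compound_id"].where(treated, df["role"])
        dup = pd.DataFrame({"g": group, "r": df["replicate"]}).duplicated()
        if dup.any():
            well = df.loc[dup, "well_id"].iloc[0]
            raise ValidationError(
                f"duplicate replicate index within a well group (well {well!r})"
            )

    def treated_compounds(self) -> set[str]:
        mask = self.df["role"] == "TREATED"
        return set(self.df.loc[mask, "compound_id"].astype(str))

    def roles_present(self) -> set[str]:
        return set(self.df["role"])

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateReadout):
            return NotImplemented
        return self.df.equals(other.df)

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()


class HitCallTable:
    """Per-compound triage status and hit call.

    TOXIC compounds carry no call (and usually no activity); ASSAYED
    compounds carry a normalized activity and a HIT/NONHIT call.
    """

    columns = ("compound_id", "status", "activity", "call")

    def __init__(self, df: pd.DataFrame, threshold: float | None = None):
        df = df.loc[:, list(self.columns)].copy()
        df["compound_id"] = df["compound_id"].astype(str)
        df["status"] = df["status"].astype(str)
        df["activity"] = df["activity"].astype(float)
        df["call"] = df["call"].astype(object)
        df = df.sort_values("compound_id", kind="mergesort").reset_index(drop=True)
        self._validate(df)
        self.df = df
        self.threshold = threshold

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if not df["status"].isin(["TOXIC", "ASSAYED"]).all():
            raise ValidationError("status must be TOXIC or ASSAYED")
        if df["compound_id"].duplicated().any():
            raise ValidationError("duplicate compound_id in hit-call table")
        toxic = df["status"] == "TOXIC"
        if df.loc[toxic, "call"].notna().any():
            raise ValidationError("TOXIC compounds must not carry a call")
        assayed_calls = df.loc[~toxic, "call"]
        if assayed_calls.isna().any():
            raise ValidationError("ASSAYED compounds must carry a call")
        if not assayed_calls.isin(["HIT", "NONHIT"]).all():
            raise ValidationError("call must be HIT or NONHIT")

    def hits(self) -> set[str]:
        m = self.df["call"] == "HIT"
        return set(self.df.loc[m, "compound_id"])

    def nonhits(self) -> set[str]:
        m = self.df["call"] == "NONHIT"
        return set(self.df.loc[m, "compound_id"])

    def toxic(self) -> set[str]:
        m = self.df["status"] == "TOXIC"
        return set(self.df.loc[m, "compound_id"])

    def assayed(self) -> set[str]:
        m = self.df["status"] == "ASSAYED"
        return set(self.df.loc[m, "compound_id"])

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HitCallTable):
            return NotImplemented
        return self.df.equals(other.df)

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()


class TargetRankingTable:
    """Per-target ranking: hit frequency, potency, primary count, enrichment."""

    columns = (
        "target_id",
        "hit_frequency",
        "mean_pic50",
        "primary_count",
        "nonhit_frequency",
        "p_enrich",
        "q_enrich",
    )

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, list(self.columns)].copy()
        df["target_id"] = df["target_id"].astype(str)
        df["hit_frequency"] = df["hit_frequency"].astype(int)
        df["mean_pic50"] = df["mean_pic50"].astype(float)
        df["primary_count"] = df["primary_count"].astype(int)
        df["nonhit_frequency"] = df["nonhit_frequency"].astype(int)
        df["p_enrich"] = df["p_enrich"].astype(float)
        df["q_enrich"] = df["q_enrich"].astype(float)
        df = df.reset_index(drop=True)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if (df["hit_frequency"] < 0).any() or (df["primary_count"] < 0).any():
            raise ValidationError("counts must be non-negative")
        for col in ("p_enrich", "q_enrich"):
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValidationError(f"{col} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetRankingTable):
            return NotImplemented
        return self.df.equals(other.df)

    def to_frame(self) -> pd.DataFrame:
        return self.df.copy()


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(
        path, sep=sep, dtype=str, comment="#", keep_default_na=False, na_values=[]
    )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path | str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")


def read_annotations(
    path: str | Path, dialect: Dialect = Dialect()
) -> tuple[TargetAnnotationTable, LoadReport]:
    """Read a compound x target annotation table (TSV by default).

    Returns the normalized table and a :class:`LoadReport` with the record
    count, the number of records lacking a pIC50, and the number of
    duplicate rows collapsed under the keep-max-pIC50 policy.
    """
    raw = _read_tsv(path, sep=dialect.sep)
    d = dialect
    _require_columns(raw, [d.compound_col, d.target_col, d.pic50_col, d.primary_col], path)
    records = (
        {
            "compound_id": row[d.compound_col],
            "target_id": row[d.target_col],
            "pic50": row[d.pic50_col],
            "is_primary": row[d.primary_col],
        }
        for row in raw.to_dict("records")
    )
    return TargetAnnotationTable.from_records(records)


def read_annotations_excel(
    path: str | Path, dialect: Dialect = Dialect(), sheet: int | str = 0
) -> tuple[TargetAnnotationTable, LoadReport]:
    """Thin adapter for supplementary-shaped Excel workbooks.

    Column names are configurable through the dialect because deposited
    workbook layouts vary; values are normalized exactly as for TSV input.
    """
    raw = pd.read_excel(path, sheet_name=sheet, dtype=object)
    d = dialect
    _require_columns(raw, [d.compound_col, d.target_col, d.pic50_col, d.primary_col], path)
    records = (
        {
            "compound_id": row[d.compound_col],
            "target_id": row[d.target_col],
            "pic50": row[d.pic50_col],
            "is_primary": row[d.primary_col],
        }
        for row in raw.to_dict("records")
    )
    return TargetAnnotationTable.from_records(records)


def read_plate(path: str | Path, sep: str = "\t") -> PlateReadout:
    """Read a per-well plate readout; roles are parsed case-insensitively."""
    raw = _read_tsv(path, sep=sep)
    _require_columns(
        raw, ["well_id", "role", "compound_id", "replicate", "fluorescence"], path
    )
    n = len(raw)
    df = pd.DataFrame(
        {
            "well_id": raw["well_id"].astype(str),
            "role": raw["role"].str.strip().str.upper(),
            "compound_id": raw["compound_id"].where(raw["compound_id"].str.strip() != "", None)
            if n
            else pd.Series([], dtype=object),
            "replicate": [
                int(_parse_float(v, i + 1, "replicate"))
                for i, v in enumerate(raw["replicate"])
            ],
            "fluorescence": [
                _parse_float(v, i + 1, "fluorescence")
                for i, v in enumerate(raw["fluorescence"])
            ],
            "viability": [
                _parse_float(v, i + 1, "viability")
                for i, v in enumerate(raw["viability"])
            ]
            if "viability" in raw.columns
            else [math.nan] * n,
        }
    )
    return PlateReadout(df)


def read_hit_calls(path: str | Path, sep: str = "\t") -> HitCallTable:
    raw = _read_tsv(path, sep=sep)
    _require_columns(raw, ["compound_id", "status", "activity", "call"], path)
    df = pd.DataFrame(
        {
            "compound_id": raw["compound_id"],
            "status": raw["status"].str.strip().str.upper(),
            "activity": [
                _parse_float(v, i + 1, "activity") for i, v in enumerate(raw["activity"])
            ],
            "call": raw["call"].where(raw["call"].str.strip() != "", None)
            if len(raw)
            else pd.Series([], dtype=object),
        }
    )
    return HitCallTable(df)


def read_ranking(path: str | Path, sep: str = "\t") -> TargetRankingTable:
    raw = _read_tsv(path, sep=sep)
    _require_columns(raw, list(TargetRankingTable.columns), path)
    df = pd.DataFrame(
        {
            "target_id": raw["target_id"],
            "hit_frequency": raw["hit_frequency"].astype(int),
            "mean_pic50": [
                _parse_float(v, i + 1, "mean_pic50")
                for i, v in enumerate(raw["mean_pic50"])
            ],
            "primary_count": raw["primary_count"].astype(int),
            "nonhit_frequency": raw["nonhit_frequency"].astype(int),
            "p_enrich": [
                _parse_float(v, i + 1, "p_enrich") for i, v in enumerate(raw["p_enrich"])
            ],
            "q_enrich": [
                _parse_float(v, i + 1, "q_enrich") for i, v in enumerate(raw["q_enrich"])
            ],
        }
    )
    return TargetRankingTable(df)


# ---------------------------------------------------------------------------
# writer


def _format_cell(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (float, np.floating)):
        if math.isnan(value):
            return ""
        return repr(float(value))
    return str(value)


def write_table(
    table: object, path: str | Path, header_comments: Sequence[str] = ()
) -> Path:
    """Write any pipeline table as TSV; round-trips exactly through its reader.

    Absent values become empty cells; booleans become ``true``/``false``;
    floats are written with full precision (``repr``).  Optional '#'-prefixed
    provenance comments go above the header and are skipped by all readers.
    """
    df = table.to_frame()
    path = Path(path)
    lines = [f"# {c}".rstrip() for c in header_comments]
    lines.append("\t".join(df.columns))
    for row in df.itertuples(index=False):
        lines.append("\t".join(_format_cell(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
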