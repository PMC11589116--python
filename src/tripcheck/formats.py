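"""Reading and writing the pipeline's tabular interchange formats.

All files are plain delimited text (comma or tab, auto-detected, UTF-8).
pandas DataFrames are the canonical in-memory containers; the column
conventions are:

* peak table (long):  sample_id, marker_id, allele_size_bp, height_rfu
* peak table (wide):  sample_id, marker_id, allele1, height1, allele2,
  height2[, allele3, height3]  (auto-detected by header)
* panel file:         marker_id, repeat_motif_bp, size_min_bp, size_max_bp,
  multiplex_group
* genotype table:     sample_id, marker_id, alleles (';'-joined sizes),
  copy_numbers (';'-joined or blank when dosage is unknown)
* sample metadata:    sample_id, experiment, stage, treatment_psi,
  family_id, replicate_id, role
* mortality counts:   unit_id, interval, n_start, n_dead

Every input row is either ingested or accounted for in a diagnostics
report; nothing is silently dropped.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dosage import LocusCall, configuration_from_copies

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError", "ValidationError", "MarkerPanel", "PeakRecord",
    "PeakTableDiagnostics", "read_peak_table", "read_panel",
    "read_genotype_table", "write_genotype_table", "read_sample_meta",
    "read_mortality_counts", "write_results", "load_config", "dump_config",
    "TREATMENTS_PSI", "STAGES", "ROLES", "INTERVALS",
]

TREATMENTS_PSI = (0, 6500, 7500, 8500, 9500)
STAGES = ("egg", "parr", "parent")
ROLES = ("dam", "sire", "offspring")
INTERVALS = ("fertilization_to_eyed_egg", "eyed_egg_to_start_feed",
             "start_feed_to_parr")


class FormatError(ValueError):
    """File structure does not match the expected format."""


class ValidationError(ValueError):
    """File parsed but carries invalid values."""


@dataclass(frozen=True)
class PeakRecord:
    """One electropherogram peak."""
    sample_id: str
    marker_id: str
    allele_size_bp: float
    height_rfu: float

    def __post_init__(self) -> None:
        if self.height_rfu < 0:
            raise ValidationError("height_rfu must be non-negative")


class MarkerPanel:
    """Marker-panel definition: repeat motif length and size range per marker.

    The motif length drives both stutter filtering (stutter sits one motif
    below the parent peak) and the base-pair-shift rule (slippage moves an
    allele by one or two motifs).
    """

    REQUIRED = ("marker_id", "repeat_motif_bp", "size_min_bp", "size_max_bp",
                "multiplex_group")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise FormatError(f"panel table missing column(s): {', '.join(missing)}")
        table = table.loc[:, list(self.REQUIRED)].copy()
        if table["marker_id"].duplicated().any():
            dups = table.loc[table["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValidationError(f"duplicate marker_id(s) in panel: {dups}")
        motifs = table["repeat_motif_bp"].astype(int)
        bad = ~motifs.isin([2, 3, 4, 5, 6])
        if bad.any():
            raise ValidationError(
                f"repeat_motif_bp must be in 2..6; offending markers: "
                f"{table.loc[bad, 'marker_id'].tolist()}")
        for col in ("size_min_bp", "size_max_bp"):
            table[col] = table[col].astype(float)
        if not (table["size_min_bp"] < table["size_max_bp"]).all():
            raise ValidationError("size_min_bp must be < size_max_bp for every marker")
        table["repeat_motif_bp"] = motifs
        self.table = table.reset_index(drop=True)
        self.motif_map: dict[str, int] = dict(
            zip(self.table["marker_id"], self.table["repeat_motif_bp"]))
        self._range = {
            m: (lo, hi) for m, lo, hi in zip(
                self.table["marker_id"], self.table["size_min_bp"],
                self.table["size_max_bp"])}

    @classmethod
    def from_file(cls, path) -> "MarkerPanel":
        return cls(_read_delimited(path))

    def to_file(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker_id"])

    def motif(self, marker_id: str) -> int:
        return self.motif_map[marker_id]

    def size_range(self, marker_id: str) -> tuple[float, float]:
        return self._range[marker_id]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.motif_map

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PeakTableDiagnostics:
    """Row-level accounting for a peak-table read."""
    n_rows_read: int = 0
    n_peaks: int = 0
    unknown_markers: list[tuple[int, str]] = field(default_factory=list)
    out_of_range: list[tuple[int, str, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _read_delimited(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited UTF-8 text file (auto-detected)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
        if not head.strip():
            raise FormatError(f"{path}: empty file (no header)")
        sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     encoding="utf-8", skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    return df


def read_panel(path) -> MarkerPanel:
    return MarkerPanel.from_file(path)


def read_peak_table(path, panel: MarkerPanel
                    ) -> tuple[pd.DataFrame, PeakTableDiagnostics]:
    """Read a fragment-analysis peak export (long or wide dialect).

    Returns the long-format peak table and a diagnostics report.  Rows
    naming markers absent from the panel, or alleles outside the marker's
    size range, are kept but reported.  A negative peak height is a
    hard validation error (it can only be a corrupted export).
    """
    raw = _read_delimited(path)
    cols = set(raw.columns)
    diagnostics = PeakTableDiagnostics(n_rows_read=len(raw))

    if {"allele_size_bp", "height_rfu"} <= cols:
        dialect = "long"
        required = ["sample_id", "marker_id", "allele_size_bp", "height_rfu"]
    elif "allele1" in cols:
        dialect = "wide"
        required = ["sample_id", "marker_id", "allele1", "height1"]
    else:
        dialect = "long"
        required = ["sample_id", "marker_id", "allele_size_bp", "height_rfu"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}")

    if dialect == "long":
        out = raw.loc[:, ["sample_id", "marker_id", "allele_size_bp",
                          "height_rfu"]].copy()
        out["_row"] = np.arange(2, len(out) + 2)  # 1-based incl. header
    else:
        pairs = [("allele1", "height1"), ("allele2", "height2"),
                 ("allele3", "height3")]
        frames = []
        for a_col, h_col in pairs:
            if a_col not in cols:
                continue
            if h_col not in cols:
                raise FormatError(f"{path}: missing mandatory column(s): {h_col}")
            sub = raw.loc[:, ["sample_id", "marker_id", a_col, h_col]].copy()
            sub.columns = ["sample_id", "marker_id", "allele_size_bp",
                           "height_rfu"]
            sub["_row"] = np.arange(2, len(sub) + 2)
            sub = sub[(sub["allele_size_bp"].str.strip() != "")
                      & (sub["height_rfu"].str.strip() != "")]
            frames.append(sub)
        out = pd.concat(frames, ignore_index=True) if frames else raw.iloc[:0]

    if len(out) == 0:
        diagnostics.warnings.append("no peak rows found")
        logger.warning("%s: no peak rows found", path)
        empty = pd.DataFrame(columns=["sample_id", "marker_id",
                                      "allele_size_bp", "height_rfu"])
        return empty, diagnostics

    for col in ("allele_size_bp", "height_rfu"):
        try:
            out[col] = out[col].astype(float)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric value in {col}: {exc}")

    neg = out["height_rfu"] < 0
    if neg.any():
        row = int(out.loc[neg, "_row"].iloc[0])
        raise ValidationError(
            f"{path}: negative height_rfu at row {row}")

    known = out["marker_id"].isin(panel.marker_ids)
    for _, r in out.loc[~known].iterrows():
        diagnostics.unknown_markers.append((int(r["_row"]), r["marker_id"]))
    for _, r in out.loc[known].iterrows():
        lo, hi = panel.size_range(r["marker_id"])
        if not (lo <= r["allele_size_bp"] <= hi):
            diagnostics.out_of_range.append(
                (int(r["_row"]), r["marker_id"], float(r["allele_size_bp"])))
    if diagnostics.unknown_markers:
        logger.warning("%s: %d peak(s) at markers absent from the panel",
                       path, len(diagnostics.unknown_markers))

    out = out.drop(columns="_row").reset_index(drop=True)
    diagnostics.n_peaks = len(out)
    return out, diagnostics


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def _parse_alleles(text: str) -> tuple[float, ...]:
    parts = [p for p in str(text).replace(",", ";").split(";") if p.strip()]
    return tuple(float(p) for p in parts)


def _locuscall_from_row(sample: str, marker: str, alleles: str, copies: str
                        ) -> LocusCall:
    allele_tuple = _parse_alleles(alleles)
    copies = str(copies).strip()
    if copies in ("", "-", "NA"):
        copy_tuple = None
    else:
        copy_tuple = tuple(int(float(c)) for c in copies.split(";") if c.strip())
        if len(copy_tuple) != len(allele_tuple):
            raise ValidationError(
                f"sample {sample}, marker {marker}: {len(allele_tuple)} allele(s) "
                f"but {len(copy_tuple)} copy number(s)")
    if copy_tuple is not None:
        somy = int(sum(copy_tuple))
        config = configuration_from_copies(copy_tuple)
    else:
        somy = None
        config = "homozygous" if len(allele_tuple) == 1 else "unresolved"
    return LocusCall(sample_id=sample, marker_id=marker, alleles=allele_tuple,
                     copy_numbers=copy_tuple, somy=somy, configuration=config)


def read_genotype_table(path) -> dict[str, dict[str, LocusCall]]:
    """Read a genotype table into sample_id -> (marker_id -> LocusCall).

    Copy numbers are optional: without them somy stays unknown (the paper's
    homozygous-marker case, where dosage cannot be determined).
    """
    df = _read_delimited(path)
    required = ["sample_id", "marker_id", "alleles"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}")
    has_copies = "copy_numbers" in df.columns
    out: dict[str, dict[str, LocusCall]] = {}
    for _, r in df.iterrows():
        if not str(r["alleles"]).strip():
            continue
        call = _locuscall_from_row(
            r["sample_id"], r["marker_id"], r["alleles"],
            r["copy_numbers"] if has_copies else "")
        out.setdefault(r["sample_id"], {})[r["marker_id"]] = call
    return out


def write_genotype_table(genotypes: Mapping[str, Mapping[str, LocusCall]],
                         path) -> None:
    rows = []
    for sample in sorted(genotypes):
        for marker in sorted(genotypes[sample]):
            call = genotypes[sample][marker]
            rows.append({
                "sample_id": sample,
                "marker_id": marker,
                "alleles": ";".join(_fmt(a) for a in call.alleles),
                "copy_numbers": (";".join(str(c) for c in call.copy_numbers)
                                 if call.copy_numbers is not None else "-"),
            })
    pd.DataFrame(rows, columns=["sample_id", "marker_id", "alleles",
                                "copy_numbers"]).to_csv(path, index=False)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


# ---------------------------------------------------------------------------
# metadata and mortality
# ---------------------------------------------------------------------------

def read_sample_meta(path) -> pd.DataFrame:
    """Read and validate sample metadata.

    Unknown treatment/stage/role labels are rejected, never coerced.
    Parents carry no treatment; Experiment 1 offspring carry a replicate_id.
    """
    df = _read_delimited(path)
    required = ["sample_id", "experiment", "stage", "treatment_psi",
                "family_id", "replicate_id", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}")
    df = df.loc[:, required].copy()

    bad = ~df["stage"].isin(STAGES)
    if bad.any():
        raise ValidationError(f"{path}: unknown stage label(s): "
                              f"{sorted(df.loc[bad, 'stage'].unique())}")
    bad = ~df["role"].isin(ROLES)
    if bad.any():
        raise ValidationError(f"{path}: unknown role label(s): "
                              f"{sorted(df.loc[bad, 'role'].unique())}")
    df["experiment"] = df["experiment"].astype(int)
    bad = ~df["experiment"].isin([1, 2])
    if bad.any():
        raise ValidationError(f"{path}: experiment must be 1 or 2")

    is_parent = df["role"].isin(["dam", "sire"])
    treat = df["treatment_psi"].str.strip()
    if (treat[is_parent] != "").any():
        raise ValidationError(f"{path}: parents must not carry a treatment")
    off_treat = treat[~is_parent]
    try:
        vals = off_treat.astype(float)
    except ValueError:
        raise ValidationError(f"{path}: non-numeric treatment_psi")
    bad_vals = ~vals.isin(TREATMENTS_PSI)
    if bad_vals.any():
        raise ValidationError(
            f"{path}: unknown treatment_psi value(s): "
            f"{sorted(vals[bad_vals].unique())}")
    df["treatment_psi"] = pd.array(
        [int(float(t)) if t.strip() else pd.NA for t in df["treatment_psi"]],
        dtype="Int64")

    exp1_off = (df["experiment"] == 1) & (df["role"] == "offspring")
    if (df.loc[exp1_off, "replicate_id"].str.strip() == "").any():
        raise ValidationError(
            f"{path}: Experiment 1 offspring must carry a replicate_id")
    return df


def read_mortality_counts(path) -> pd.DataFrame:
    df = _read_delimited(path)
    required = ["unit_id", "interval", "n_start", "n_dead"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}")
    df = df.loc[:, required].copy()
    bad = ~df["interval"].isin(INTERVALS)
    if bad.any():
        raise ValidationError(f"{path}: unknown interval label(s): "
                              f"{sorted(df.loc[bad, 'interval'].unique())}")
    df["n_start"] = df["n_start"].astype(int)
    df["n_dead"] = df["n_dead"].astype(int)
    if ((df["n_dead"] < 0) | (df["n_dead"] > df["n_start"])).any():
        raise ValidationError(f"{path}: need 0 <= n_dead <= n_start")
    return df


# ---------------------------------------------------------------------------
# result writing and config
# ---------------------------------------------------------------------------

def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write pipeline output tables as delimited text with deterministic
    ordering (stable sort on sample_id when present; fixed column order).

    Re-running on the same inputs produces byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in sorted(tables):
            df = tables[name]
            if "sample_id" in df.columns:
                df = df.sort_values("sample_id", kind="mergesort")
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False, lineterminator="\n",
                      float_format="%.6g")
            written.append(path)
        return written
    except OSError as exc:
        raise OSError(f"cannot write results to {out_dir}: {exc}") from exc


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def dump_config(cfg: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
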