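"""Microsatellite allele-dosage inference from electropherogram peak heights.

The MAC-PR idea (microsatellite DNA allele counting -- peak ratios): at a
heterozygous microsatellite locus the relative heights of the allele peaks
carry copy-number information.  A disomic AB genotype gives two peaks of
roughly equal height; a trisomic AAB (ABB) genotype gives a ~2:1 (~1:2)
height ratio; three distinct peaks force the trisomic ABC configuration.
Homozygous profiles show a single peak whose dosage -- and hence the locus
somy -- cannot be determined by fragment analysis.

This module classifies per-locus peak profiles into allelic configurations,
filters PCR stutter, and screens markers for dosage informativeness.  The
classification core is vectorised over many loci at once; the single-locus
API wraps it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DosageCalibration",
    "LocusCall",
    "classify_locus",
    "classify_matrix",
    "call_loci",
    "filter_stutter",
    "screen_informative_loci",
    "configuration_from_copies",
    "CONFIG_LABELS",
    "CONFIG_CODES",
]

# Configuration codes used by the vectorised core.
CONFIG_LABELS = (
    "no_call",      # 0 - no usable peaks, or too many
    "homozygous",   # 1 - single peak; somy unknown
    "AB",           # 2 - disomic heterozygote, copies 1:1
    "AAB",          # 3 - trisomic, smaller-size allele duplicated (2:1)
    "ABB",          # 4 - trisomic, larger-size allele duplicated (1:2)
    "ABC",          # 5 - trisomic, three distinct alleles
    "unresolved",   # 6 - two peaks, ratio in a guard gap between bands
)
CONFIG_CODES = {label: code for code, label in enumerate(CONFIG_LABELS)}

_SOMY_BY_CODE = np.array([0, 0, 2, 3, 3, 3, 0], dtype=np.int8)  # 0 = unknown

# qc flag bits (vectorised core); string names on LocusCall
FLAG_NO_SIGNAL = 1
FLAG_EXCESS_PEAKS = 2
FLAG_STUTTER_FILTERED = 4
FLAG_UNRESOLVED_RATIO = 8
_FLAG_NAMES = {
    FLAG_NO_SIGNAL: "no_signal",
    FLAG_EXCESS_PEAKS: "excess_peaks",
    FLAG_STUTTER_FILTERED: "stutter_filtered",
    FLAG_UNRESOLVED_RATIO: "unresolved_ratio",
}


@dataclass(frozen=True)
class DosageCalibration:
    """Peak-height-ratio bands mapping a two-peak profile to a configuration.

    The ratio is r = height(smaller-size allele) / height(larger-size allele).
    Theoretical centres are 1 (AB), 2 (AAB) and 0.5 (ABB); the bands leave
    guard gaps in which a call is reported ``unresolved`` rather than guessed.
    Ratios exactly on a band boundary are unresolved (conservative).

    Parameters
    ----------
    balanced_band, two_one_band, one_two_band
        Open intervals (low, high) on r classified as 1:1, 2:1 and 1:2.
    min_peak_height_rfu
        Peaks below this height are ignored.
    max_stutter_fraction
        A peak exactly one repeat motif below a retained peak and below this
        fraction of its height is removed as stutter.
    stutter_correction
        Expected stutter ratio subtracted from a retained peak one motif
        below another retained peak, to undo stutter bleed-through into a
        true allele. 0 disables.
    size_bias_per_bp
        Optional differential-amplification correction: heights are
        multiplied by exp(size_bias_per_bp * (size - min size in profile))
        before ratio computation (shorter fragments amplify more, so a
        positive value boosts longer alleles). Default off.
    """

    balanced_band: tuple[float, float] = (0.75, 1.40)
    two_one_band: tuple[float, float] = (1.60, 2.60)
    one_two_band: tuple[float, float] = (0.38, 0.63)
    min_peak_height_rfu: float = 100.0
    max_stutter_fraction: float = 0.15
    stutter_correction: float = 0.08
    size_bias_per_bp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("one_two_band", "balanced_band", "two_one_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy low < high, got ({lo}, {hi})")
        if not (self.one_two_band[1] < self.balanced_band[0]
                and self.balanced_band[1] < self.two_one_band[0]):
            raise ValueError("ratio bands must be disjoint and ordered "
                             "one_two < balanced < two_one")
        if not 0 < self.max_stutter_fraction < 1:
            raise ValueError("max_stutter_fraction must lie in (0, 1)")
        if self.min_peak_height_rfu < 0:
            raise ValueError("min_peak_height_rfu must be non-negative")

    @classmethod
    def from_dict(cls, d: Mapping) -> "DosageCalibration":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {}
        for key, value in d.items():
            if key not in known:
                raise ValueError(f"unknown calibration field: {key!r}")
            if key.endswith("_band"):
                value = tuple(float(v) for v in value)
            else:
                value = float(value)
            kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "balanced_band": list(self.balanced_band),
            "two_one_band": list(self.two_one_band),
            "one_two_band": list(self.one_two_band),
            "min_peak_height_rfu": self.min_peak_height_rfu,
            "max_stutter_fraction": self.max_stutter_fraction,
            "stutter_correction": self.stutter_correction,
            "size_bias_per_bp": self.size_bias_per_bp,
        }


@dataclass(frozen=True)
class LocusCall:
    """Resolved genotype of one individual at one marker.

    ``copy_numbers`` aligns with ``alleles`` (sorted ascending by size) and,
    when known, sums to ``somy``.  A homozygous profile carries a single
    allele and unknown somy (``None``), because a one-peak profile is
    consistent with any copy number.
    """

    sample_id: str
    marker_id: str
    alleles: tuple[float, ...]
    copy_numbers: tuple[int, ...] | None
    somy: int | None
    configuration: str
    ratio_observed: float | None = None
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.configuration not in CONFIG_CODES:
            raise ValueError(f"unknown configuration {self.configuration!r}")
        if self.copy_numbers is not None:
            if len(self.copy_numbers) != len(self.alleles):
                raise ValueError("copy_numbers must align with alleles")
            if self.somy is not None and sum(self.copy_numbers) != self.somy:
                raise ValueError("copy numbers must sum to somy")

    @property
    def is_resolved_het(self) -> bool:
        """True when the call carries usable somy information."""
        return self.configuration in ("AB", "AAB", "ABB", "ABC")

    @property
    def is_trisomic(self) -> bool:
        return self.configuration in ("AAB", "ABB", "ABC")

    @property
    def is_scored(self) -> bool:
        """Any genotype at all (including homozygous/unresolved)."""
        return self.configuration != "no_call"


def configuration_from_copies(copy_numbers: Sequence[int]) -> str:
    """Label forced by per-allele copy numbers (alleles sorted by size)."""
    key = tuple(copy_numbers)
    table = {(1, 1): "AB", (2, 1): "AAB", (1, 2): "ABB", (1, 1, 1): "ABC"}
    if len(key) == 1:
        return "homozygous"
    return table.get(key, "unresolved")


# ---------------------------------------------------------------------------
# vectorised core
# ---------------------------------------------------------------------------

def classify_matrix(sizes: np.ndarray, heights: np.ndarray,
                    motif_bp: np.ndarray,
                    calibration: DosageCalibration) -> dict[str, np.ndarray]:
    """Classify many peak profiles at once.

    Parameters
    ----------
    sizes, heights
        Arrays of shape (n_profiles, max_peaks); absent peaks are NaN.
    motif_bp
        Repeat-motif length per profile, shape (n_profiles,) (or scalar).

    Returns a dict of per-profile arrays: ``config`` (int codes, see
    CONFIG_CODES), ``somy`` (0 = unknown), ``ratio`` (NaN when undefined),
    ``flags`` (bitmask), ``retained`` (bool peak mask), ``heights``
    (stutter-corrected), and ``order`` (argsort of retained sizes).
    """
    sizes = np.asarray(sizes, dtype=float)
    heights = np.asarray(heights, dtype=float).copy()
    n, p = sizes.shape
    motif = np.broadcast_to(np.asarray(motif_bp, dtype=float), (n,))

    flags = np.zeros(n, dtype=np.uint8)
    valid = (np.isfinite(sizes) & np.isfinite(heights)
             & (heights >= calibration.min_peak_height_rfu))

    # stutter removal relative to retained peaks, iterated to a fixpoint
    diff = sizes[:, None, :] - sizes[:, :, None]          # [n, i, j] = s_j - s_i
    one_below = np.isclose(diff, motif[:, None, None])
    retained = valid.copy()
    for _ in range(p):
        small = heights[:, :, None] < (calibration.max_stutter_fraction
                                       * heights[:, None, :])
        drop = (one_below & small & retained[:, None, :]).any(axis=2) & retained
        if not drop.any():
            break
        retained &= ~drop
    flags |= np.where((valid & ~retained).any(axis=1), FLAG_STUTTER_FILTERED, 0
                      ).astype(np.uint8)

    # subtract expected stutter bleed-through between retained adjacent alleles
    if calibration.stutter_correction > 0:
        pair = one_below & retained[:, :, None] & retained[:, None, :]
        bleed = calibration.stutter_correction * np.where(
            pair, np.nan_to_num(heights)[:, None, :], 0.0).sum(axis=2)
        heights = np.where(retained, np.maximum(heights - bleed, 1.0), heights)

    # optional differential-amplification (size bias) correction
    if calibration.size_bias_per_bp != 0.0:
        any_ret = retained.any(axis=1)
        ref = np.zeros(n)
        if any_ret.any():
            ref[any_ret] = np.min(np.where(retained, sizes, np.inf)[any_ret],
                                  axis=1)
        heights = np.where(
            retained,
            heights * np.exp(calibration.size_bias_per_bp * (sizes - ref[:, None])),
            heights)

    k = retained.sum(axis=1)

    # peak order by size among retained peaks
    sort_sizes = np.where(retained, sizes, np.inf)
    order = np.argsort(sort_sizes, axis=1, kind="stable")
    rows = np.arange(n)
    h0 = heights[rows, order[:, 0]]                       # smallest retained
    h1 = heights[rows, order[:, 1]] if p > 1 else np.full(n, np.nan)

    ratio = np.full(n, np.nan)
    two = k == 2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio[two] = h0[two] / h1[two]

    config = np.zeros(n, dtype=np.int8)
    config[k == 1] = CONFIG_CODES["homozygous"]
    config[k == 3] = CONFIG_CODES["ABC"]
    flags |= np.where(k == 0, FLAG_NO_SIGNAL, 0).astype(np.uint8)
    flags |= np.where(k > 3, FLAG_EXCESS_PEAKS, 0).astype(np.uint8)

    lo, hi = calibration.balanced_band
    config[two & (ratio > lo) & (ratio < hi)] = CONFIG_CODES["AB"]
    lo, hi = calibration.two_one_band
    config[two & (ratio > lo) & (ratio < hi)] = CONFIG_CODES["AAB"]
    lo, hi = calibration.one_two_band
    config[two & (ratio > lo) & (ratio < hi)] = CONFIG_CODES["ABB"]
    unresolved = two & (config == CONFIG_CODES["no_call"])
    config[unresolved] = CONFIG_CODES["unresolved"]
    flags |= np.where(unresolved, FLAG_UNRESOLVED_RATIO, 0).astype(np.uint8)

    return {
        "config": config,
        "somy": _SOMY_BY_CODE[config],
        "ratio": ratio,
        "flags": flags,
        "retained": retained,
        "heights": heights,
        "order": order,
    }


_COPIES_BY_CODE: dict[int, tuple[int, ...] | None] = {
    CONFIG_CODES["AB"]: (1, 1),
    CONFIG_CODES["AAB"]: (2, 1),
    CONFIG_CODES["ABB"]: (1, 2),
    CONFIG_CODES["ABC"]: (1, 1, 1),
}


def _flag_names(bits: int) -> frozenset[str]:
    return frozenset(name for bit, name in _FLAG_NAMES.items() if bits & bit)


def classify_locus(peaks: Iterable, calibration: DosageCalibration,
                   motif_bp: int, *, sample_id: str = "", marker_id: str = ""
                   ) -> LocusCall:
    """Classify the peak profile of one sample x marker.

    ``peaks`` is an iterable of (allele_size_bp, height_rfu) pairs or of
    objects with those attributes.
    """
    pairs = []
    for pk in peaks:
        if isinstance(pk, (tuple, list)):
            pairs.append((float(pk[0]), float(pk[1])))
        else:
            pairs.append((float(pk.allele_size_bp), float(pk.height_rfu)))
    width = max(len(pairs), 1)
    sizes = np.full((1, width), np.nan)
    heights = np.full((1, width), np.nan)
    for j, (s, h) in enumerate(pairs):
        sizes[0, j] = s
        heights[0, j] = h
    res = classify_matrix(sizes, heights, motif_bp, calibration)
    code = int(res["config"][0])
    retained = res["retained"][0]
    order = res["order"][0]
    kept = [j for j in order if retained[j]]
    alleles = tuple(sizes[0, j] for j in kept)
    copies = _COPIES_BY_CODE.get(code)
    somy = int(res["somy"][0]) or None
    ratio = float(res["ratio"][0]) if np.isfinite(res["ratio"][0]) else None
    return LocusCall(sample_id=sample_id, marker_id=marker_id,
                     alleles=alleles, copy_numbers=copies, somy=somy,
                     configuration=CONFIG_LABELS[code], ratio_observed=ratio,
                     qc_flags=_flag_names(int(res["flags"][0])))


def filter_stutter(peaks: Sequence[tuple[float, float]], motif_bp: int,
                   max_stutter_fraction: float = 0.15
                   ) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Remove stutter peaks: one motif below a retained peak and below the
    height fraction.  Pure filter; returns (kept, removed)."""
    peaks = [(float(s), float(h)) for s, h in peaks]
    kept = list(peaks)
    removed: list[tuple[float, float]] = []
    changed = True
    while changed:
        changed = False
        for pk in list(kept):
            s, h = pk
            for s2, h2 in kept:
                if np.isclose(s2 - s, motif_bp) and h < max_stutter_fraction * h2:
                    kept.remove(pk)
                    removed.append(pk)
                    changed = True
                    break
            if changed:
                break
    return kept, removed


# ---------------------------------------------------------------------------
# DataFrame interface
# ---------------------------------------------------------------------------

def _motif_lookup(panel) -> Mapping[str, int]:
    if hasattr(panel, "motif_map"):
        return panel.motif_map
    return panel  # assume mapping marker_id -> motif length


def call_loci(peaks: pd.DataFrame, panel, calibration: DosageCalibration
              ) -> pd.DataFrame:
    """Classify every (sample, marker) profile of a long-format peak table.

    ``peaks`` needs columns sample_id, marker_id, allele_size_bp, height_rfu.
    ``panel`` is a MarkerPanel or a mapping marker_id -> repeat motif (bp).

    Returns the locus-call table: one row per sample x marker with columns
    sample_id, marker_id, alleles (';'-joined), copy_numbers, somy (0 when
    unknown), configuration, ratio, qc_flags.
    """
    motifs = _motif_lookup(panel)
    df = peaks.sort_values(["sample_id", "marker_id", "allele_size_bp"],
                           kind="mergesort")
    keys, first = np.unique(
        df[["sample_id", "marker_id"]].astype(str).agg("\x1f".join, axis=1).to_numpy(),
        return_index=True)
    # stable group index per row
    group = np.searchsorted(keys, df[["sample_id", "marker_id"]].astype(str)
                            .agg("\x1f".join, axis=1).to_numpy())
    pos = _cumcount(group)
    width = int(pos.max()) + 1 if len(pos) else 1
    n = len(keys)
    sizes = np.full((n, width), np.nan)
    heights = np.full((n, width), np.nan)
    sizes[group, pos] = df["allele_size_bp"].to_numpy(dtype=float)
    heights[group, pos] = df["height_rfu"].to_numpy(dtype=float)

    samples = np.array([k.split("\x1f")[0] for k in keys])
    markers = np.array([k.split("\x1f")[1] for k in keys])
    motif_arr = np.array([float(motifs.get(m, 4)) for m in markers])

    res = classify_matrix(sizes, heights, motif_arr, calibration)
    codes = res["config"]
    retained = res["retained"]
    order = res["order"]

    allele_strs = []
    copy_strs = []
    for i in range(n):
        kept = [order[i, j] for j in range(width) if retained[i, order[i, j]]]
        al = [sizes[i, j] for j in kept]
        allele_strs.append(";".join(_fmt_size(a) for a in al))
        copies = _COPIES_BY_CODE.get(int(codes[i]))
        copy_strs.append(";".join(str(c) for c in copies) if copies else "")

    return pd.DataFrame({
        "sample_id": samples,
        "marker_id": markers,
        "alleles": allele_strs,
        "copy_numbers": copy_strs,
        "somy": res["somy"].astype(int),
        "configuration": [CONFIG_LABELS[c] for c in codes],
        "ratio": res["ratio"],
        "qc_flags": [";".join(sorted(_flag_names(int(f)))) for f in res["flags"]],
    })


def _cumcount(group: np.ndarray) -> np.ndarray:
    """Position of each element within its (sorted, contiguous) group."""
    if len(group) == 0:
        return np.array([], dtype=int)
    starts = np.r_[0, np.flatnonzero(np.diff(group)) + 1]
    idx = np.arange(len(group))
    return idx - starts[np.searchsorted(starts, idx, side="right") - 1]


def _fmt_size(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


# ---------------------------------------------------------------------------
# informative-locus screening
# ---------------------------------------------------------------------------

def _screen_row(marker_id: str, n_eval: int, n_two: int, n_unres: int,
                n_conflict: int, n_het: int, max_unresolved_fraction: float,
                max_stutter_conflict_rate: float, min_het_calls: int) -> dict:
    frac_unres = n_unres / n_two if n_two else 0.0
    conflict_rate = n_conflict / n_eval if n_eval else 0.0
    flags = []
    informative = True
    if n_het < min_het_calls:
        informative = False
        flags.append("no_heterozygotes")
    if frac_unres > max_unresolved_fraction:
        informative = False
        flags.append("unresolved_excess")
    if conflict_rate > max_stutter_conflict_rate:
        informative = False
        flags.append("stutter_conflicts")
    return {
        "marker_id": marker_id,
        "n_samples_evaluated": n_eval,
        "fraction_unresolved": frac_unres,
        "stutter_conflict_rate": conflict_rate,
        "informative": informative,
        "flags": ";".join(flags),
    }


def screen_from_matrix(config_codes: np.ndarray, flag_codes: np.ndarray,
                       marker_ids: Sequence[str],
                       max_unresolved_fraction: float = 0.25,
                       max_stutter_conflict_rate: float = 0.25,
                       min_het_calls: int = 1) -> pd.DataFrame:
    """Informative-locus screen on (n_samples, n_markers) code matrices
    (fast path; same decision rule as :func:`screen_informative_loci`)."""
    codes = np.asarray(config_codes)
    flags = np.asarray(flag_codes)
    two_codes = [CONFIG_CODES[c] for c in ("AB", "AAB", "ABB", "unresolved")]
    het_codes = [CONFIG_CODES[c] for c in ("AB", "AAB", "ABB", "ABC")]
    fail_codes = [CONFIG_CODES[c] for c in ("unresolved", "no_call")]
    rows = []
    for j, marker in enumerate(marker_ids):
        col = codes[:, j]
        fl = flags[:, j]
        conflict = ((fl & FLAG_STUTTER_FILTERED) > 0) & np.isin(col, fail_codes)
        rows.append(_screen_row(
            marker, len(col), int(np.isin(col, two_codes).sum()),
            int((col == CONFIG_CODES["unresolved"]).sum()),
            int(conflict.sum()), int(np.isin(col, het_codes).sum()),
            max_unresolved_fraction, max_stutter_conflict_rate,
            min_het_calls))
    return pd.DataFrame(rows)


def screen_informative_loci(calls: pd.DataFrame,
                            max_unresolved_fraction: float = 0.25,
                            max_stutter_conflict_rate: float = 0.25,
                            min_het_calls: int = 1) -> pd.DataFrame:
    """Per-marker quality screen for dosage informativeness.

    A marker is informative when, across the cohort, its two-peak calls
    resolve cleanly into the ratio bands.  ``fraction_unresolved`` is the
    share of two-peak profiles falling in the guard gaps;
    ``stutter_conflict_rate`` is the share of calls where stutter filtering
    intervened and the call still failed to resolve.  Markers without any
    heterozygous call carry no dosage information at all.

    Screened-out markers remain usable for family assignment and aberration
    typing; they are only excluded from somy aggregation.
    """
    rows = []
    for marker, g in calls.groupby("marker_id", sort=True):
        two_peak = g["configuration"].isin(["AB", "AAB", "ABB", "unresolved"])
        stutter = g["qc_flags"].str.contains("stutter_filtered", na=False)
        conflict = stutter & g["configuration"].isin(["unresolved", "no_call"])
        n_het = int(g["configuration"].isin(["AB", "AAB", "ABB", "ABC"]).sum())
        rows.append(_screen_row(
            marker, len(g), int(two_peak.sum()),
            int((g["configuration"] == "unresolved").sum()),
            int(conflict.sum()), n_het, max_unresolved_fraction,
            max_stutter_conflict_rate, min_het_calls))
    return pd.DataFrame(rows)
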