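"""Individual-level ploidy classification from per-locus somy calls.

The rule is the study's: over the informative heterozygous markers with
resolved somy, compute the trisomic proportion p; an individual is diploid
when p = 0, triploid when p = 1, and aneuploid when 0 < p < 1.  Individuals
homozygous (or unresolved) at every informative marker are undetermined.
Before classification, individuals with low genotyping success (< 50% of
the informative panel scored) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dosage import CONFIG_CODES, LocusCall

__all__ = [
    "PloidyCall", "CohortFilterReport", "call_ploidy",
    "filter_by_genotyping_success", "degree_of_aneuploidy",
    "call_cohort_ploidy", "ploidy_matrix",
]

PLOIDY_CLASSES = ("undetermined", "diploid", "triploid", "aneuploid")
_CLASS_CODES = {c: i for i, c in enumerate(PLOIDY_CLASSES)}

_HET_CODES = (CONFIG_CODES["AB"], CONFIG_CODES["AAB"],
              CONFIG_CODES["ABB"], CONFIG_CODES["ABC"])
_TRI_CODES = (CONFIG_CODES["AAB"], CONFIG_CODES["ABB"], CONFIG_CODES["ABC"])


@dataclass(frozen=True)
class PloidyCall:
    sample_id: str
    n_scored: int
    n_informative_het: int
    n_trisomic: int
    trisomic_proportion: float          # NaN when undefined
    ploidy_class: str
    aneuploidy_degree: str              # none / single_locus_deviation / intermediate
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class CohortFilterReport:
    threshold: float
    panel_size: int
    n_input: int
    n_retained: int
    n_excluded: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + self.n_excluded:
            raise ValueError("retained + excluded must equal input")


def _classify_counts(n_het: int, n_tri: int) -> tuple[float, str]:
    if n_het == 0:
        return float("nan"), "undetermined"
    p = n_tri / n_het
    if p == 0.0:
        return p, "diploid"
    if p == 1.0:
        return p, "triploid"
    return p, "aneuploid"


def degree_of_aneuploidy(ploidy_call: PloidyCall) -> str:
    """Classify the degree of aneuploidy of an aneuploid individual.

    ``single_locus_deviation``: trisomic at exactly one locus (otherwise
    diploid) or disomic at exactly one locus (otherwise triploid);
    everything else is ``intermediate``.
    """
    if ploidy_call.ploidy_class != "aneuploid":
        raise ValueError("degree of aneuploidy is defined for aneuploids only")
    n_dev = min(ploidy_call.n_trisomic,
                ploidy_call.n_informative_het - ploidy_call.n_trisomic)
    return "single_locus_deviation" if n_dev == 1 else "intermediate"


def call_ploidy(locus_calls: Iterable[LocusCall],
                informative_markers: Sequence[str]) -> PloidyCall:
    """Classify one individual from its locus calls.

    Only markers in ``informative_markers`` contribute to the somy counts;
    markers screened out for dosage remain usable elsewhere (family
    assignment, aberration typing) but not here.
    """
    calls = list(locus_calls)
    if not calls:
        raise ValueError("empty call set: the genotyping-success filter "
                         "should have excluded this individual")
    informative = set(informative_markers)
    sample_id = calls[0].sample_id
    n_scored = sum(1 for c in calls
                   if c.marker_id in informative and c.is_scored)
    het = [c for c in calls if c.marker_id in informative and c.is_resolved_het]
    n_tri = sum(1 for c in het if c.is_trisomic)
    p, cls = _classify_counts(len(het), n_tri)
    flags = set()
    if len(het) == 1:
        flags.add("low_confidence_single_locus")
    pc = PloidyCall(sample_id=sample_id, n_scored=n_scored,
                    n_informative_het=len(het), n_trisomic=n_tri,
                    trisomic_proportion=p, ploidy_class=cls,
                    aneuploidy_degree="none", flags=frozenset(flags))
    if cls == "aneuploid":
        pc = PloidyCall(**{**pc.__dict__, "aneuploidy_degree":
                           degree_of_aneuploidy(pc)})
    return pc


def filter_by_genotyping_success(n_scored: np.ndarray, panel_size: int,
                                 threshold: float = 0.5
                                 ) -> tuple[np.ndarray, CohortFilterReport]:
    """Apply the genotyping-success filter.

    An individual is retained iff n_scored / panel_size >= threshold;
    strictly below the threshold is excluded (the boundary itself is kept,
    reading "< 50%" as strict).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    n_scored = np.asarray(n_scored)
    retained = (n_scored / panel_size) >= threshold
    report = CohortFilterReport(
        threshold=threshold, panel_size=panel_size, n_input=len(n_scored),
        n_retained=int(retained.sum()),
        n_excluded=int((~retained).sum()))
    return retained, report


# ---------------------------------------------------------------------------
# matrix path (shared rule implementation for cohort-scale work)
# ---------------------------------------------------------------------------

def ploidy_matrix(config_codes: np.ndarray, informative_mask: np.ndarray,
                  threshold: float = 0.5) -> dict[str, np.ndarray]:
    """Vectorised ploidy calling over a cohort.

    Parameters
    ----------
    config_codes
        (n_individuals, n_markers) int codes from the dosage caller
        (``dosage.CONFIG_CODES``).
    informative_mask
        (n_markers,) booleans marking the dosage-informative panel.
    threshold
        Genotyping-success threshold over the informative panel.

    Returns per-individual arrays: retained, n_scored, n_informative_het,
    n_trisomic, p, class_code (index into ``PLOIDY_CLASSES``), degree_code
    (0 none, 1 single-locus deviation, 2 intermediate).
    """
    codes = np.asarray(config_codes)
    info = np.asarray(informative_mask, dtype=bool)
    panel_size = int(info.sum())
    sub = codes[:, info]
    scored = sub != CONFIG_CODES["no_call"]
    het = np.isin(sub, _HET_CODES)
    tri = np.isin(sub, _TRI_CODES)
    n_scored = scored.sum(axis=1)
    n_het = het.sum(axis=1)
    n_tri = tri.sum(axis=1)
    retained, report = filter_by_genotyping_success(n_scored, panel_size,
                                                    threshold)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_het > 0, n_tri / np.maximum(n_het, 1), np.nan)
    cls = np.zeros(len(codes), dtype=np.int8)  # undetermined
    cls[(n_het > 0) & (n_tri == 0)] = _CLASS_CODES["diploid"]
    cls[(n_het > 0) & (n_tri == n_het)] = _CLASS_CODES["triploid"]
    cls[(n_tri > 0) & (n_tri < n_het)] = _CLASS_CODES["aneuploid"]
    n_dev = np.minimum(n_tri, n_het - n_tri)
    degree = np.zeros(len(codes), dtype=np.int8)
    aneu = cls == _CLASS_CODES["aneuploid"]
    degree[aneu & (n_dev == 1)] = 1
    degree[aneu & (n_dev > 1)] = 2
    return {
        "retained": retained, "report": report, "n_scored": n_scored,
        "n_informative_het": n_het, "n_trisomic": n_tri, "p": p,
        "class_code": cls, "degree_code": degree,
    }


_DEGREES = ("none", "single_locus_deviation", "intermediate")


def call_cohort_ploidy(calls: pd.DataFrame, informative_markers: Sequence[str],
                       threshold: float = 0.5
                       ) -> tuple[pd.DataFrame, CohortFilterReport]:
    """Ploidy-call a cohort from a locus-call table.

    ``calls`` is the dosage caller's output (columns sample_id, marker_id,
    configuration, ...).  Returns the per-individual ploidy table (excluded
    individuals keep a row, flagged ``excluded_low_success``) and the filter
    report.
    """
    informative = [m for m in informative_markers]
    samples = np.sort(calls["sample_id"].unique())
    sample_idx = {s: i for i, s in enumerate(samples)}
    marker_idx = {m: j for j, m in enumerate(informative)}
    codes = np.zeros((len(samples), len(informative)), dtype=np.int8)
    sub = calls[calls["marker_id"].isin(marker_idx)]
    rows = sub["sample_id"].map(sample_idx).to_numpy()
    cols = sub["marker_id"].map(marker_idx).to_numpy()
    codes[rows, cols] = sub["configuration"].map(CONFIG_CODES).to_numpy()

    res = ploidy_matrix(codes, np.ones(len(informative), dtype=bool),
                        threshold)
    report: CohortFilterReport = res["report"]
    retained = res["retained"]
    out = pd.DataFrame({
        "sample_id": samples,
        "n_scored": res["n_scored"],
        "n_informative_het": res["n_informative_het"],
        "n_trisomic": res["n_trisomic"],
        "trisomic_proportion": res["p"],
        "ploidy_class": [PLOIDY_CLASSES[c] if keep else "excluded"
                         for c, keep in zip(res["class_code"], retained)],
        "aneuploidy_degree": [_DEGREES[d] if keep else "none"
                              for d, keep in zip(res["degree_code"], retained)],
    })
    flags = []
    for keep, n_het in zip(retained, res["n_informative_het"]):
        f = []
        if not keep:
            f.append("excluded_low_success")
        elif n_het == 1:
            f.append("low_confidence_single_locus")
        flags.append(";".join(f))
    out["flags"] = flags
    return out, report
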