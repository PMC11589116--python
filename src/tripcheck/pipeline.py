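"""End-to-end orchestration: simulate/ingest -> dosage -> ploidy ->
assignment -> aberrations -> stats -> report.

Two entry levels:

* :func:`classify_cohort` -- fast array path from a simulated cohort to
  per-individual ploidy calls (used by recovery studies that loop over
  many seeds);
* :func:`run_pipeline` -- the full file-producing run driven by a
  :class:`RunConfig`, writing every stage table plus a reproducibility
  manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .aberrations import (UPD_LOCUS_THRESHOLD, aggregate_aberrations,
                          detect_locus_mismatches)
from .dosage import (DosageCalibration, LocusCall, call_loci,
                     screen_from_matrix, screen_informative_loci,
                     classify_matrix)
from .formats import MarkerPanel, load_config, write_results
from .glm import (BinomialGLM, ModelSpec, RandomInterceptLogit,
                  detect_separation, drop1_aic, mortality_rates)
from .pedigree import ParentPair, assign_cohort
from .ploidy import PLOIDY_CLASSES, ploidy_matrix
from .simulate import SimCohort, SimParams, build_study

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "classify_cohort",
           "summarize_report", "genotypes_from_calls"]


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""
    mode: str = "simulate"               # simulate | ingest
    design: str = "experiment_1"
    seed: int = 0
    out_dir: str = "tripcheck_run"
    # ingest-mode inputs
    peaks_path: str | None = None
    panel_path: str | None = None
    parents_path: str | None = None
    meta_path: str | None = None
    mortality_path: str | None = None
    # thresholds
    success_threshold: float = 0.5
    mismatch_tolerance: int = 1
    upd_locus_threshold: int = UPD_LOCUS_THRESHOLD
    max_unresolved_fraction: float = 0.25
    max_stutter_conflict_rate: float = 0.25
    calibration: dict = field(default_factory=dict)
    sim_params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_dict(load_config(path))


# ---------------------------------------------------------------------------
# fast array path
# ---------------------------------------------------------------------------

def classify_cohort(cohort: SimCohort,
                    calibration: DosageCalibration | None = None,
                    success_threshold: float = 0.5,
                    max_unresolved_fraction: float = 0.25,
                    max_stutter_conflict_rate: float = 0.25) -> dict:
    """Dosage-call, screen and ploidy-call a simulated cohort in one pass.

    Returns a dict with the screen report, the informative-marker mask,
    per-individual arrays from the ploidy caller, and a merged
    per-individual DataFrame (``table``) carrying metadata, truth labels
    and the ploidy call for every genotyped individual.
    """
    calibration = calibration or DosageCalibration()
    gidx = np.flatnonzero(cohort.genotyped)
    L = cohort.params.n_markers
    n = len(gidx)
    sizes = cohort.peak_sizes[gidx].reshape(n * L, 6)
    heights = cohort.peak_heights[gidx].reshape(n * L, 6)
    motifs = np.tile(cohort.model.motifs, n)
    res = classify_matrix(sizes, heights, motifs, calibration)
    config = res["config"].reshape(n, L)
    flags = res["flags"].reshape(n, L)

    screen = screen_from_matrix(
        config, flags, cohort.model.marker_ids,
        max_unresolved_fraction=max_unresolved_fraction,
        max_stutter_conflict_rate=max_stutter_conflict_rate)
    informative = screen["informative"].to_numpy(dtype=bool)

    pl = ploidy_matrix(config, informative, threshold=success_threshold)
    truth = cohort.truth.iloc[gidx].reset_index(drop=True)
    table = truth.copy()
    table["n_scored"] = pl["n_scored"]
    table["n_informative_het"] = pl["n_informative_het"]
    table["n_trisomic"] = pl["n_trisomic"]
    table["trisomic_proportion"] = pl["p"]
    table["retained"] = pl["retained"]
    table["ploidy_class"] = np.where(
        pl["retained"],
        np.asarray(PLOIDY_CLASSES, dtype=object)[pl["class_code"]],
        "excluded")
    degree_labels = np.asarray(
        ["none", "single_locus_deviation", "intermediate"], dtype=object)
    table["aneuploidy_degree"] = degree_labels[pl["degree_code"]]
    return {
        "screen": screen,
        "informative_mask": informative,
        "config_codes": config,
        "classify": res,
        "ploidy": pl,
        "table": table,
        "filter_report": pl["report"],
    }


def genotypes_from_calls(calls: pd.DataFrame,
                         dosage_markers: set[str] | None = None
                         ) -> dict[str, dict[str, LocusCall]]:
    """Per-sample genotype mappings from a locus-call table.

    When ``dosage_markers`` is given, copy numbers are kept only for those
    markers: loci that failed the dosage screen stay usable for family
    assignment and aberration typing, but only through allele presence
    (their inferred dosage is not trustworthy).
    """
    out: dict[str, dict[str, LocusCall]] = {}
    for r in calls.itertuples(index=False):
        if r.configuration == "no_call" or not r.alleles:
            continue
        alleles = tuple(float(a) for a in str(r.alleles).split(";"))
        copies = (tuple(int(c) for c in str(r.copy_numbers).split(";"))
                  if r.copy_numbers else None)
        somy = int(r.somy) if r.somy else None
        config = r.configuration
        if (dosage_markers is not None and r.marker_id not in dosage_markers
                and len(alleles) >= 2):
            copies, somy = None, None
            config = "ABC" if len(alleles) == 3 else "unresolved"
            if config == "ABC":          # three distinct alleles force somy 3
                copies, somy = (1, 1, 1), 3
        call = LocusCall(
            sample_id=r.sample_id, marker_id=r.marker_id, alleles=alleles,
            copy_numbers=copies, somy=somy, configuration=config,
            ratio_observed=None if pd.isna(r.ratio) else float(r.ratio))
        out.setdefault(r.sample_id, {})[r.marker_id] = call
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def summarize_report(ploidy_table: pd.DataFrame,
                     aberration_table: pd.DataFrame | None = None,
                     by: tuple[str, ...] = ("treatment_psi", "stage")
                     ) -> dict[str, pd.DataFrame]:
    """Category-proportion tables per stratum (the structure behind the
    study's ploidy and aberration figures)."""
    df = ploidy_table[ploidy_table["ploidy_class"] != "excluded"]
    counts = (df.groupby([*by, "ploidy_class"], sort=True)
              .size().rename("n").reset_index())
    totals = counts.groupby(list(by))["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    out = {"ploidy_proportions": counts}
    if aberration_table is not None and len(aberration_table):
        ab = aberration_table.merge(
            df[["sample_id", *by]].drop_duplicates("sample_id"),
            on="sample_id", how="left")
        ab_counts = (ab.groupby([*[c for c in by], "type"], dropna=False,
                                sort=True).size().rename("n").reset_index())
        out["aberration_counts"] = ab_counts
    if "true_class" in ploidy_table.columns:
        conf = (df.groupby(["true_class", "ploidy_class"], sort=True)
                .size().rename("n").reset_index())
        out["ploidy_confusion"] = conf
    return out


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def _stats_tables(analysis: pd.DataFrame, experiment: int
                  ) -> dict[str, pd.DataFrame]:
    """Fit the incidence models for both responses, with the separation
    remedy (refit without the offending treatment levels) when needed."""
    tables: dict[str, pd.DataFrame] = {}
    analysis = analysis.copy()
    analysis["triploid"] = (analysis["ploidy_class"] == "triploid").astype(int)
    analysis["aneuploid"] = (analysis["ploidy_class"] == "aneuploid").astype(int)
    analysis["treatment_psi"] = analysis["treatment_psi"].astype(str)
    fixed = ("treatment_psi", "family_id", "stage")
    fixed = tuple(f for f in fixed if analysis[f].nunique() > 1)

    for response in ("triploid", "aneuploid"):
        spec = ModelSpec(response=response, fixed_effects=fixed,
                         ref_levels={"treatment_psi": "0", "family_id": "1"})
        if experiment == 1:
            analysis["unit"] = (analysis["treatment_psi"].astype(str) + "_"
                                + analysis["replicate_id"].astype(str))
            spec = ModelSpec(response=response, fixed_effects=fixed,
                             random_intercept_group="unit",
                             ref_levels=spec.ref_levels)
            model = RandomInterceptLogit(analysis, spec)
        else:
            model = BinomialGLM(analysis, spec)
        fit = model.fit()
        tables[f"model_{response}"] = fit.to_frame()
        tables[f"drop1_{response}"] = drop1_aic(model)
        if fit.separation_flag:
            drop = {}
            for factor, level, _ in fit.offending_levels:
                drop.setdefault(factor, []).append(level)
            remedied = model.refit_without_levels(drop).fit()
            tables[f"model_{response}_no_separation"] = remedied.to_frame()
    return tables


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the stage tables plus a run manifest.

    Returns a dict with the in-memory tables and the output paths.
    Stage outputs are written as each stage completes, so a late failure
    does not corrupt earlier outputs.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calibration = DosageCalibration.from_dict(config.calibration) \
        if config.calibration else DosageCalibration()

    if config.mode == "simulate":
        params = SimParams(**config.sim_params) if config.sim_params \
            else SimParams()
        cohort = build_study(config.design, params, seed=config.seed)
        panel = cohort.panel
        peaks = cohort.peak_table()
        meta = cohort.meta_table()
        mortality = cohort.mortality
        parent_pairs = cohort.parent_pairs()
        truth = cohort.truth
        logger.info("simulated %s: %s", config.design, cohort.design_ledger)
    elif config.mode == "ingest":
        from .formats import (read_genotype_table, read_mortality_counts,
                              read_panel, read_peak_table, read_sample_meta)
        panel = read_panel(config.panel_path)
        peaks, diag = read_peak_table(config.peaks_path, panel)
        meta = read_sample_meta(config.meta_path)
        mortality = (read_mortality_counts(config.mortality_path)
                     if config.mortality_path else None)
        parent_geno = read_genotype_table(config.parents_path)
        parent_meta = meta[meta["role"].isin(["dam", "sire"])]
        sires = parent_meta.loc[parent_meta["role"] == "sire", "sample_id"]
        if len(sires) != 1:
            raise ValueError("expected exactly one sire in the metadata")
        sire_geno = {m: c.alleles for m, c in
                     parent_geno[sires.iloc[0]].items()}
        parent_pairs = []
        for r in parent_meta[parent_meta["role"] == "dam"].itertuples():
            dam_geno = {m: c.alleles for m, c in
                        parent_geno[r.sample_id].items()}
            parent_pairs.append(ParentPair(family_id=str(r.family_id),
                                           dam=dam_geno, sire=sire_geno))
        cohort = None
        truth = None
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # ---- dosage ----------------------------------------------------------
    calls = call_loci(peaks, panel, calibration)
    screen = screen_informative_loci(
        calls, max_unresolved_fraction=config.max_unresolved_fraction,
        max_stutter_conflict_rate=config.max_stutter_conflict_rate)
    informative = screen.loc[screen["informative"], "marker_id"].tolist()
    write_results({"locus_calls": calls, "locus_screen": screen}, out_dir)
    logger.info("dosage: %d calls, %d/%d informative markers",
                len(calls), len(informative), len(screen))

    # ---- ploidy ----------------------------------------------------------
    from .ploidy import call_cohort_ploidy
    ploidy_df, filter_report = call_cohort_ploidy(
        calls, informative, threshold=config.success_threshold)
    ploidy_df = ploidy_df.merge(meta, on="sample_id", how="left")
    if truth is not None:
        ploidy_df = ploidy_df.merge(
            truth[["sample_id", "true_class", "viability_category"]],
            on="sample_id", how="left")
    write_results({"ploidy": ploidy_df}, out_dir)

    # ---- family assignment ----------------------------------------------
    genotypes = genotypes_from_calls(calls, dosage_markers=set(informative))
    classes = dict(zip(ploidy_df["sample_id"], ploidy_df["ploidy_class"]))
    offspring_ids = set(meta.loc[meta["role"] == "offspring", "sample_id"])
    off_genos = {s: g for s, g in genotypes.items() if s in offspring_ids}
    results = assign_cohort(off_genos, classes, parent_pairs,
                            mismatch_tolerance=config.mismatch_tolerance,
                            motif_by_marker=panel.motif_map)
    known_family = dict(zip(meta["sample_id"], meta["family_id"]))
    assign_df = pd.DataFrame([{
        "sample_id": r.sample_id,
        "assigned_family": r.assigned_family or "",
        "status": r.status,
        "min_mismatches": min(r.mismatches.values()),
        "excused_loci": ";".join(r.excused_loci),
        "known_family": known_family.get(r.sample_id, ""),
        "agrees_with_known": (r.assigned_family == known_family.get(
            r.sample_id) if r.assigned_family else False),
        "flags": ";".join(sorted(r.flags)),
    } for r in results])
    write_results({"assignments": assign_df}, out_dir)

    # ---- aberration typing ----------------------------------------------
    pair_by_family = {p.family_id: p for p in parent_pairs}
    events = []
    finding_rows = []
    for sample_id, geno in off_genos.items():
        fam = known_family.get(sample_id) or ""
        if fam not in pair_by_family:
            res = next(r for r in results if r.sample_id == sample_id)
            fam = res.assigned_family or ""
        pair = pair_by_family.get(str(fam))
        if pair is None:
            continue
        context = classes.get(sample_id, "unknown")
        findings = {}
        for marker, call in geno.items():
            dam = pair.dam.get(marker)
            sire = pair.sire.get(marker)
            if not dam or not sire:
                continue
            findings[marker] = detect_locus_mismatches(
                call, dam, sire, panel.motif(marker), context)
        for marker, f in findings.items():
            if f not in ("ok", "skipped"):
                finding_rows.append({"sample_id": sample_id,
                                     "marker_id": marker, "finding": f})
        events.extend(aggregate_aberrations(
            sample_id, findings, geno, (pair.dam, pair.sire),
            upd_locus_threshold=config.upd_locus_threshold))
    aberr_df = pd.DataFrame([{
        "sample_id": e.sample_id, "type": e.type, "n_loci": len(e.loci),
        "loci": ";".join(e.loci), "detail": e.detail,
        "flags": ";".join(sorted(e.flags)),
    } for e in events], columns=["sample_id", "type", "n_loci", "loci",
                                 "detail", "flags"])
    write_results({"aberrations": aberr_df,
                   "locus_findings": pd.DataFrame(
                       finding_rows, columns=["sample_id", "marker_id",
                                              "finding"])}, out_dir)

    # ---- statistics ------------------------------------------------------
    experiment = int(meta["experiment"].iloc[0])
    analysis = ploidy_df[(ploidy_df["ploidy_class"]
                          .isin(["diploid", "triploid", "aneuploid"]))
                         & (ploidy_df["role"] == "offspring")].copy()
    stats_tables = {}
    try:
        stats_tables = _stats_tables(analysis, experiment)
        write_results(stats_tables, out_dir)
    except Exception:
        logger.exception("stats stage failed; earlier outputs are intact")
        raise

    # ---- mortality & report ---------------------------------------------
    tables = {}
    if mortality is not None and len(mortality):
        by = [c for c in ("treatment_psi",) if c in mortality.columns]
        tables["mortality_rates"] = mortality_rates(mortality, by=by or None)
    tables.update(summarize_report(
        ploidy_df, aberr_df if len(aberr_df) else None))
    write_results(tables, out_dir)

    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "n_calls": int(len(calls)),
        "filter_report": {
            "threshold": filter_report.threshold,
            "panel_size": filter_report.panel_size,
            "n_input": filter_report.n_input,
            "n_retained": filter_report.n_retained,
            "n_excluded": filter_report.n_excluded,
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "calls": calls, "screen": screen, "ploidy": ploidy_df,
        "assignments": assign_df, "aberrations": aberr_df,
        "stats": stats_tables, "report": tables, "manifest": manifest,
        "out_dir": out_dir, "cohort": cohort,
    }
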