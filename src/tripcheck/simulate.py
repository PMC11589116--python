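"""Forward simulation of the half-sib, pressure-gradient study design.

The generator produces cohorts with the statistical structure the analysis
assumes, keeping full latent truth for recovery testing:

* 12 dams crossed with one shared sire (half-sib families), each offspring
  receiving one maternal and one paternal gamete per (unlinked) marker;
* hydrostatic pressure retains the second polar body with a probability
  that rises logistically in PSI, duplicating the maternal set (triploidy);
* a treatment-disruption channel, strongest at intermediate pressures
  (4 r (1-r) shape in the retention probability r), that makes polar-body
  retention partial -- some loci gain or lose the extra maternal copy
  (aneuploidy) and occasionally lose the maternal contribution entirely
  (maternal-missing / UPD-like patterns);
* spontaneous, family-specific nondisjunction adding an extra maternal or
  paternal copy (paternal-extra only without a retention event, matching
  the observation that double-paternal trisomies appear only at low
  pressures);
* rare whole-genome events: androgenesis (maternal set absent) and
  multi-locus uniparental-disomy blocks;
* repeat-slippage mutations moving one inherited allele by 1-2 motifs;
* peak synthesis with per-allele lognormal height noise and stutter; and
* viability selection that purges aberrant individuals between the eyed-egg
  and parr stages, with mortality concentrated in the eyed-egg ->
  start-feeding interval.

A single global seed spawns per-stage substreams, so seeded runs are
bit-reproducible and stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .dosage import CONFIG_CODES
from .formats import INTERVALS, MarkerPanel

__all__ = [
    "SimParams", "SimCohort", "retention_probability", "simulate_parents",
    "simulate_offspring", "synthesize_peaks", "apply_viability_selection",
    "build_study", "simulate_logistic_groups", "DEFAULT_FAMILY_RATES",
]

#: per-locus spontaneous nondisjunction probability per family (12 dams);
#: families 1-3 (used in the five-treatment experiment) get
#: 0.010 / 0.008 / 0.003 so that family 3 shows the fewest aneuploids.
DEFAULT_FAMILY_RATES = (0.010, 0.008, 0.003, 0.006, 0.004, 0.012,
                        0.005, 0.007, 0.004, 0.006, 0.014, 0.011)

#: survival probability per stage interval (fertilization->eyed egg,
#: eyed egg->start feed, start feed->parr) by latent viability category.
DEFAULT_SURVIVAL = {
    "baseline": (0.975, 0.965, 0.960),
    "single_locus": (0.950, 0.700, 0.850),
    "intermediate": (0.800, 0.250, 0.550),
    "maternal_loss": (0.700, 0.100, 0.500),
}

_MOTIF_CYCLE = (4, 2, 4, 3, 2, 4)


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; the defaults are the study conditions."""

    n_dams: int = 12
    n_markers: int = 30
    n_informative: int = 20          # low-noise, dosage-informative markers
    n_alleles_range: tuple[int, int] = (4, 8)

    # logistic second-polar-body retention curve in PSI
    retention_midpoint_psi: float = 7500.0
    retention_scale_psi: float = 400.0

    # treatment-disruption channel (partial polar-body retention/loss),
    # probability disruption_max * 4 r (1 - r); per-locus gain/loss rate
    disruption_max: float = 0.35
    disruption_locus_rate: float = 0.15
    maternal_missing_given_disruption: float = 0.10
    maternal_missing_mean_loci: float = 1.5   # 1 + Poisson(mean) loci lost

    family_nondisjunction_rates: tuple[float, ...] = DEFAULT_FAMILY_RATES
    upd_rate: float = 0.004
    upd_block_range: tuple[int, int] = (5, 9)  # inclusive bounds, all > 3
    androgenesis_rate: float = 0.002
    slippage_rate: float = 0.025               # per individual, ~2-3%
    pb_heterozygous_retention: float = 0.5     # P(PB copy != egg copy | het dam)

    base_height_rfu: float = 1500.0
    noise_sd: float = 0.05                     # lognormal sd per allele peak
    noise_sd_uninformative: float = 0.35
    stutter_fraction: float = 0.08

    survival: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SURVIVAL))

    def __post_init__(self) -> None:
        probs = [self.disruption_max, self.disruption_locus_rate,
                 self.maternal_missing_given_disruption, self.upd_rate,
                 self.androgenesis_rate, self.slippage_rate,
                 self.pb_heterozygous_retention, self.stutter_fraction]
        probs += [r for r in self.family_nondisjunction_rates]
        probs += [s for v in self.survival.values() for s in v]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.upd_block_range[0] <= 3:
            raise ValueError("UPD blocks must span more than 3 loci")
        if not 0 < self.n_informative <= self.n_markers:
            raise ValueError("need 0 < n_informative <= n_markers")


def retention_probability(pressure_psi, params: SimParams) -> np.ndarray:
    """Probability of second-polar-body retention, logistic in PSI and
    monotone non-decreasing."""
    psi = np.asarray(pressure_psi, dtype=float)
    return expit((psi - params.retention_midpoint_psi)
                 / params.retention_scale_psi)


# ---------------------------------------------------------------------------
# marker model and parents
# ---------------------------------------------------------------------------

@dataclass
class MarkerModel:
    """Allele ladders and frequencies for a simulated panel."""
    marker_ids: list[str]
    motifs: np.ndarray                 # (L,)
    ladders: list[np.ndarray]          # allele sizes per marker
    freqs: list[np.ndarray]
    noise_sd: np.ndarray               # (L,) per-marker peak noise

    def to_panel(self) -> MarkerPanel:
        rows = []
        for i, m in enumerate(self.marker_ids):
            lad = self.ladders[i]
            rows.append({
                "marker_id": m,
                "repeat_motif_bp": int(self.motifs[i]),
                "size_min_bp": float(lad.min() - 3 * self.motifs[i]),
                "size_max_bp": float(lad.max() + 3 * self.motifs[i]),
                "multiplex_group": f"MP{i % 5 + 1}",
            })
        return MarkerPanel(pd.DataFrame(rows))


def build_marker_model(params: SimParams, rng: np.random.Generator
                       ) -> MarkerModel:
    L = params.n_markers
    marker_ids = [f"M{i + 1:02d}" for i in range(L)]
    motifs = np.array([_MOTIF_CYCLE[i % len(_MOTIF_CYCLE)] for i in range(L)])
    ladders, freqs = [], []
    lo, hi = params.n_alleles_range
    for i in range(L):
        n_alleles = int(rng.integers(lo, hi + 1))
        start = 90 + 12 * i
        gaps = rng.integers(1, 4, size=n_alleles - 1)
        sizes = start + motifs[i] * np.r_[0, np.cumsum(gaps)]
        ladders.append(sizes.astype(float))
        f = rng.dirichlet(np.full(n_alleles, 1.5))
        freqs.append(f)
    noise = np.full(L, params.noise_sd_uninformative)
    noise[:params.n_informative] = params.noise_sd
    return MarkerModel(marker_ids, motifs.astype(float), ladders, freqs, noise)


def simulate_parents(params: SimParams, rng: np.random.Generator,
                     model: MarkerModel | None = None
                     ) -> dict:
    """Draw diploid parents (one sire + n_dams dams) from the per-marker
    allele-frequency model."""
    if model is None:
        model = build_marker_model(params, rng)
    L = params.n_markers
    n_par = params.n_dams + 1
    genos = np.empty((n_par, L, 2))
    for i in range(L):
        lad, f = model.ladders[i], model.freqs[i]
        if len(lad) < 2:
            import warnings
            warnings.warn(f"marker {model.marker_ids[i]} has < 2 alleles "
                          "and will be uninformative")
        draws = rng.choice(len(lad), size=(n_par, 2), p=f)
        genos[:, i, :] = lad[draws]
    genos.sort(axis=2)
    return {"model": model, "dams": genos[:params.n_dams],
            "sire": genos[params.n_dams]}


# ---------------------------------------------------------------------------
# offspring (latent truth)
# ---------------------------------------------------------------------------

# latent copy slots
SLOT_MATERNAL = 0       # egg pronucleus copy
SLOT_PATERNAL = 1       # sperm copy
SLOT_MATERNAL_EXTRA = 2  # retained polar-body copy / maternal extra
SLOT_PATERNAL_EXTRA = 3  # paternal extra (spontaneous only)


def simulate_offspring(dam_geno: np.ndarray, sire_geno: np.ndarray,
                       pressure_psi: float, params: SimParams,
                       rng: np.random.Generator, n: int = 1,
                       family_rate: float | None = None,
                       motifs: np.ndarray | None = None) -> dict:
    """Simulate latent offspring of one dam x sire cross at one pressure.

    Returns a dict with ``sizes`` (n, L, 4) allele sizes (NaN = copy
    absent; slots: maternal, paternal, maternal-extra, paternal-extra) and
    per-individual truth labels.
    """
    L = dam_geno.shape[0]
    ar = np.arange(L)
    if family_rate is None:
        family_rate = params.family_nondisjunction_rates[0]
    r = float(retention_probability(pressure_psi, params))
    retained = rng.random(n) < r

    dam_pick = rng.integers(0, 2, (n, L))
    m1 = dam_geno[ar, dam_pick]
    other = dam_geno[ar, 1 - dam_pick]
    pat = sire_geno[ar, rng.integers(0, 2, (n, L))]
    pb = np.where(rng.random((n, L)) < params.pb_heterozygous_retention,
                  other, m1)

    sizes = np.full((n, L, 4), np.nan)
    sizes[:, :, SLOT_MATERNAL] = m1
    sizes[:, :, SLOT_PATERNAL] = pat
    sizes[retained, :, SLOT_MATERNAL_EXTRA] = pb[retained]

    # treatment-disruption channel: partial polar-body retention/loss
    d_prob = params.disruption_max * 4.0 * r * (1.0 - r)
    disrupted = rng.random(n) < d_prob
    locus_hit = rng.random((n, L)) < params.disruption_locus_rate
    lose = disrupted[:, None] & retained[:, None] & locus_hit
    sizes[:, :, SLOT_MATERNAL_EXTRA] = np.where(
        lose, np.nan, sizes[:, :, SLOT_MATERNAL_EXTRA])
    gain = disrupted[:, None] & ~retained[:, None] & locus_hit
    sizes[:, :, SLOT_MATERNAL_EXTRA] = np.where(
        gain, pb, sizes[:, :, SLOT_MATERNAL_EXTRA])

    treatment_maternal_loss = np.zeros((n, L), dtype=bool)
    mm_draw = disrupted & (rng.random(n)
                           < params.maternal_missing_given_disruption)
    for i in np.flatnonzero(mm_draw):
        k = 1 + int(rng.poisson(params.maternal_missing_mean_loci))
        loci = rng.choice(L, size=min(k, L), replace=False)
        treatment_maternal_loss[i, loci] = True
    sizes[:, :, SLOT_MATERNAL] = np.where(
        treatment_maternal_loss, np.nan, sizes[:, :, SLOT_MATERNAL])
    sizes[:, :, SLOT_MATERNAL_EXTRA] = np.where(
        treatment_maternal_loss, np.nan, sizes[:, :, SLOT_MATERNAL_EXTRA])

    # spontaneous nondisjunction (family-specific rate per locus)
    nd = rng.random((n, L)) < family_rate
    # triploid template: the unstable retained-PB copy is lost
    nd_lose = nd & retained[:, None] & np.isfinite(
        sizes[:, :, SLOT_MATERNAL_EXTRA])
    sizes[:, :, SLOT_MATERNAL_EXTRA] = np.where(
        nd_lose, np.nan, sizes[:, :, SLOT_MATERNAL_EXTRA])
    # diploid template: gain an extra copy; paternal origin only possible
    # without a retention event
    free_slot2 = ~np.isfinite(sizes[:, :, SLOT_MATERNAL_EXTRA])
    nd_gain = nd & ~retained[:, None] & free_slot2 & ~treatment_maternal_loss
    maternal_origin = rng.random((n, L)) < 0.5
    extra_m = np.where(rng.random((n, L)) < 0.5, m1, other)
    sire_other = sire_geno[ar, rng.integers(0, 2, (n, L))]
    sizes[:, :, SLOT_MATERNAL_EXTRA] = np.where(
        nd_gain & maternal_origin, extra_m, sizes[:, :, SLOT_MATERNAL_EXTRA])
    sizes[:, :, SLOT_PATERNAL_EXTRA] = np.where(
        nd_gain & ~maternal_origin, sire_other, np.nan)

    # whole-genome events
    upd = rng.random(n) < params.upd_rate
    upd_loci = np.zeros((n, L), dtype=bool)
    lo, hi = params.upd_block_range
    for i in np.flatnonzero(upd):
        k = int(rng.integers(lo, hi + 1))
        upd_loci[i, rng.choice(L, size=min(k, L), replace=False)] = True
    andro = rng.random(n) < params.androgenesis_rate
    maternal_gone = upd_loci | andro[:, None]
    for slot in (SLOT_MATERNAL, SLOT_MATERNAL_EXTRA):
        sizes[:, :, slot] = np.where(maternal_gone, np.nan, sizes[:, :, slot])

    # repeat slippage: one allele copy moves by 1-2 motifs
    slip = rng.random(n) < params.slippage_rate
    slip_locus = np.full(n, -1)
    for i in np.flatnonzero(slip):
        present = np.argwhere(np.isfinite(sizes[i]))
        if len(present) == 0:
            continue
        loc, slot = present[rng.integers(len(present))]
        steps = 1 if rng.random() < 0.8 else 2
        sign = 1 if rng.random() < 0.5 else -1
        motif = motifs[loc] if motifs is not None else 4.0
        sizes[i, loc, slot] += sign * steps * motif
        slip_locus[i] = loc

    copies = np.isfinite(sizes).sum(axis=2)
    maternal_present = (np.isfinite(sizes[:, :, SLOT_MATERNAL])
                        | np.isfinite(sizes[:, :, SLOT_MATERNAL_EXTRA]))
    template = np.where(retained, 3, 2)
    n_deviant = (copies != template[:, None]).sum(axis=1)

    return {
        "sizes": sizes,
        "retained": retained,
        "disrupted": disrupted,
        "upd": upd,
        "upd_loci": upd_loci,
        "androgenesis": andro,
        "treatment_maternal_loss": treatment_maternal_loss,
        "maternal_missing_count": (~maternal_present).sum(axis=1),
        "slip_locus": slip_locus,
        "copies": copies,
        "n_deviant_loci": n_deviant,
    }


def viability_category(latent: dict) -> np.ndarray:
    """Latent viability category per individual (array of labels)."""
    n = len(latent["retained"])
    cat = np.full(n, "baseline", dtype=object)
    dev = latent["n_deviant_loci"]
    cat[dev == 1] = "single_locus"
    cat[dev >= 2] = "intermediate"
    mm = (latent["maternal_missing_count"] > 0)
    cat[mm | latent["upd"] | latent["androgenesis"]] = "maternal_loss"
    return cat


def true_class(latent: dict) -> np.ndarray:
    """Latent ploidy label implied by per-locus copy counts."""
    copies = latent["copies"]
    all3 = (copies == 3).all(axis=1)
    all2 = (copies == 2).all(axis=1)
    out = np.full(len(copies), "aneuploid", dtype=object)
    out[all2] = "diploid"
    out[all3] = "triploid"
    return out


# ---------------------------------------------------------------------------
# peak synthesis (the generative inverse of the dosage caller)
# ---------------------------------------------------------------------------

def synthesize_peaks(sizes: np.ndarray, motifs: np.ndarray,
                     noise_sd: np.ndarray, params: SimParams,
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Observed peaks from latent allele copies.

    Identical alleles merge their copies into one peak; per allele peak,
    height = base_height x copy_number x lognormal(0, sd); an optional
    stutter peak sits one motif below each allele at the stutter fraction
    (merging into a real allele's peak when they coincide).

    Returns (peak_sizes, peak_heights), shape (n, L, 6), NaN-padded.
    """
    n, L, _ = sizes.shape
    order = np.argsort(np.where(np.isfinite(sizes), sizes, np.inf), axis=2)
    s = np.take_along_axis(sizes, order, axis=2)

    out_sizes = np.full((n, L, 6), np.nan)
    out_heights = np.full((n, L, 6), np.nan)

    # unique alleles + copy counts among the (<=4) sorted slots
    uniq = np.full((n, L, 3), np.nan)
    counts = np.zeros((n, L, 3), dtype=np.int8)
    ui = np.full((n, L), -1, dtype=np.int8)
    for j in range(s.shape[2]):
        fin = np.isfinite(s[:, :, j])
        is_new = fin & ((j == 0) | (s[:, :, j] != s[:, :, j - 1 if j else 0]))
        ui = np.where(is_new, ui + 1, ui)
        for u in range(3):
            sel = fin & (ui == u)
            uniq[:, :, u] = np.where(sel & is_new, s[:, :, j], uniq[:, :, u])
            counts[:, :, u] = counts[:, :, u] + sel.astype(np.int8)

    # lognormal with per-marker sd: draw standard normals and scale
    z = rng.standard_normal((n, L, 3))
    noise = np.exp(z * noise_sd[None, :, None])
    heights = params.base_height_rfu * counts * noise
    heights = np.where(counts > 0, heights, np.nan)
    out_sizes[:, :, :3] = uniq
    out_heights[:, :, :3] = heights

    if params.stutter_fraction > 0:
        for u in range(3):
            st_size = uniq[:, :, u] - motifs[None, :]
            st_h = params.stutter_fraction * heights[:, :, u]
            placed = np.zeros((n, L), dtype=bool)
            for v in range(3):
                merge = np.isfinite(uniq[:, :, v]) & np.isclose(
                    uniq[:, :, v], st_size) & ~placed
                out_heights[:, :, v] = np.where(
                    merge, out_heights[:, :, v] + st_h, out_heights[:, :, v])
                placed |= merge
            new = np.isfinite(st_size) & ~placed & (st_h > 0)
            out_sizes[:, :, 3 + u] = np.where(new, st_size, np.nan)
            out_heights[:, :, 3 + u] = np.where(new, st_h, np.nan)

    return out_sizes, out_heights


# ---------------------------------------------------------------------------
# viability selection
# ---------------------------------------------------------------------------

def apply_viability_selection(categories: np.ndarray, params: SimParams,
                              rng: np.random.Generator
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Draw survival per individual through the three stage intervals.

    Returns (alive, death_interval): ``alive`` is True for parr-stage
    survivors; ``death_interval`` holds the interval index (0-2) of death
    or -1.
    """
    n = len(categories)
    surv = np.empty((n, 3))
    for cat, probs in params.survival.items():
        mask = categories == cat
        surv[mask] = probs
    u = rng.random((n, 3))
    dies = u >= surv
    death_interval = np.where(dies.any(axis=1), dies.argmax(axis=1), -1)
    return death_interval == -1, death_interval


# ---------------------------------------------------------------------------
# study builder
# ---------------------------------------------------------------------------

EXPERIMENT_DESIGNS = {
    "experiment_1": {
        "experiment": 1,
        "families": (0, 1, 2),
        "treatments": (0, 6500, 7500, 8500, 9500),
        "replicates": ("A", "B"),
        "n_sampled_eggs": 15,
        "n_reared": 100,
    },
    "experiment_2": {
        "experiment": 2,
        "families": tuple(range(12)),
        "treatments": (0, 9500),
        "replicates": (None,),
        "n_sampled_eggs": 20,
        "n_reared": 100,
    },
}


@dataclass
class SimCohort:
    """A simulated study: latent truth, observed peaks, metadata, ledger."""
    design: str
    seed: int
    params: SimParams
    model: MarkerModel
    panel: MarkerPanel
    dams: np.ndarray                    # (n_dams, L, 2)
    sire: np.ndarray                    # (L, 2)
    truth: pd.DataFrame                 # one row per individual
    latent_sizes: np.ndarray            # (N, L, 4)
    peak_sizes: np.ndarray              # (N, L, 6), NaN where not genotyped
    peak_heights: np.ndarray
    mortality: pd.DataFrame
    design_ledger: dict

    @property
    def genotyped(self) -> np.ndarray:
        return self.truth["genotyped"].to_numpy(dtype=bool)

    def meta_table(self) -> pd.DataFrame:
        t = self.truth
        meta = pd.DataFrame({
            "sample_id": t["sample_id"],
            "experiment": t["experiment"],
            "stage": t["stage"],
            "treatment_psi": t["treatment_psi"],
            "family_id": t["family_id"],
            "replicate_id": t["replicate_id"],
            "role": "offspring",
        })
        return meta[self.genotyped].reset_index(drop=True)

    def peak_table(self) -> pd.DataFrame:
        """Long-format peak table of the genotyped individuals."""
        idx = np.flatnonzero(self.genotyped)
        n_idx, L = len(idx), self.params.n_markers
        ps = self.peak_sizes[idx].reshape(n_idx, L, 6)
        ph = self.peak_heights[idx].reshape(n_idx, L, 6)
        fin = np.isfinite(ps) & np.isfinite(ph)
        ii, ll, pp = np.nonzero(fin)
        samples = self.truth["sample_id"].to_numpy()[idx]
        return pd.DataFrame({
            "sample_id": samples[ii],
            "marker_id": np.asarray(self.model.marker_ids)[ll],
            "allele_size_bp": ps[ii, ll, pp],
            "height_rfu": ph[ii, ll, pp],
        })

    def family_ids(self) -> list[str]:
        return [str(f + 1) for f in range(self.params.n_dams)]

    def parent_genotype(self, which: str, index: int = 0
                        ) -> dict[str, tuple[float, ...]]:
        geno = self.sire if which == "sire" else self.dams[index]
        return {m: tuple(sorted(set(geno[i])))
                for i, m in enumerate(self.model.marker_ids)}

    def parent_pairs(self):
        from .pedigree import ParentPair
        sire = self.parent_genotype("sire")
        fams = EXPERIMENT_DESIGNS[self.design]["families"]
        return [ParentPair(family_id=str(f + 1),
                           dam=self.parent_genotype("dam", f), sire=sire)
                for f in fams]


def build_study(design: str, params: SimParams | None = None,
                seed: int = 0) -> SimCohort:
    """Simulate a full experiment with the printed sampling ledger.

    Experiment 1: 3 families x 5 treatments x 2 replicates, 15 sampled
    eyed eggs and 100 reared individuals per family-treatment-replicate
    (450 sampled eggs, 3000 reared).  Experiment 2: 12 families x 2
    treatments, 20 sampled eggs and 100 reared per family-treatment unit
    (480 sampled eggs, 2400 juveniles).
    """
    if design not in EXPERIMENT_DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of "
                         f"{sorted(EXPERIMENT_DESIGNS)}")
    d = EXPERIMENT_DESIGNS[design]
    params = params or SimParams()
    ss = np.random.SeedSequence(seed)
    rng_parents, rng_off, rng_peaks, rng_via = (
        np.random.default_rng(c) for c in ss.spawn(4))

    parents = simulate_parents(params, rng_parents)
    model: MarkerModel = parents["model"]

    blocks = []
    rows = []
    counter = 0
    for fam in d["families"]:
        fam_rate = params.family_nondisjunction_rates[
            fam % len(params.family_nondisjunction_rates)]
        for psi in d["treatments"]:
            for rep in d["replicates"]:
                n_unit = d["n_sampled_eggs"] + d["n_reared"]
                latent = simulate_offspring(
                    parents["dams"][fam], parents["sire"], psi, params,
                    rng_off, n=n_unit, family_rate=fam_rate,
                    motifs=model.motifs)
                cats = viability_category(latent)
                tclass = true_class(latent)
                sampled = np.zeros(n_unit, dtype=bool)
                sampled[:d["n_sampled_eggs"]] = True
                for i in range(n_unit):
                    counter += 1
                    rows.append({
                        "sample_id": f"X{d['experiment']}-{counter:05d}",
                        "experiment": d["experiment"],
                        "family_id": str(fam + 1),
                        "treatment_psi": psi,
                        "replicate_id": rep if rep is not None else "",
                        "sampled_egg": bool(sampled[i]),
                        "retention": bool(latent["retained"][i]),
                        "disrupted": bool(latent["disrupted"][i]),
                        "upd": bool(latent["upd"][i]),
                        "androgenesis": bool(latent["androgenesis"][i]),
                        "maternal_missing_loci":
                            int(latent["maternal_missing_count"][i]),
                        "n_deviant_loci": int(latent["n_deviant_loci"][i]),
                        "slip_locus": int(latent["slip_locus"][i]),
                        "viability_category": cats[i],
                        "true_class": tclass[i],
                    })
                blocks.append(latent["sizes"])
    truth = pd.DataFrame(rows)
    latent_sizes = np.concatenate(blocks, axis=0)
    N = len(truth)

    # viability selection on the reared individuals
    reared = ~truth["sampled_egg"].to_numpy()
    cats = truth["viability_category"].to_numpy(dtype=object)
    alive = np.zeros(N, dtype=bool)
    death = np.full(N, -1)
    alive_r, death_r = apply_viability_selection(cats[reared], params, rng_via)
    alive[reared] = alive_r
    death[reared] = death_r

    truth["stage"] = np.where(truth["sampled_egg"], "egg",
                              np.where(alive, "parr", "dead"))
    truth["death_interval"] = death
    truth["genotyped"] = truth["sampled_egg"].to_numpy() | alive

    # mortality accounting per treatment/family/replicate unit
    mort_rows = []
    for (psi, fam, rep), g in truth[reared].groupby(
            ["treatment_psi", "family_id", "replicate_id"], sort=True):
        n_alive = len(g)
        for k, interval in enumerate(INTERVALS):
            n_dead = int((g["death_interval"] == k).sum())
            mort_rows.append({
                "unit_id": f"{psi}_{fam}_{rep}" if rep else f"{psi}_{fam}",
                "treatment_psi": psi, "family_id": fam, "replicate_id": rep,
                "interval": interval, "n_start": n_alive, "n_dead": n_dead,
            })
            n_alive -= n_dead
    mortality = pd.DataFrame(mort_rows)

    # observed peaks for genotyped individuals
    peak_sizes = np.full((N, params.n_markers, 6), np.nan)
    peak_heights = np.full((N, params.n_markers, 6), np.nan)
    gidx = np.flatnonzero(truth["genotyped"].to_numpy())
    ps, ph = synthesize_peaks(latent_sizes[gidx], model.motifs,
                              model.noise_sd, params, rng_peaks)
    peak_sizes[gidx] = ps
    peak_heights[gidx] = ph

    ledger = {
        "n_sampled_eggs": int(truth["sampled_egg"].sum()),
        "n_reared": int(reared.sum()),
        "n_parr_survivors": int(alive.sum()),
        "n_genotyped": int(truth["genotyped"].sum()),
        "n_units": len(d["families"]) * len(d["treatments"])
        * len(d["replicates"]),
    }
    return SimCohort(design=design, seed=seed, params=params, model=model,
                     panel=model.to_panel(), dams=parents["dams"],
                     sire=parents["sire"], truth=truth,
                     latent_sizes=latent_sizes, peak_sizes=peak_sizes,
                     peak_heights=peak_heights, mortality=mortality,
                     design_ledger=ledger)


# ---------------------------------------------------------------------------
# grouped logistic data for the mixed-model recovery tests
# ---------------------------------------------------------------------------

def simulate_logistic_groups(n_groups: int, n_per_group: int,
                             intercept: float, effect: float,
                             group_sd: float, rng: np.random.Generator
                             ) -> pd.DataFrame:
    """Bernoulli data with one two-level covariate and Gaussian group
    intercepts -- the recovery target for the random-intercept logit."""
    u = rng.normal(0.0, group_sd, size=n_groups)
    rows = []
    for g in range(n_groups):
        x = rng.integers(0, 2, size=n_per_group)
        eta = intercept + effect * x + u[g]
        y = rng.random(n_per_group) < expit(eta)
        rows.append(pd.DataFrame({
            "y": y.astype(int), "x": np.where(x == 1, "b", "a"),
            "group": f"g{g:02d}"}))
    return pd.concat(rows, ignore_index=True)
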