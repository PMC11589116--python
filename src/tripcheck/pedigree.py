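"""Exclusion-based family assignment for half-sib diploid/triploid cohorts.

Offspring are compared against every candidate (dam, sire) pair and
excluded from families whose gametes cannot produce the observed genotype.
The half-sib design (many dams, one shared sire) means discrimination comes
entirely from the dams.  Triploid offspring from second-polar-body
retention carry two maternal copies and one paternal copy per locus, and
the compatibility rule respects that: two dam alleles (any pair from the
dam's two, with dosage consistency when copy numbers are resolved) plus one
sire allele.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

from .dosage import LocusCall

__all__ = ["ParentPair", "AssignmentResult", "locus_compatible",
           "assign_family", "assign_cohort", "explain_genotype"]


@dataclass(frozen=True)
class ParentPair:
    """One family's parents: marker -> allele sizes (parents are diploid)."""
    family_id: str
    dam: Mapping[str, tuple[float, ...]]
    sire: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for label, geno in (("dam", self.dam), ("sire", self.sire)):
            for marker, alleles in geno.items():
                if not 1 <= len(alleles) <= 2:
                    raise ValueError(
                        f"{label} genotype at {marker} must carry 1-2 alleles "
                        f"(parents are diploid), got {alleles}")


@dataclass(frozen=True)
class AssignmentResult:
    sample_id: str
    mismatches: Mapping[str, int]       # family_id -> incompatible locus count
    assigned_family: str | None
    status: str                          # unique / ambiguous_tie / unassigned
    excused_loci: tuple[str, ...] = ()   # bp-shift candidates not counted
    flags: frozenset[str] = frozenset()


def _offspring_multiset(call: LocusCall) -> Counter | None:
    """Allele multiset expanded by copy numbers; None when dosage unknown."""
    if not call.alleles:
        return None
    if call.copy_numbers is None:
        return None
    return Counter(dict(zip(call.alleles, call.copy_numbers)))


def explain_genotype(call: LocusCall, dam: Sequence[float],
                     sire: Sequence[float], ploidy_context: str) -> bool:
    """True when some standard dam x sire gamete combination produces the
    observed genotype under the given ploidy context."""
    dam = tuple(dam)
    sire = tuple(sire)
    alleles = set(call.alleles)
    ms = _offspring_multiset(call)
    if ploidy_context == "diploid":
        if ms is not None:
            return any(Counter([d, s]) == ms for d in dam for s in sire)
        # dosage unknown: allele presence must match a one-from-each draw
        return any(alleles == {d, s} for d in dam for s in sire)
    if ploidy_context == "triploid":
        if ms is not None:
            return any(Counter([d1, d2, s]) == ms
                       for d1, d2 in combinations_with_replacement(dam, 2)
                       for s in sire)
        return any(alleles == {d1, d2, s}
                   for d1, d2 in combinations_with_replacement(dam, 2)
                   for s in sire)
    # aneuploid / unknown context: presence-based
    return alleles <= set(dam) | set(sire)


def locus_compatible(call: LocusCall, dam: Sequence[float],
                     sire: Sequence[float], ploidy_context: str = "unknown"
                     ) -> str:
    """Classify one locus as compatible / incompatible / uninformative
    with a candidate parent pair under the offspring's ploidy context."""
    if not call.alleles or not call.is_scored:
        return "uninformative"
    if ploidy_context not in ("diploid", "triploid"):
        ploidy_context = "unknown"
    return ("compatible"
            if explain_genotype(call, dam, sire, ploidy_context)
            else "incompatible")


def shift_variants(call: LocusCall, motif: float, targets=None):
    """All genotypes obtained by moving one observed allele by +-1 or +-2
    repeat motifs (the slippage hypothesis).  A shift landing on another
    observed allele merges with it, pooling copy numbers.  ``targets``
    restricts which observed alleles may be treated as mutant (typically
    the alleles absent from both parents)."""
    from .dosage import configuration_from_copies
    if targets is None:
        targets = call.alleles
    for target in targets:
        for k in (-2, -1, 1, 2):
            new = target + k * motif
            if call.copy_numbers is not None:
                cnt: Counter = Counter()
                for al, c in zip(call.alleles, call.copy_numbers):
                    cnt[new if al == target else al] += c
                alleles = tuple(sorted(cnt))
                copies = tuple(int(cnt[a]) for a in alleles)
                somy = call.somy
                config = configuration_from_copies(copies)
            else:
                alleles = tuple(sorted({new if al == target else al
                                        for al in call.alleles}))
                copies, somy = None, None
                config = "homozygous" if len(alleles) == 1 else "unresolved"
            yield LocusCall(sample_id=call.sample_id,
                            marker_id=call.marker_id, alleles=alleles,
                            copy_numbers=copies, somy=somy,
                            configuration=config)


def _shift_explains(call: LocusCall, dam: Sequence[float],
                    sire: Sequence[float], context: str, motif: float) -> bool:
    """Would a single slippage of a non-parental observed allele make the
    genotype compatible?"""
    ctx = context if context in ("diploid", "triploid") else "unknown"
    novel = [a for a in call.alleles if a not in dam and a not in sire]
    return any(explain_genotype(trial, dam, sire, ctx)
               for trial in shift_variants(call, motif, targets=novel))


def assign_family(sample_id: str,
                  genotype: Mapping[str, LocusCall],
                  ploidy_class: str,
                  parent_pairs: Sequence[ParentPair],
                  mismatch_tolerance: int = 1,
                  motif_by_marker: Mapping[str, int] | None = None
                  ) -> AssignmentResult:
    """Assign one offspring to a family by exclusion.

    Incompatible loci are counted per family; loci whose incompatibility is
    explainable by a single +-1-2-motif slippage are excused (up to the
    tolerance) and reported.  The offspring is assigned only when exactly
    one family lies within the tolerance; two or more candidate families
    leave it ambiguous, none leaves it unassigned.
    """
    if not parent_pairs:
        raise ValueError("at least one parent pair is required")
    scored = {m: c for m, c in genotype.items() if c.is_scored and c.alleles}
    if not scored:
        raise ValueError(f"{sample_id}: zero scored loci")
    context = ploidy_class if ploidy_class in ("diploid", "triploid") else "unknown"

    mismatches: dict[str, int] = {}
    excused: dict[str, list[str]] = {}
    for pair in parent_pairs:
        n_bad = 0
        exc: list[str] = []
        for marker, call in scored.items():
            dam = pair.dam.get(marker)
            sire = pair.sire.get(marker)
            if not dam or not sire:
                continue
            verdict = locus_compatible(call, dam, sire, context)
            if verdict != "incompatible":
                continue
            motif = (motif_by_marker or {}).get(marker)
            if (motif and len(exc) < mismatch_tolerance
                    and _shift_explains(call, dam, sire, context, motif)):
                exc.append(marker)
            else:
                n_bad += 1
        mismatches[pair.family_id] = n_bad
        excused[pair.family_id] = exc

    candidates = [f for f, n in mismatches.items() if n <= mismatch_tolerance]
    flags = set()
    if len(candidates) == 1:
        fam = candidates[0]
        status, assigned = "unique", fam
    elif len(candidates) >= 2:
        status, assigned, fam = "ambiguous_tie", None, None
    else:
        status, assigned, fam = "unassigned", None, None

    # an offspring matching its family only through sire-side alleles is
    # suspicious in a half-sib design (possible absence of maternal DNA)
    if assigned is not None:
        pair = next(p for p in parent_pairs if p.family_id == assigned)
        maternal_evidence = 0
        for marker, call in scored.items():
            dam = pair.dam.get(marker, ())
            sire = pair.sire.get(marker, ())
            if any(a in dam and a not in sire for a in call.alleles):
                maternal_evidence += 1
        if maternal_evidence == 0:
            flags.add("questionable_no_maternal_evidence")

    return AssignmentResult(
        sample_id=sample_id, mismatches=mismatches, assigned_family=assigned,
        status=status,
        excused_loci=tuple(excused[fam]) if fam else (),
        flags=frozenset(flags))


def assign_cohort(genotypes: Mapping[str, Mapping[str, LocusCall]],
                  ploidy_classes: Mapping[str, str],
                  parent_pairs: Sequence[ParentPair],
                  mismatch_tolerance: int = 1,
                  motif_by_marker: Mapping[str, int] | None = None
                  ) -> list[AssignmentResult]:
    results = []
    for sample_id in sorted(genotypes):
        results.append(assign_family(
            sample_id, genotypes[sample_id],
            ploidy_classes.get(sample_id, "unknown"), parent_pairs,
            mismatch_tolerance, motif_by_marker))
    return results
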