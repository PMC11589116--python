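"""Typing of inheritance aberrations from parent-offspring comparisons.

Offspring genotypes are evaluated against their assigned dam and sire at
every scored locus.  Findings are per-locus; per-individual events collapse
them into the study's aberration types:

* ``missing_maternal_few``   - maternal allele absent at 1-3 loci
* ``missing_maternal_multi`` - maternal allele absent at >3 loci
  (uniparental disomy pattern; a whole-genome variant is flagged
  ``total_maternal_absence``)
* ``missing_paternal``       - the mirror case (not observed in the study,
  detected for generality)
* ``double_paternal_trisomy``- a trisomic locus with two allele copies
  attributable only to the sire, inconsistent with polar-body retention
* ``bp_shift``               - an allele offset from a parental allele by
  exactly one or two repeat motifs (slippage)

A locus where at least one standard dam x sire gamete combination explains
the observed call is never reported as aberrant; shared parental alleles
yield ``ambiguous`` rather than a false positive.  Slippage is the
preferred explanation over a missing parent at a single locus, because
repeat slippage is common and benign.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .dosage import LocusCall
from .pedigree import explain_genotype, shift_variants

__all__ = ["AberrationEvent", "detect_locus_mismatches",
           "aggregate_aberrations", "classify_extra_allele_origin",
           "UPD_LOCUS_THRESHOLD"]

#: loci lacking the maternal allele beyond this count collapse into one
#: multi-locus (UPD-pattern) event
UPD_LOCUS_THRESHOLD = 3

FINDINGS = ("ok", "ambiguous", "maternal_allele_missing",
            "paternal_allele_missing", "double_paternal",
            "bp_shift_candidate", "incompatible", "skipped")


@dataclass(frozen=True)
class AberrationEvent:
    sample_id: str
    type: str
    loci: tuple[str, ...]
    detail: str = ""
    flags: frozenset[str] = frozenset()


def _subset_of(call: LocusCall, parent: Sequence[float]) -> bool:
    return set(call.alleles) <= set(parent)


def _one_dam_two_sire(call: LocusCall, dam: Sequence[float],
                      sire: Sequence[float]) -> bool:
    """Trisomic genotype formable as one dam allele + two sire alleles."""
    ms = Counter(dict(zip(call.alleles, call.copy_numbers))) \
        if call.copy_numbers is not None else None
    if ms is None:
        return False
    from itertools import combinations_with_replacement
    return any(Counter([d, s1, s2]) == ms
               for d in dam
               for s1, s2 in combinations_with_replacement(tuple(sire), 2))




def detect_locus_mismatches(call: LocusCall, dam: Sequence[float],
                            sire: Sequence[float], motif_bp: float,
                            ploidy_context: str = "unknown") -> str:
    """Classify one offspring locus against the parents.

    Returns one of ``FINDINGS``.  The decision enumerates gamete
    explanations: a normal explanation wins unless an aberrant explanation
    coexists, in which case the locus is ambiguous (never a false
    positive).
    """
    if not call.alleles or not call.is_scored:
        return "skipped"
    dam = tuple(dam)
    sire = tuple(sire)

    def explains_normally(c: LocusCall) -> bool:
        # A locus with resolved somy is judged by its own somy: a trisomic
        # locus must satisfy the two-maternal + one-paternal expectation
        # even inside an otherwise-diploid (aneuploid) individual.  With
        # somy unknown, any standard diploid or triploid gamete
        # combination counts as a normal explanation (conservative).
        if c.somy == 2:
            return explain_genotype(c, dam, sire, "diploid")
        if c.somy == 3:
            return explain_genotype(c, dam, sire, "triploid")
        if ploidy_context in ("diploid", "triploid"):
            return explain_genotype(c, dam, sire, ploidy_context)
        return (explain_genotype(c, dam, sire, "diploid")
                or explain_genotype(c, dam, sire, "triploid"))

    normal = explains_normally(call)
    maternal_missing = _subset_of(call, sire)   # formable without the dam
    paternal_missing = _subset_of(call, dam)
    double_pat = (call.somy == 3 and call.copy_numbers is not None
                  and _one_dam_two_sire(call, dam, sire)
                  and not explain_genotype(call, dam, sire, "triploid"))

    if normal:
        if maternal_missing or paternal_missing:
            return "ambiguous"
        return "ok"

    if double_pat:
        return "double_paternal"

    # Slippage is preferred over a missing-parent explanation, but only a
    # novel allele (absent from both parents) can be the mutant copy: a
    # profile made entirely of parental alleles carries no slippage
    # evidence and falls through to the missing-parent patterns.
    novel = [a for a in call.alleles if a not in dam and a not in sire]
    if any(explains_normally(trial)
           for trial in shift_variants(call, motif_bp, targets=novel)):
        return "bp_shift_candidate"

    if maternal_missing and paternal_missing:
        return "ambiguous"
    if maternal_missing:
        return "maternal_allele_missing"
    if paternal_missing:
        return "paternal_allele_missing"
    return "incompatible"


def classify_extra_allele_origin(call: LocusCall, dam: Sequence[float],
                                 sire: Sequence[float]
                                 ) -> tuple[str, frozenset[str]]:
    """Resolve which parent supplied the duplicated copy of a trisomic call.

    Enumerates decompositions (one dam gamete + one sire gamete + one extra
    copy); if decompositions disagree about the extra copy's source, or the
    extra allele is shared by both parents, the origin is ambiguous.
    """
    if call.somy != 3 or call.copy_numbers is None:
        return "ambiguous", frozenset({"unresolved_copy_numbers"})
    ms = Counter(dict(zip(call.alleles, call.copy_numbers)))
    origins = set()
    for d in dam:
        for s in sire:
            for extra in set(call.alleles):
                if Counter([d, s, extra]) != ms:
                    continue
                in_dam, in_sire = extra in dam, extra in sire
                if in_dam and in_sire:
                    origins.add("ambiguous")
                elif in_dam:
                    origins.add("maternal")
                elif in_sire:
                    origins.add("paternal")
    if len(origins) == 1:
        return origins.pop(), frozenset()
    return "ambiguous", frozenset()


def aggregate_aberrations(sample_id: str, findings: Mapping[str, str],
                          genotype: Mapping[str, LocusCall] | None = None,
                          parents: tuple[Mapping, Mapping] | None = None,
                          upd_locus_threshold: int = UPD_LOCUS_THRESHOLD
                          ) -> list[AberrationEvent]:
    """Collapse per-locus findings into typed events for one individual.

    Maternal-missing findings at more than ``upd_locus_threshold`` loci
    become a single multi-locus (UPD-pattern) event, otherwise a few-loci
    event.  ``total_maternal_absence`` is flagged when no scored locus
    shows unambiguous maternal inheritance (a dam-specific allele) --
    the pattern of androgenetic or whole-genome maternal-DNA loss.
    Different event types may coexist on one individual.
    """
    by_type: dict[str, list[str]] = {}
    for marker in sorted(findings):
        by_type.setdefault(findings[marker], []).append(marker)

    events: list[AberrationEvent] = []

    mat = by_type.get("maternal_allele_missing", [])
    if mat:
        flags = set()
        if genotype is not None and parents is not None:
            dam_geno, sire_geno = parents
            evidence = 0
            for marker, call in genotype.items():
                dam = tuple(dam_geno.get(marker, ()))
                sire = tuple(sire_geno.get(marker, ()))
                if any(a in dam and a not in sire for a in call.alleles):
                    evidence += 1
            if evidence == 0:
                flags.add("total_maternal_absence")
        etype = ("missing_maternal_multi" if len(mat) > upd_locus_threshold
                 else "missing_maternal_few")
        events.append(AberrationEvent(
            sample_id=sample_id, type=etype, loci=tuple(mat),
            detail=f"maternal allele absent at {len(mat)} locus/loci",
            flags=frozenset(flags)))

    pat = by_type.get("paternal_allele_missing", [])
    if pat:
        events.append(AberrationEvent(
            sample_id=sample_id, type="missing_paternal", loci=tuple(pat),
            detail=f"paternal allele absent at {len(pat)} locus/loci"))

    dp = by_type.get("double_paternal", [])
    if dp:
        events.append(AberrationEvent(
            sample_id=sample_id, type="double_paternal_trisomy",
            loci=tuple(dp),
            detail="two paternal allele copies at a trisomic locus"))

    bp = by_type.get("bp_shift_candidate", [])
    if bp:
        events.append(AberrationEvent(
            sample_id=sample_id, type="bp_shift", loci=tuple(bp),
            detail="allele offset by 1-2 repeat motifs from a parental allele"))

    inc = by_type.get("incompatible", [])
    if inc:
        events.append(AberrationEvent(
            sample_id=sample_id, type="extra_allele_ambiguous_origin",
            loci=tuple(inc),
            detail="genotype not explainable by any gamete combination"))

    return events
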