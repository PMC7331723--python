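"""Autosomal-recessive co-segregation checking and control screening.

Under a fully penetrant autosomal recessive model every affected
individual is homozygous for the candidate allele, no unaffected
individual is, and every unaffected parent of an affected child is an
obligate heterozygous carrier.  The checker also flags plain Mendelian
errors (a child's genotype impossible given both typed parents).
Missing genotypes impose no constraint — matching clinical practice in
partially typed families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .pedigree import Pedigree
from .vcfio import HET, HOM_ALT, HOM_REF, MISSING

#: Violation reason codes.
AFFECTED_NOT_HOMALT = "affected_not_homalt"
UNAFFECTED_HOMALT = "unaffected_homalt"
OBLIGATE_CARRIER_NOT_HET = "obligate_carrier_not_het"
MENDELIAN_ERROR = "mendelian_error"

#: Alleles a parent with the given genotype can transmit.
_TRANSMISSIBLE = {HOM_REF: (0,), HET: (0, 1), HOM_ALT: (1,)}


@dataclass
class SegregationResult:
    violations: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.violations

    def reasons(self) -> set[str]:
        return {reason for _, _, reason in self.violations}


def check_ar_segregation(
    pedigree: Pedigree, genotypes: Mapping[str, int]
) -> SegregationResult:
    """Check candidate genotypes against fully penetrant AR transmission.

    ``genotypes`` maps individual id to a genotype code (0/1/2, or -1 for
    missing).  Individuals absent from the mapping, or typed as missing,
    constrain nothing.  Raises ``KeyError`` for a typed individual that
    is not in the pedigree.
    """
    for iid in genotypes:
        if iid not in pedigree:
            raise KeyError(f"typed individual {iid!r} absent from pedigree")

    def typed(iid: str) -> int | None:
        g = genotypes.get(iid, MISSING)
        return None if g == MISSING else int(g)

    result = SegregationResult()
    obligate_parents = {
        parent
        for aff in pedigree.affected_ids()
        for parent in (pedigree.parents(aff) or ())
    }
    for iid in pedigree.ids:
        g = typed(iid)
        if g is None:
            continue
        ind = pedigree[iid]
        if ind.affected is True and g != HOM_ALT:
            result.violations.append((iid, g, AFFECTED_NOT_HOMALT))
        if ind.affected is not True and g == HOM_ALT:
            result.violations.append((iid, g, UNAFFECTED_HOMALT))
        if (
            iid in obligate_parents
            and ind.affected is not True
            and g != HET
        ):
            result.violations.append((iid, g, OBLIGATE_CARRIER_NOT_HET))
        parents = pedigree.parents(iid)
        if parents is not None:
            gf, gm = typed(parents[0]), typed(parents[1])
            if gf is not None and gm is not None:
                possible = {
                    a + b
                    for a in _TRANSMISSIBLE[gf]
                    for b in _TRANSMISSIBLE[gm]
                }
                if g not in possible:
                    result.violations.append((iid, g, MENDELIAN_ERROR))
    return result


def screen_controls(control_genotypes: Iterable[int]) -> tuple[int, int]:
    """Tabulate (heterozygous carriers, homozygotes) in a control cohort."""
    n_het = n_hom = 0
    for g in control_genotypes:
        if g == HET:
            n_het += 1
        elif g == HOM_ALT:
            n_hom += 1
    return n_het, n_hom
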