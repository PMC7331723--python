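"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by exhaustive enumeration, sharing
no code with the implementations they check.
"""

from __future__ import annotations

import numpy as np

from autozyg.pedigree import Pedigree
from autozyg.vcfio import HET, HOM_ALT, HOM_REF, MISSING


def brute_force_maximal_runs(calls, min_snps, max_het):
    """All maximal homozygous spans by O(n²) enumeration.

    A span is a pair of indices (a, b) into the non-missing subsequence
    with at least ``min_snps`` calls and at most ``max_het`` het calls; it
    is maximal when neither one-step extension still qualifies.  Returned
    as (start, end, n_het) in original array indices, sorted.
    """
    calls = list(calls)
    keep = [i for i, c in enumerate(calls) if c != MISSING]
    comp = [calls[i] for i in keep]
    n = len(comp)
    het_prefix = np.concatenate(
        [[0], np.cumsum([1 if c == HET else 0 for c in comp])]
    )

    def hets(a, b):  # inclusive
        return int(het_prefix[b + 1] - het_prefix[a])

    out = []
    for a in range(n):
        for b in range(a, n):
            if b - a + 1 < min_snps or hets(a, b) > max_het:
                continue
            left_ext = a > 0 and hets(a - 1, b) <= max_het
            right_ext = b < n - 1 and hets(a, b + 1) <= max_het
            if not left_ext and not right_ext:
                out.append((keep[a], keep[b], hets(a, b)))
    return sorted(set(out))


def brute_force_ar_check(pedigree: Pedigree, genotypes: dict[str, int]):
    """Rule-by-rule AR co-segregation check via explicit allele enumeration.

    Returns a sorted list of (individual, reason) violation pairs.
    """
    typed = {
        i: g for i, g in genotypes.items() if g != MISSING
    }
    violations = []
    for iid, g in typed.items():
        ind = pedigree[iid]
        if ind.affected is True and g != HOM_ALT:
            violations.append((iid, "affected_not_homalt"))
        if ind.affected is not True and g == HOM_ALT:
            violations.append((iid, "unaffected_homalt"))
    # obligate carriers: unaffected typed parents of an affected child
    for iid in pedigree.ids:
        if pedigree[iid].affected is not True:
            continue
        for parent in pedigree.parents(iid) or ():
            if (
                parent in typed
                and pedigree[parent].affected is not True
                and typed[parent] != HET
            ):
                violations.append((parent, "obligate_carrier_not_het"))
    # Mendelian: enumerate transmissible allele pairs
    alleles = {HOM_REF: [0], HET: [0, 1], HOM_ALT: [1]}
    for iid, g in typed.items():
        parents = pedigree.parents(iid)
        if parents is None:
            continue
        pf, pm = parents
        if pf in typed and pm in typed:
            possible = {
                a + b for a in alleles[typed[pf]] for b in alleles[typed[pm]]
            }
            if g not in possible:
                violations.append((iid, "mendelian_error"))
    return sorted(set(violations))
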