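"""Exclusion-rule cascade for rare recessive candidate variants.

Annotated variants are excluded, in order, when:

1. fewer than 3 reads support the alternate allele in any sequenced
   affected sample (``low_alt_support``);
2. the reference-population allele frequency exceeds 0.05 OR the variant
   was seen in more than 30 individuals of the in-house exome cohort
   (``common_or_recurrent`` — one rule with two OR-joined clauses);
3. the variant has homozygotes in the reference population
   (``population_homozygote``);
4. the variant is synonymous (``synonymous``);
5. the variant lies in a 5' UTR, or is intronic beyond the splice-site
   window (``utr_or_deep_intronic``).

A variant is attributed to the *first* rule it fails, so the per-rule
exclusion counts plus the survivors always sum to the input count.  The
rules are independent predicates: permuting their order changes the
attribution, never the surviving set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import CONSEQUENCE_CLASSES
from .vcfio import VariantTable

RULE_NAMES = (
    "low_alt_support",
    "common_or_recurrent",
    "population_homozygote",
    "synonymous",
    "utr_or_deep_intronic",
)


@dataclass(frozen=True)
class FilterThresholds:
    """Tunable cut-offs; defaults are the cascade's canonical values."""

    min_alt_reads: int = 3
    max_pop_af: float = 0.05
    max_inhouse: int = 30
    exclude_pop_hom: bool = True
    splice_window_bp: int = 2
    exclude_utr3: bool = False  # the literal rule spares 3' UTR variants

    def __post_init__(self) -> None:
        if min(self.min_alt_reads, self.max_inhouse, self.splice_window_bp) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.max_pop_af <= 1.0:
            raise ValueError("max_pop_af outside [0,1]")


@dataclass
class FilterReport:
    n_input: int
    rule_order: tuple[str, ...]
    excluded: dict[str, int]  # per-rule first-failure counts, ordered
    surviving_ids: list[str]
    first_fail: dict[str, str]  # variant id -> rule that removed it

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_ids)

    def conserved(self) -> bool:
        """Input count equals survivors plus the per-rule exclusions."""
        return self.n_input == self.n_surviving + sum(self.excluded.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": rule, "excluded": self.excluded[rule]}
            for rule in self.rule_order
        ]
        rows.append({"stage": "surviving", "excluded": self.n_surviving})
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _rule_masks(
    table: VariantTable,
    thresholds: FilterThresholds,
    affected_samples: list[str],
) -> dict[str, np.ndarray]:
    """Boolean failure mask per rule (True = variant fails that rule)."""
    info = table.info
    csq = info["csqclass"]
    unknown = ~csq.isin(CONSEQUENCE_CLASSES)
    if unknown.any():
        i = int(np.flatnonzero(unknown.to_numpy())[0])
        raise ValueError(
            f"variant {info['chrom'][i]}:{info['pos'][i]} has unknown "
            f"consequence class {csq[i]!r}"
        )
    cols = [table.sample_index(s) for s in affected_samples]
    if not cols:
        raise ValueError("need at least one sequenced affected sample")
    low_support = (table.ad_alt[:, cols] < thresholds.min_alt_reads).any(axis=1)

    af = info["exac_af"].to_numpy(dtype=float)
    inhouse = info["inhouse_n"].to_numpy(dtype=int)
    common = (af > thresholds.max_pop_af) | (inhouse > thresholds.max_inhouse)

    pop_hom = (
        info["exac_hom"].to_numpy(dtype=int) > 0
        if thresholds.exclude_pop_hom
        else np.zeros(len(info), dtype=bool)
    )

    synonymous = (csq == "synonymous").to_numpy()

    dist = info["dist2exon"].to_numpy(dtype=int)
    intronic = csq.isin(["intronic_near_splice", "intronic_deep"]).to_numpy()
    noncoding = (
        (csq == "utr5").to_numpy()
        | (intronic & (dist > thresholds.splice_window_bp))
    )
    if thresholds.exclude_utr3:
        noncoding |= (csq == "utr3").to_numpy()

    return {
        "low_alt_support": low_support,
        "common_or_recurrent": common,
        "population_homozygote": pop_hom,
        "synonymous": synonymous,
        "utr_or_deep_intronic": noncoding,
    }


def apply_filters(
    table: VariantTable,
    thresholds: FilterThresholds,
    affected_samples: list[str],
    rule_order: tuple[str, ...] = RULE_NAMES,
) -> FilterReport:
    """Run the cascade; attribute each exclusion to its first failed rule."""
    if sorted(rule_order) != sorted(RULE_NAMES):
        raise ValueError("rule_order must be a permutation of RULE_NAMES")
    masks = _rule_masks(table, thresholds, affected_samples)
    ids = table.variant_ids
    assigned = np.full(len(ids), -1, dtype=int)
    for k, rule in enumerate(rule_order):
        hit = masks[rule] & (assigned < 0)
        assigned[hit] = k
    excluded = {
        rule: int((assigned == k).sum()) for k, rule in enumerate(rule_order)
    }
    surviving = [vid for vid, a in zip(ids, assigned) if a < 0]
    first_fail = {
        vid: rule_order[a] for vid, a in zip(ids, assigned) if a >= 0
    }
    return FilterReport(
        n_input=len(ids),
        rule_order=tuple(rule_order),
        excluded=excluded,
        surviving_ids=surviving,
        first_fail=first_fail,
    )


def compute_allele_frequency(alt_count: int, total_alleles: int) -> float:
    """Minor allele frequency as a percentage (full precision).

    E.g. 3 alternate alleles out of 187,624 genotyped alleles give
    0.0015989...%, displayed as 0.0016% at two significant figures.
    """
    if total_alleles <= 0:
        raise ValueError("total_alleles must be positive")
    if not 0 <= alt_count <= total_alleles:
        raise ValueError("alt_count outside [0, total_alleles]")
    return 100.0 * alt_count / total_alleles


def format_allele_frequency(percent: float, sig_figs: int = 2) -> str:
    """Display form of a percent frequency at ``sig_figs`` significant figures."""
    if percent == 0:
        return "0%"
    return f"{percent:.{sig_figs}g}%"
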