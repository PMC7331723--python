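"""Genome map for the gene-dropping simulator.

The map fixes the coordinate system shared by every downstream stage:
chromosomes with a physical length (bp) and a genetic length (Morgans),
a sorted set of bi-allelic marker positions per chromosome, and the
founder (population) alternate-allele frequency of every marker.

Coordinates are build-agnostic: nothing downstream assumes a particular
reference assembly, only that positions are 1-based and strictly
increasing within a chromosome (the VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Variant consequence vocabulary used by the annotation payloads and the
#: filtering cascade.
CONSEQUENCE_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice_site",
    "synonymous",
    "utr5",
    "utr3",
    "intronic_near_splice",
    "intronic_deep",
    "intergenic",
)

_INTRONIC = ("intronic_near_splice", "intronic_deep")


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length_bp: int
    length_morgans: float


@dataclass
class GenomeMap:
    chromosomes: list[ChromSpec]
    positions: dict[str, np.ndarray]  # 1-based bp, strictly increasing
    alt_freqs: dict[str, np.ndarray]  # founder alternate-allele frequency

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            pos = np.asarray(self.positions[chrom.name])
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{chrom.name}: marker positions not increasing")
            if pos.size and (pos[0] < 1 or pos[-1] > chrom.length_bp):
                raise ValueError(f"{chrom.name}: marker outside chromosome")
            freq = np.asarray(self.alt_freqs[chrom.name])
            if freq.shape != pos.shape:
                raise ValueError(f"{chrom.name}: freq/position length mismatch")
            if freq.size and (freq.min() < 0 or freq.max() > 1):
                raise ValueError(f"{chrom.name}: allele frequency outside [0,1]")

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def n_markers(self) -> int:
        return int(sum(len(self.positions[c.name]) for c in self.chromosomes))

    @property
    def total_bp(self) -> int:
        return int(sum(c.length_bp for c in self.chromosomes))

    def chrom(self, name: str) -> ChromSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def marker_index(self, chrom: str, position: int) -> int:
        pos = self.positions[chrom]
        i = int(np.searchsorted(pos, position))
        if i >= len(pos) or pos[i] != position:
            raise KeyError(f"no marker at {chrom}:{position}")
        return i


@dataclass
class BackgroundAnnotationModel:
    """Two-component allele-frequency mixture for background markers.

    Markers are either "common" (frequency uniform on ``common_af``) or
    "rare" (uniform on ``rare_af``).  The mixture deliberately exercises
    every branch of the exclusion cascade: common markers trip the
    population-frequency and population-homozygote rules, rare markers
    survive them; consequence classes are drawn from ``class_probs`` so
    the synonymous/noncoding rules also see traffic.

    Reference-population annotations are derived from the drawn frequency:
    homozygote counts assume Hardy-Weinberg in a cohort of
    ``ref_population_size`` individuals, in-house carrier counts assume a
    sequenced local cohort of ``inhouse_cohort_size`` individuals.  A
    small fraction of rare variants receives a single reference-population
    homozygote (``rare_hom_prob``) so the homozygote rule is not fully
    collinear with the frequency rule.
    """

    common_fraction: float = 0.5
    common_af: tuple[float, float] = (0.05, 0.5)
    rare_af: tuple[float, float] = (0.0, 0.001)
    class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 0.50,
            "synonymous": 0.35,
            "utr5": 0.03,
            "utr3": 0.05,
            "intronic_near_splice": 0.02,
            "intronic_deep": 0.03,
            "nonsense": 0.01,
            "frameshift": 0.005,
            "splice_site": 0.005,
        }
    )
    ref_population_size: int = 60_000
    inhouse_cohort_size: int = 1_000
    rare_hom_prob: float = 0.05

    def draw_frequencies(self, n: int, rng: np.random.Generator) -> np.ndarray:
        common = rng.random(n) < self.common_fraction
        freq = np.where(
            common,
            rng.uniform(*self.common_af, n),
            rng.uniform(*self.rare_af, n),
        )
        return freq


def default_genome_map(
    n_chromosomes: int = 4,
    chrom_length_bp: int = 100_000_000,
    chrom_length_morgans: float = 1.0,
    markers_per_chromosome: int = 1_000,
    background: BackgroundAnnotationModel | None = None,
    rng: np.random.Generator | None = None,
) -> GenomeMap:
    """Evenly spaced exome-like marker map.

    Defaults give 0.1 cM marker spacing, so the 25-SNP homozygosity rule
    corresponds to a 2.5 cM genetic span — dense enough that the
    autozygous segments of first-cousin offspring (mean ≈ 33 cM) are
    essentially always detectable.
    """
    background = background or BackgroundAnnotationModel()
    rng = rng if rng is not None else np.random.default_rng(0)
    chromosomes = [
        ChromSpec(f"chr{i + 1}", chrom_length_bp, chrom_length_morgans)
        for i in range(n_chromosomes)
    ]
    positions = {}
    freqs = {}
    for c in chromosomes:
        step = c.length_bp // (markers_per_chromosome + 1)
        positions[c.name] = np.arange(1, markers_per_chromosome + 1) * step
        freqs[c.name] = background.draw_frequencies(markers_per_chromosome, rng)
    return GenomeMap(chromosomes, positions, freqs)


def draw_annotations(
    gmap: GenomeMap,
    model: BackgroundAnnotationModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Annotation payload per marker, aligned with the map's marker order.

    Columns: chrom, pos, ref, alt, csqclass, exac_af, exac_hom,
    inhouse_n, dist2exon (``-1`` for non-intronic classes).
    """
    classes = list(model.class_probs)
    probs = np.array([model.class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    frames = []
    bases = np.array(list("ACGT"))
    for chrom in gmap.chrom_names:
        pos = gmap.positions[chrom]
        af = gmap.alt_freqs[chrom]
        n = len(pos)
        csq = rng.choice(classes, size=n, p=probs)
        # Hardy-Weinberg homozygote counts in the reference population.
        exac_hom = np.round(af**2 * model.ref_population_size).astype(int)
        rare = af < model.common_af[0]
        exac_hom[rare] = (rng.random(rare.sum()) < model.rare_hom_prob).astype(int)
        carrier_p = 1.0 - (1.0 - af) ** 2
        inhouse = rng.binomial(model.inhouse_cohort_size, carrier_p)
        dist = np.full(n, -1, dtype=int)
        near = csq == "intronic_near_splice"
        deep = csq == "intronic_deep"
        dist[near] = rng.integers(1, 3, near.sum())
        dist[deep] = rng.integers(20, 5_000, deep.sum())
        ref_idx = rng.integers(0, 4, n)
        alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": bases[ref_idx],
                    "alt": bases[alt_idx],
                    "csqclass": csq,
                    "exac_af": af,
                    "exac_hom": exac_hom,
                    "inhouse_n": inhouse,
                    "dist2exon": dist,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
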