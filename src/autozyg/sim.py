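"""Synthetic consanguineous-family simulator.

Generates everything the downstream mapping analysis consumes, together
with ground truth for recovery testing:

* a pedigree with a configurable consanguinity loop (default: first-cousin
  parents of an eight-child sibship);
* gene dropping — founder haplotypes transmitted through each meiosis with
  a Poisson number of crossovers per chromosome (Haldane model, no
  interference) — yielding per-individual haplotype mosaics labelled by
  founder haplotype of origin, from which autozygous (homozygous by
  descent) segments are read off exactly;
* a rare variant planted on one founder haplotype inside the loop, with
  affection status assigned under a fully penetrant autosomal recessive
  model, optionally conditioned on a target number of affected children;
* noisy multi-sample genotypes with read depths and annotation payloads;
* hand-bone length measurements whose standardized values follow
  configurable per-group z bands with fixed per-bone outliers.

All randomness flows from numpy Generators; callers split streams in a
documented order (annotations → founder alleles → meioses → noise →
measurements) so a single integer seed reproduces a whole study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .anthropometry import HAND_BONES, NormTable, lookup_norm
from .genome import GenomeMap
from .pedigree import FEMALE, MALE, Individual, Pedigree, PedigreeError
from .vcfio import HET, HOM_ALT, HOM_REF, MISSING, VariantTable

_LOOP_DEGREE = {"siblings": 1, "first_cousins": 2, "second_cousins": 3}


# ---------------------------------------------------------------------------
# Pedigree construction
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSpec:
    """Family layout for the simulator.

    ``consanguinity`` is the degree of the loop joining the two focal
    parents: ``"first_cousins"`` (default) makes the parents' parents
    siblings, so the parents share one grandparental founder couple;
    ``None`` makes the parents unrelated founders.  ``child_sexes`` may
    fix the sibship's sexes (list of 1/2 codes); by default sexes
    alternate male/female.
    """

    n_children: int = 8
    consanguinity: str | int | None = "first_cousins"
    n_affected_target: int | None = 5
    child_sexes: Sequence[int] | None = None
    family_id: str = "FAM1"

    def loop_degree(self) -> int | None:
        if self.consanguinity is None:
            return None
        if isinstance(self.consanguinity, str):
            try:
                return _LOOP_DEGREE[self.consanguinity]
            except KeyError:
                raise PedigreeError(
                    f"unknown consanguinity {self.consanguinity!r}; "
                    f"use one of {sorted(_LOOP_DEGREE)} or an integer degree"
                ) from None
        return int(self.consanguinity)

    def __post_init__(self) -> None:
        if self.n_children < 0:
            raise PedigreeError("n_children must be non-negative")
        if (
            self.n_affected_target is not None
            and self.n_affected_target > self.n_children
        ):
            raise PedigreeError("n_affected_target exceeds n_children")
        if self.child_sexes is not None and len(self.child_sexes) != self.n_children:
            raise PedigreeError("child_sexes length must equal n_children")


def build_pedigree(spec: PedigreeSpec) -> Pedigree:
    """Construct the pedigree graph described by ``spec``.

    For a loop of degree *d* the two focal parents descend from one shared
    founder couple through *d* meioses on each side; intermediate
    individuals marry founder spouses so every non-founder has both
    parents present.  First cousins (d=2) with 8 children therefore yield
    16 individuals: the shared couple, two intermediate siblings and
    their two spouses, the two parents, and the sibship.  Children are
    created with affection status unassigned.
    """
    inds: list[Individual] = []
    degree = spec.loop_degree()
    if degree is None:
        inds.append(Individual("FA", sex=MALE))
        inds.append(Individual("MO", sex=FEMALE))
    else:
        if degree < 1:
            raise PedigreeError(
                "consanguinity loop needs at least one generation of shared "
                "founder ancestors (degree >= 1)"
            )
        inds.append(Individual("ANC-1", sex=MALE))
        inds.append(Individual("ANC-2", sex=FEMALE))
        for branch, sex in (("A", MALE), ("B", FEMALE)):
            father, mother = "ANC-1", "ANC-2"
            for gen in range(1, degree):
                iid, spouse = f"{branch}{gen}", f"{branch}{gen}-SP"
                inds.append(Individual(iid, father, mother, sex=sex))
                inds.append(
                    Individual(spouse, sex=FEMALE if sex == MALE else MALE)
                )
                father, mother = (
                    (iid, spouse) if sex == MALE else (spouse, iid)
                )
            bottom = "FA" if branch == "A" else "MO"
            inds.append(Individual(bottom, father, mother, sex=sex))
    sexes = list(
        spec.child_sexes
        if spec.child_sexes is not None
        else [MALE if i % 2 == 0 else FEMALE for i in range(spec.n_children)]
    )
    for i in range(spec.n_children):
        inds.append(Individual(f"C{i + 1}", "FA", "MO", sex=sexes[i]))
    ped = Pedigree(inds, family_id=spec.family_id)
    if degree is not None and not ped.common_ancestors("FA", "MO"):
        raise PedigreeError("configured loop produced no shared ancestors")
    return ped


def focal_couple(pedigree: Pedigree) -> tuple[str, str]:
    """The couple whose children are the terminal sibship.

    Looks for the unique (father, mother) pair all of whose children are
    leaves of the pedigree.  Raises if the pedigree has no or several such
    couples, in which case the caller must name the couple explicitly.
    """
    has_children = {i.iid for i in pedigree if pedigree.children(i.iid)}
    couples = {
        (i.father, i.mother)
        for i in pedigree
        if i.father is not None and i.iid not in has_children
    }
    couples = {
        c
        for c in couples
        if all(
            ch not in has_children
            for ch in pedigree.children(c[0])
            if pedigree[ch].mother == c[1]
        )
    }
    if len(couples) != 1:
        raise PedigreeError(
            f"expected exactly one terminal sibship couple, found {len(couples)}"
        )
    return couples.pop()  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Haplotypes and meiosis
# ---------------------------------------------------------------------------

@dataclass
class Haplotype:
    """A chromosome as a mosaic of founder-haplotype segments.

    ``bounds`` holds ascending segment *end* coordinates (the last equals
    the chromosome length); segment *i* covers the half-open genetic
    interval ``(bounds[i-1], bounds[i]]`` and carries the integer founder
    haplotype label ``labels[i]``.
    """

    bounds: np.ndarray
    labels: np.ndarray

    def labels_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.bounds, positions, side="left")
        return self.labels[idx]


def meiosis(
    pat: Haplotype,
    mat: Haplotype,
    length_bp: float,
    morgans: float,
    rng: np.random.Generator,
) -> tuple[Haplotype, np.ndarray]:
    """One gamete from a haplotype pair.

    Crossover count ~ Poisson(genetic length in Morgans); crossover
    positions uniform on the chromosome (Haldane: no interference, and a
    uniform genetic map).  Returns the gamete and the crossover positions.
    """
    k = int(rng.poisson(morgans))
    xs = np.sort(rng.uniform(0.0, length_bp, size=k)) if k else np.empty(0)
    cur = int(rng.integers(2))
    bounds: list[float] = []
    labels: list[int] = []
    prev = 0.0
    for cut in [*xs.tolist(), float(length_bp)]:
        if cut > prev:
            src = pat if cur == 0 else mat
            i = int(np.searchsorted(src.bounds, prev, side="right"))
            start = prev
            while start < cut:
                end = min(float(src.bounds[i]), cut)
                lab = int(src.labels[i])
                if labels and labels[-1] == lab:
                    bounds[-1] = end
                else:
                    bounds.append(end)
                    labels.append(lab)
                start = end
                i += 1
        prev = cut
        cur ^= 1
    return Haplotype(np.asarray(bounds), np.asarray(labels, dtype=np.int64)), xs


def autozygous_segments(
    pat: Haplotype, mat: Haplotype
) -> list[tuple[float, float]]:
    """Intervals where both haplotypes carry the same founder label."""
    cuts = np.union1d(pat.bounds, mat.bounds)
    lp = pat.labels[np.searchsorted(pat.bounds, cuts, side="left")]
    lm = mat.labels[np.searchsorted(mat.bounds, cuts, side="left")]
    same = lp == lm
    out: list[tuple[float, float]] = []
    start = 0.0
    for i, cut in enumerate(cuts):
        if same[i]:
            if out and out[-1][1] == start:
                out[-1] = (out[-1][0], float(cut))
            else:
                out.append((start, float(cut)))
        start = float(cut)
    return out


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Simulator ground truth for recovery testing."""

    planted_chrom: str | None
    planted_pos: int | None
    planted_genotypes: dict[str, int]
    ibd_segments: dict[str, list[tuple[str, float, float]]]
    crossover_positions: dict[str, dict[str, list[float]]]
    autozygous_fraction: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        d["ibd_segments"] = {
            k: [(c, float(a), float(b)) for c, a, b in v]
            for k, v in d["ibd_segments"].items()
        }
        return cls(**d)


class GeneDropper:
    """Transmits founder haplotypes down a pedigree.

    Founder haplotypes receive labels ``2i`` and ``2i+1`` in pedigree
    order.  Founder marker alleles are drawn lazily (independent
    Bernoulli draws at the map's allele frequencies) from a dedicated
    stream, so structure-only experiments (e.g. inbreeding estimation)
    never pay for them.
    """

    def __init__(
        self, pedigree: Pedigree, gmap: GenomeMap, rng: np.random.Generator
    ):
        if gmap.n_markers == 0:
            raise ValueError("genome map has no markers")
        self.pedigree = pedigree
        self.gmap = gmap
        self._rng_alleles, self.rng = rng.spawn(2)
        self.founder_hap_labels: dict[str, tuple[int, int]] = {
            f: (2 * i, 2 * i + 1) for i, f in enumerate(pedigree.founders())
        }
        self.n_founder_haps = 2 * len(self.founder_hap_labels)
        self._founder_alleles: dict[str, np.ndarray] | None = None
        self._forced: list[tuple[str, int, int, int]] = []
        self.haplotypes: dict[str, dict[str, tuple[Haplotype, Haplotype]]] = {}
        self.crossovers: dict[str, dict[str, list[float]]] = {}
        for f, (la, lb) in self.founder_hap_labels.items():
            self.haplotypes[f] = {}
            for c in gmap.chromosomes:
                length = float(c.length_bp)
                self.haplotypes[f][c.name] = (
                    Haplotype(np.array([length]), np.array([la])),
                    Haplotype(np.array([length]), np.array([lb])),
                )

    # -- founder alleles ----------------------------------------------------

    def force_founder_allele(
        self, chrom: str, marker_idx: int, hap_label: int, allele: int
    ) -> None:
        """Pin one founder haplotype's allele at one marker.

        All other founder haplotypes are set to the reference allele at
        that marker (used to plant a variant private to one ancestor).
        """
        self._forced.append((chrom, marker_idx, hap_label, allele))
        if self._founder_alleles is not None:
            self._apply_forced(self._founder_alleles)

    def _apply_forced(self, alleles: dict[str, np.ndarray]) -> None:
        for chrom, idx, lab, allele in self._forced:
            alleles[chrom][:, idx] = 0
            alleles[chrom][lab, idx] = allele

    @property
    def founder_alleles(self) -> dict[str, np.ndarray]:
        if self._founder_alleles is None:
            out = {}
            for c in self.gmap.chromosomes:
                freq = self.gmap.alt_freqs[c.name]
                out[c.name] = (
                    self._rng_alleles.random((self.n_founder_haps, len(freq)))
                    < freq
                ).astype(np.int8)
            self._apply_forced(out)
            self._founder_alleles = out
        return self._founder_alleles

    # -- transmission -------------------------------------------------------

    def draw_individual(self, iid: str, chroms: Sequence[str] | None = None) -> None:
        """(Re)draw the two gametes forming ``iid`` on the given chromosomes."""
        father, mother = self.pedigree.parents(iid)  # type: ignore[misc]
        self.haplotypes.setdefault(iid, {})
        for cname in chroms or self.gmap.chrom_names:
            cspec = self.gmap.chrom(cname)
            gam_p, xs_p = meiosis(
                *self.haplotypes[father][cname],
                cspec.length_bp,
                cspec.length_morgans,
                self.rng,
            )
            gam_m, xs_m = meiosis(
                *self.haplotypes[mother][cname],
                cspec.length_bp,
                cspec.length_morgans,
                self.rng,
            )
            self.haplotypes[iid][cname] = (gam_p, gam_m)
            self.crossovers.setdefault(f"{iid}|{father}", {})[cname] = (
                xs_p.tolist()
            )
            self.crossovers.setdefault(f"{iid}|{mother}", {})[cname] = (
                xs_m.tolist()
            )

    def drop_all(self) -> None:
        for iid in self.pedigree.topological_order():
            if not self.pedigree[iid].is_founder:
                self.draw_individual(iid)

    # -- observables --------------------------------------------------------

    def allele_at(self, iid: str, chrom: str, marker_idx: int, which: int) -> int:
        hap = self.haplotypes[iid][chrom][which]
        pos = self.gmap.positions[chrom][marker_idx]
        lab = int(hap.labels_at(np.array([pos]))[0])
        return int(self.founder_alleles[chrom][lab, marker_idx])

    def genotype_at(self, iid: str, chrom: str, marker_idx: int) -> int:
        return self.allele_at(iid, chrom, marker_idx, 0) + self.allele_at(
            iid, chrom, marker_idx, 1
        )

    def genotype_matrix(self) -> tuple[list[str], pd.DataFrame, np.ndarray]:
        """True genotypes for every marker × every pedigree member.

        Returns (sample order, site frame with chrom/pos, genotype matrix).
        """
        samples = self.pedigree.ids
        blocks = []
        sites = []
        for cname in self.gmap.chrom_names:
            pos = self.gmap.positions[cname]
            alleles = self.founder_alleles[cname]
            cols = []
            for iid in samples:
                pat, mat = self.haplotypes[iid][cname]
                ar = np.arange(len(pos))
                g = (
                    alleles[pat.labels_at(pos), ar]
                    + alleles[mat.labels_at(pos), ar]
                )
                cols.append(g.astype(np.int8))
            blocks.append(np.stack(cols, axis=1))
            sites.append(pd.DataFrame({"chrom": cname, "pos": pos}))
        return samples, pd.concat(sites, ignore_index=True), np.vstack(blocks)

    def ibd_segments(self, iid: str) -> list[tuple[str, float, float]]:
        out = []
        for cname in self.gmap.chrom_names:
            pat, mat = self.haplotypes[iid][cname]
            for a, b in autozygous_segments(pat, mat):
                out.append((cname, a, b))
        return out

    def autozygous_fraction(self, iid: str) -> float:
        total = sum(b - a for _, a, b in self.ibd_segments(iid))
        return total / self.gmap.total_bp

    def truth(
        self, planted_chrom: str | None = None, planted_pos: int | None = None
    ) -> TruthRecord:
        genos: dict[str, int] = {}
        if planted_chrom is not None and planted_pos is not None:
            idx = self.gmap.marker_index(planted_chrom, planted_pos)
            genos = {
                iid: self.genotype_at(iid, planted_chrom, idx)
                for iid in self.pedigree.ids
            }
        return TruthRecord(
            planted_chrom=planted_chrom,
            planted_pos=planted_pos,
            planted_genotypes=genos,
            ibd_segments={i: self.ibd_segments(i) for i in self.pedigree.ids},
            crossover_positions=self.crossovers,
            autozygous_fraction={
                i: self.autozygous_fraction(i) for i in self.pedigree.ids
            },
        )


def gene_drop(
    pedigree: Pedigree, gmap: GenomeMap, seed: int | np.random.Generator
) -> GeneDropper:
    """Unconditional gene drop of the whole pedigree."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dropper = GeneDropper(pedigree, gmap, rng)
    dropper.drop_all()
    return dropper


def estimate_inbreeding(
    pedigree: Pedigree,
    gmap: GenomeMap,
    individual: str,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Replicate autozygous genome fractions for one pedigree member.

    The mean over replicates estimates the inbreeding coefficient F; for
    offspring of first cousins the path-counting value is 1/16.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_replicates)
    for r, child_rng in enumerate(rng.spawn(n_replicates)):
        out[r] = gene_drop(pedigree, gmap, child_rng).autozygous_fraction(
            individual
        )
    return out


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------

@dataclass
class PlantedVariantSpec:
    """A rare pathogenic allele carried by one founder haplotype.

    Defaults mirror an ultra-rare missense allele: reference-population
    frequency 1.6e-5 (3 alternate alleles out of 187,624) with no
    homozygotes and no in-house carriers.
    """

    chrom: str | None = None  # default: first chromosome
    position: int | None = None  # default: middle marker
    consequence: str = "missense"
    annotated_af: float = 3 / 187_624
    annotated_hom_count: int = 0
    inhouse_carriers: int = 0
    source_ancestor: str | None = None  # default: first shared founder

    def __post_init__(self) -> None:
        if not 0.0 <= self.annotated_af <= 1.0:
            raise ValueError("annotated_af outside [0,1]")


class PlantingError(RuntimeError):
    """Conditioned transmission could not be achieved within the attempt bound."""


@dataclass
class PlantedDrop:
    dropper: GeneDropper
    pedigree: Pedigree  # with affection statuses assigned
    spec: PlantedVariantSpec
    chrom: str
    position: int
    marker_idx: int
    affected: list[str]
    truth: TruthRecord

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.position}"


def plant_variant(
    pedigree: Pedigree,
    gmap: GenomeMap,
    spec: PlantedVariantSpec,
    rng: np.random.Generator,
    n_affected_target: int | None = None,
    max_attempts: int = 10_000,
) -> PlantedDrop:
    """Gene-drop with a planted recessive allele and assign affection.

    One haplotype of ``spec.source_ancestor`` (a founder inside the
    consanguinity loop) carries the alternate allele; every other founder
    haplotype is reference, so homozygosity for the allele is necessarily
    homozygosity by descent.  Affection is the fully penetrant recessive
    phenotype: affected ⇔ homozygous alternate.

    When ``n_affected_target`` is set the transmissions are conditioned on
    the affection pattern by staged rejection: the ancestor meioses of the
    planted chromosome are redrawn until both focal parents carry the
    allele, a uniformly random subset of children of the target size is
    designated affected, and each child's planted-chromosome gametes are
    redrawn until its genotype matches its designation.  Chromosomes
    segregate independently, and children are exchangeable, so this
    samples the gene-drop distribution conditional on the observed
    affected count.  Each stage is bounded by ``max_attempts``.
    """
    chrom = spec.chrom or gmap.chrom_names[0]
    positions = gmap.positions[chrom]
    position = (
        spec.position
        if spec.position is not None
        else int(positions[len(positions) // 2])
    )
    marker_idx = gmap.marker_index(chrom, position)

    father, mother = focal_couple(pedigree)
    children = sorted(
        (
            c
            for c in pedigree.children(father)
            if pedigree[c].mother == mother
        ),
        key=pedigree.ids.index,
    )
    shared = sorted(
        pedigree.common_ancestors(father, mother), key=pedigree.ids.index
    )
    source = spec.source_ancestor
    if source is None:
        founder_shared = [s for s in shared if pedigree[s].is_founder]
        if not founder_shared:
            raise PedigreeError(
                "no shared founder ancestor to carry the planted allele"
            )
        source = founder_shared[0]
    if not pedigree[source].is_founder:
        raise PedigreeError(f"source ancestor {source!r} is not a founder")

    dropper = GeneDropper(pedigree, gmap, rng)
    dropper.force_founder_allele(
        chrom, marker_idx, dropper.founder_hap_labels[source][0], 1
    )

    dropper.drop_all()

    def carries(iid: str) -> bool:
        return (
            dropper.allele_at(iid, chrom, marker_idx, 0)
            + dropper.allele_at(iid, chrom, marker_idx, 1)
            > 0
        )

    affected_set: set[str]
    if n_affected_target is not None:
        uppers = [
            i
            for i in pedigree.topological_order()
            if not pedigree[i].is_founder and i not in children
        ]
        for attempt in range(max_attempts):
            if carries(father) and carries(mother):
                break
            for iid in uppers:
                dropper.draw_individual(iid, chroms=[chrom])
            # redrawing ancestor segments invalidates the children's copies
            for ch in children:
                dropper.draw_individual(ch, chroms=[chrom])
        else:
            raise PlantingError(
                f"focal parents not both carriers after {max_attempts} attempts"
            )
        affected_set = {
            str(c)
            for c in dropper.rng.choice(
                children, size=n_affected_target, replace=False
            )
        }
        for ch in children:
            want = ch in affected_set
            for attempt in range(max_attempts):
                if (
                    dropper.genotype_at(ch, chrom, marker_idx) == 2
                ) == want:
                    break
                dropper.draw_individual(ch, chroms=[chrom])
            else:
                raise PlantingError(
                    f"child {ch}: target genotype not reached after "
                    f"{max_attempts} attempts"
                )
    else:
        affected_set = {
            ch
            for ch in children
            if dropper.genotype_at(ch, chrom, marker_idx) == 2
        }

    status = {
        iid: dropper.genotype_at(iid, chrom, marker_idx) == 2
        for iid in pedigree.ids
    }
    ped_with_status = pedigree.with_affection(status)
    truth = dropper.truth(planted_chrom=chrom, planted_pos=position)
    return PlantedDrop(
        dropper=dropper,
        pedigree=ped_with_status,
        spec=spec,
        chrom=chrom,
        position=position,
        marker_idx=marker_idx,
        affected=sorted(affected_set, key=pedigree.ids.index),
        truth=truth,
    )


def apply_planted_annotation(
    annotations: pd.DataFrame, planted: PlantedDrop
) -> pd.DataFrame:
    """Overwrite the planted site's annotation row with the spec's payload."""
    out = annotations.copy()
    mask = (out["chrom"] == planted.chrom) & (out["pos"] == planted.position)
    if mask.sum() != 1:
        raise ValueError("planted site not found in annotation table")
    spec = planted.spec
    out.loc[mask, ["csqclass", "exac_af", "exac_hom", "inhouse_n", "dist2exon"]] = [
        spec.consequence,
        spec.annotated_af,
        spec.annotated_hom_count,
        spec.inhouse_carriers,
        -1,
    ]
    return out


# ---------------------------------------------------------------------------
# Genotype emission with noise
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Genotype-call and read-depth noise.

    ``genotype_error_rate`` is the probability a true homozygous call is
    emitted heterozygous and vice versa.  Depth is Poisson around
    ``mean_depth``; alternate-read counts are binomial with success
    probability ``allele_balance`` at heterozygous sites and
    ``base_error`` / ``1 - base_error`` at homozygous ref/alt sites.
    ``missing_rate`` blanks calls entirely.
    """

    genotype_error_rate: float = 0.002
    mean_depth: float = 60.0
    allele_balance: float = 0.5
    base_error: float = 0.001
    missing_rate: float = 0.005

    def __post_init__(self) -> None:
        for p in (
            self.genotype_error_rate,
            self.allele_balance,
            self.base_error,
            self.missing_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("noise probabilities must lie in [0,1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


NOISELESS = NoiseModel(
    genotype_error_rate=0.0, mean_depth=500.0, base_error=0.0, missing_rate=0.0
)


def emit_variants(
    dropper: GeneDropper,
    annotations: pd.DataFrame,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> VariantTable:
    """Turn true haplotypes into a noisy annotated multi-sample table."""
    samples, sites, true_gt = dropper.genotype_matrix()
    if not (
        np.array_equal(sites["pos"].to_numpy(), annotations["pos"].to_numpy())
        and (sites["chrom"] == annotations["chrom"]).all()
    ):
        raise ValueError("annotation table does not match the genome map")

    gt = true_gt.copy()
    flip = rng.random(gt.shape) < noise.genotype_error_rate
    pick = rng.random(gt.shape) < 0.5
    gt[(true_gt == HOM_REF) & flip] = HET
    gt[(true_gt == HOM_ALT) & flip] = HET
    het_flip = (true_gt == HET) & flip
    gt[het_flip] = np.where(pick[het_flip], HOM_REF, HOM_ALT)
    gt[rng.random(gt.shape) < noise.missing_rate] = MISSING

    dp = rng.poisson(noise.mean_depth, size=gt.shape).astype(np.int32)
    p_alt = np.full(gt.shape, noise.base_error)
    p_alt[gt == HET] = noise.allele_balance
    p_alt[gt == HOM_ALT] = 1.0 - noise.base_error
    ad_alt = rng.binomial(dp, p_alt).astype(np.int32)

    return VariantTable(
        samples=samples,
        info=annotations.reset_index(drop=True),
        gt=gt,
        ad_alt=ad_alt,
        dp=dp,
        contig_lengths={
            c.name: c.length_bp for c in dropper.gmap.chromosomes
        },
    )


# ---------------------------------------------------------------------------
# Hand measurements
# ---------------------------------------------------------------------------

@dataclass
class MeasurementSimSpec:
    """Z-band structure of simulated metacarpophalangeal lengths.

    Unaffected hands scatter within ``z_range_unaffected`` (default ±1 SD
    around the age/sex-expected mean); affected hands within
    ``z_range_affected`` (default 1–3 SD below expectation).
    ``outlier_bones`` pins individual (individual, side, bone) entries to
    a fixed z — e.g. a −7 SD first metacarpal — overriding the band.
    """

    z_range_unaffected: tuple[float, float] = (-1.0, 1.0)
    z_range_affected: tuple[float, float] = (-3.0, -1.0)
    outlier_bones: list[tuple[str, str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for lo, hi in (self.z_range_unaffected, self.z_range_affected):
            if not lo <= hi:
                raise ValueError("z range bounds out of order")
        for *_, z in self.outlier_bones:
            if not np.isfinite(z):
                raise ValueError("outlier z must be finite")


SIDES = ("left", "right")

# Plausible adult bone lengths (mm) for the synthetic reference table.
_ADULT_MEAN_MM = {
    "MC1": 45.0, "MC2": 68.0, "MC3": 65.0, "MC4": 58.0, "MC5": 52.0,
    "PP1": 32.0, "PP2": 42.0, "PP3": 46.0, "PP4": 43.0, "PP5": 33.0,
    "MP2": 25.0, "MP3": 30.0, "MP4": 28.0, "MP5": 20.0,
    "DP1": 22.0, "DP2": 17.0, "DP3": 18.0, "DP4": 18.0, "DP5": 16.0,
}


def default_norm_table(
    ages: Sequence[float] = (20, 30, 40, 50, 60, 70, 80),
    sex_ratio: float = 0.92,
    cv: float = 0.07,
) -> NormTable:
    """Synthetic adult reference norms for the 19 hand bones.

    A stand-in for an external radiographic reference atlas: means are
    plausible adult bone lengths (female = male × ``sex_ratio``), the SD
    is a fixed coefficient of variation, and values plateau across adult
    ages.  Synthetic — not derived from any published atlas.
    """
    rows = []
    for bone, male_mean in _ADULT_MEAN_MM.items():
        for sex, factor in ((MALE, 1.0), (FEMALE, sex_ratio)):
            for age in ages:
                mean = male_mean * factor
                rows.append(
                    {
                        "bone_id": bone,
                        "sex": sex,
                        "age_years": float(age),
                        "mean_mm": round(mean, 3),
                        "sd_mm": round(mean * cv, 3),
                    }
                )
    return NormTable(pd.DataFrame(rows))


def simulate_measurements(
    norms: NormTable,
    spec: MeasurementSimSpec,
    persons: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Bone lengths (mm) for each person/side/bone.

    ``persons`` needs columns individual, sex, age_years, affected.
    Lengths are mean + z·SD with z uniform in the person's group band,
    except for pinned outliers.
    """
    pinned = {(i, s, b): z for i, s, b, z in spec.outlier_bones}
    rows = []
    for person in persons.itertuples(index=False):
        lo, hi = (
            spec.z_range_affected
            if person.affected
            else spec.z_range_unaffected
        )
        for side in SIDES:
            for bone in HAND_BONES:
                z = pinned.get(
                    (person.individual, side, bone),
                    float(rng.uniform(lo, hi)),
                )
                mean, sd = lookup_norm(
                    norms, bone, int(person.sex), float(person.age_years)
                )
                rows.append(
                    {
                        "individual": person.individual,
                        "side": side,
                        "bone_id": bone,
                        "length_mm": mean + z * sd,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Demonstration clinical cohort
# ---------------------------------------------------------------------------

#: Clinical summary of the demonstration WMS sibship shipped with the
#: package: five affected adults with short stature (mean height 156.5 cm),
#: universal early-onset myopia and elevated intraocular pressure, and
#: variable lens, glaucoma and joint findings.
CLINICAL_REFERENCE = {
    "height_cm": [160.0, 149.0, 157.0, 161.0, 155.5],
    "myopia": [1, 1, 1, 1, 1],
    "microspherophakia": [1, 1, 1, 1, 0],
    "ectopia_lentis": [1, 1, 1, 1, 0],
    "elevated_iop": [1, 1, 1, 1, 1],
    "glaucoma": [0, 1, 1, 0, 0],
    "cataracts": [0, 1, 1, 0, 0],
    "joint_stiffness": [0, 0, 0, 0, 1],
}


def cohort_phenotypes(affected_ids: Sequence[str]) -> pd.DataFrame:
    """Attach the demonstration clinical table to five affected individuals."""
    n = len(CLINICAL_REFERENCE["height_cm"])
    if len(affected_ids) != n:
        raise ValueError(
            f"clinical reference describes {n} patients, got {len(affected_ids)}"
        )
    return pd.DataFrame({"individual": list(affected_ids), **CLINICAL_REFERENCE})
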