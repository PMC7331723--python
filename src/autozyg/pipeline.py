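"""End-to-end orchestration: simulate → ROH → filter → intersect →
segregate → anthropometry, with deterministic seeding and file outputs.

The candidate set at the end of a run is the intersection of three
evidence layers: variants surviving the exclusion cascade, homozygous
alternate in every sequenced affected individual, and located inside a
run of homozygosity shared by all sequenced affecteds.  Each candidate
carries a provenance trail reconstructing that evidence.

Randomness: one integer seed per run, split into four child streams in a
fixed order — annotations (marker frequencies and payloads), gene drop
(founder alleles, then meioses), genotype noise, measurements.  The same
config and seed reproduce every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import anthropometry as anthro
from . import sim
from .filtering import FilterReport, FilterThresholds, apply_filters
from .genome import BackgroundAnnotationModel, default_genome_map, draw_annotations
from .pedigree import Pedigree, read_ped, write_ped
from .roh import ROHParams, ROHRegion, call_roh_sample, shared_roh, write_roh_tsv
from .segregation import check_ar_segregation
from .vcfio import HOM_ALT, VariantTable, read_vcf, write_vcf


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    n_chromosomes: int = 4
    chrom_length_bp: int = 100_000_000
    chrom_length_morgans: float = 1.0
    markers_per_chromosome: int = 1_000


@dataclass
class AnthropometryConfig:
    brachydactyly_delta: float = 1.0
    marked_threshold: float = -5.0
    #: ages (years) assigned to the sequenced affected hand-study
    #: participants and the unaffected comparison sibling
    affected_hand_ages: tuple[float, ...] = (68.0, 64.0)
    unaffected_hand_age: float = 66.0


@dataclass
class SimulationConfig:
    pedigree: sim.PedigreeSpec = field(default_factory=sim.PedigreeSpec)
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    background: BackgroundAnnotationModel = field(
        default_factory=BackgroundAnnotationModel
    )
    planted: sim.PlantedVariantSpec = field(
        default_factory=sim.PlantedVariantSpec
    )
    noise: sim.NoiseModel = field(default_factory=sim.NoiseModel)
    measurement: sim.MeasurementSimSpec = field(
        default_factory=sim.MeasurementSimSpec
    )
    n_sequenced_affected: int = 2
    max_attempts: int = 10_000
    #: drop the planted site from the emitted variant table (emulates the
    #: causal variant escaping exome capture); affection is unchanged
    omit_planted_site: bool = False
    #: pin the canonical marked-shortening outliers (−5.3 SD right first
    #: proximal phalanx of the first sequenced affected, −7 SD left first
    #: metacarpal of the second) unless the measurement spec already
    #: defines outliers
    pin_default_outliers: bool = True


@dataclass
class InputPaths:
    vcf: str
    ped: str
    norms: str | None = None
    measurements: str | None = None
    persons: str | None = None


@dataclass
class PipelineConfig:
    simulation: SimulationConfig | None = field(
        default_factory=SimulationConfig
    )
    inputs: InputPaths | None = None
    roh: ROHParams = field(default_factory=ROHParams)
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    anthro: AnthropometryConfig = field(default_factory=AnthropometryConfig)
    seed: int = 0
    outdir: str = "autozyg_run"

    def __post_init__(self) -> None:
        if self.simulation is None and self.inputs is None:
            raise ValueError("config needs a simulation block or input paths")
        if self.inputs is not None and self.inputs.measurements is not None:
            if self.inputs.norms is None or self.inputs.persons is None:
                raise ValueError(
                    "anthropometry inputs need norms and persons tables"
                )


def _build(cls, data: dict | None):
    if data is None:
        return cls()
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"{cls.__name__}: unknown config key {key!r}")
        if isinstance(value, list) and key != "outlier_bones":
            value = tuple(value)
        if key == "outlier_bones":
            value = [tuple(v) for v in value]
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    simulation = None
    if "simulation" in data and data["simulation"] is not None:
        s = dict(data["simulation"])
        simulation = SimulationConfig(
            pedigree=_build(sim.PedigreeSpec, s.pop("pedigree", None)),
            genome=_build(GenomeConfig, s.pop("genome", None)),
            background=_build(BackgroundAnnotationModel, s.pop("background", None)),
            planted=_build(sim.PlantedVariantSpec, s.pop("planted", None)),
            noise=_build(sim.NoiseModel, s.pop("noise", None)),
            measurement=_build(sim.MeasurementSimSpec, s.pop("measurement", None)),
            **s,
        )
    inputs = (
        _build(InputPaths, data["inputs"]) if data.get("inputs") else None
    )
    return PipelineConfig(
        simulation=simulation,
        inputs=inputs,
        roh=_build(ROHParams, data.get("roh")),
        filters=_build(FilterThresholds, data.get("filters")),
        anthro=_build(AnthropometryConfig, data.get("anthro")),
        seed=int(data.get("seed", 0)),
        outdir=str(data.get("outdir", "autozyg_run")),
    )


def read_config(path: str | Path) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _yamlable(obj: Any) -> Any:
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    return obj


def write_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_yamlable(dataclasses.asdict(config)), sort_keys=False)
    )


# ---------------------------------------------------------------------------
# Simulation of one study
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    pedigree: Pedigree  # affection statuses assigned
    planted: sim.PlantedDrop
    table: VariantTable
    sequenced_affected: list[str]
    norms: anthro.NormTable | None
    persons: pd.DataFrame | None
    measurements: pd.DataFrame | None
    phenotypes: pd.DataFrame | None


def simulate_study(
    cfg: SimulationConfig,
    seed: int,
    anthro_cfg: AnthropometryConfig | None = None,
    include_measurements: bool = True,
) -> SimulatedStudy:
    """Generate one complete synthetic study from a single seed."""
    anthro_cfg = anthro_cfg or AnthropometryConfig()
    master = np.random.default_rng(seed)
    rng_ann, rng_drop, rng_noise, rng_meas = master.spawn(4)

    pedigree = sim.build_pedigree(cfg.pedigree)
    gmap = default_genome_map(
        n_chromosomes=cfg.genome.n_chromosomes,
        chrom_length_bp=cfg.genome.chrom_length_bp,
        chrom_length_morgans=cfg.genome.chrom_length_morgans,
        markers_per_chromosome=cfg.genome.markers_per_chromosome,
        background=cfg.background,
        rng=rng_ann,
    )
    annotations = draw_annotations(gmap, cfg.background, rng_ann)
    planted = sim.plant_variant(
        pedigree,
        gmap,
        cfg.planted,
        rng_drop,
        n_affected_target=cfg.pedigree.n_affected_target,
        max_attempts=cfg.max_attempts,
    )
    annotations = sim.apply_planted_annotation(annotations, planted)
    table = sim.emit_variants(planted.dropper, annotations, cfg.noise, rng_noise)
    if cfg.omit_planted_site:
        keep = ~(
            (table.info["chrom"] == planted.chrom)
            & (table.info["pos"] == planted.position)
        )
        table = table.subset_sites(np.flatnonzero(keep.to_numpy()))
    sequenced = planted.affected[: cfg.n_sequenced_affected]

    norms = persons = measurements = phenotypes = None
    if include_measurements:
        unaffected_sibs = [
            c
            for c in planted.pedigree.children("FA")
            if planted.pedigree[c].affected is False
        ]
        hand_ids = list(sequenced) + unaffected_sibs[:1]
        ages = list(anthro_cfg.affected_hand_ages[: len(sequenced)])
        ages += [50.0] * (len(sequenced) - len(ages))
        if unaffected_sibs:
            ages.append(anthro_cfg.unaffected_hand_age)
        persons = pd.DataFrame(
            {
                "individual": hand_ids,
                "sex": [planted.pedigree[i].sex for i in hand_ids],
                "age_years": ages,
                "affected": [
                    planted.pedigree[i].affected is True for i in hand_ids
                ],
            }
        )
        meas_spec = cfg.measurement
        if cfg.pin_default_outliers and not meas_spec.outlier_bones:
            outliers = []
            if len(sequenced) >= 1:
                outliers.append((sequenced[0], "right", "PP1", -5.3))
            if len(sequenced) >= 2:
                outliers.append((sequenced[1], "left", "MC1", -7.0))
            meas_spec = dataclasses.replace(meas_spec, outlier_bones=outliers)
        norms = sim.default_norm_table()
        measurements = sim.simulate_measurements(
            norms, meas_spec, persons, rng_meas
        )
        if len(planted.affected) == len(
            sim.CLINICAL_REFERENCE["height_cm"]
        ):
            phenotypes = sim.cohort_phenotypes(planted.affected)
    return SimulatedStudy(
        pedigree=planted.pedigree,
        planted=planted,
        table=table,
        sequenced_affected=sequenced,
        norms=norms,
        persons=persons,
        measurements=measurements,
        phenotypes=phenotypes,
    )


# ---------------------------------------------------------------------------
# Candidate prioritization and phenotype summary
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    candidates: list[dict[str, Any]]

    @property
    def ids(self) -> list[str]:
        return [c["id"] for c in self.candidates]


def prioritize_candidates(
    filter_report: FilterReport,
    shared_regions: list[tuple[str, int, int]],
    table: VariantTable,
    affected_samples: list[str],
) -> CandidateSet:
    """Intersect the three evidence layers into an ordered candidate set."""
    surviving = set(filter_report.surviving_ids)
    cols = [table.sample_index(s) for s in affected_samples]
    out: list[dict[str, Any]] = []
    ids = table.variant_ids
    chroms = table.info["chrom"].to_numpy()
    pos = table.info["pos"].to_numpy()
    for i, vid in enumerate(ids):
        if vid not in surviving:
            continue
        if not all(table.gt[i, j] == HOM_ALT for j in cols):
            continue
        hit = next(
            (
                r
                for r in shared_regions
                if r[0] == chroms[i] and r[1] <= pos[i] <= r[2]
            ),
            None,
        )
        if hit is None:
            continue
        out.append(
            {
                "id": vid,
                "chrom": str(chroms[i]),
                "pos": int(pos[i]),
                "consequence": str(table.info["csqclass"].iloc[i]),
                "provenance": {
                    "passed_filters": True,
                    "hom_alt_in": list(affected_samples),
                    "shared_roh": [str(hit[0]), int(hit[1]), int(hit[2])],
                },
            }
        )
    out.sort(key=lambda c: (c["chrom"], c["pos"]))
    return CandidateSet(candidates=out)


def summarize_phenotypes(cohort: pd.DataFrame) -> dict[str, Any]:
    """Mean height and per-feature fractions for a clinical cohort table."""
    heights = cohort["height_cm"].dropna()
    if heights.empty:
        raise ValueError("no heights in cohort table")
    features = {}
    for col in cohort.columns:
        if col in ("individual", "height_cm"):
            continue
        flags = cohort[col].dropna().astype(int)
        features[col] = {"count": int(flags.sum()), "n": int(len(flags))}
    return {
        "mean_height_cm": float(heights.mean()),
        "n_heights": int(len(heights)),
        "features": features,
    }


# ---------------------------------------------------------------------------
# In-memory analysis and full pipeline run
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    roh_by_sample: dict[str, list[ROHRegion]]
    shared: list[tuple[str, int, int]]
    filter_report: FilterReport
    candidates: CandidateSet


def analyze(
    table: VariantTable,
    sequenced_affected: list[str],
    roh_params: ROHParams,
    thresholds: FilterThresholds,
) -> AnalysisResult:
    """ROH → shared intersection → filter cascade → candidate set."""
    regions = {
        s: call_roh_sample(table, s, roh_params) for s in sequenced_affected
    }
    shared = shared_roh(regions, sequenced_affected)
    report = apply_filters(table, thresholds, sequenced_affected)
    candidates = prioritize_candidates(report, shared, table, sequenced_affected)
    return AnalysisResult(
        roh_by_sample=regions,
        shared=shared,
        filter_report=report,
        candidates=candidates,
    )


@dataclass
class RunResult:
    outdir: Path
    analysis: AnalysisResult
    segregation: dict[str, Any] | None
    hand_comparison: dict[str, Any] | None
    phenotype_summary: dict[str, Any] | None
    truth_variant_id: str | None


def _json_line(fh, stage: str, **payload: Any) -> None:
    fh.write(json.dumps({"stage": stage, **payload}, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute every stage, writing outputs and a JSONL run log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = open(outdir / "run_log.jsonl", "w")
    _json_line(log, "config", seed=config.seed)

    truth_vid = None
    norms = persons = measurements = phenotypes = None
    try:
        if config.simulation is not None:
            study = simulate_study(
                config.simulation, config.seed, anthro_cfg=config.anthro
            )
            write_ped(study.pedigree, outdir / "family.ped")
            write_vcf(study.table, outdir / "variants.vcf")
            study.planted.truth.to_json(outdir / "truth.json")
            truth_vid = study.planted.variant_id
            if study.norms is not None:
                study.norms.write_tsv(outdir / "norms.tsv")
                study.persons.to_csv(
                    outdir / "persons.tsv", sep="\t", index=False
                )
                study.measurements.to_csv(
                    outdir / "measurements.tsv", sep="\t", index=False
                )
            if study.phenotypes is not None:
                study.phenotypes.to_csv(
                    outdir / "phenotypes.tsv", sep="\t", index=False
                )
            # Re-read from disk so the analysed data went through the
            # same parsers a user-supplied study would.
            pedigree = read_ped(outdir / "family.ped")
            table = read_vcf(outdir / "variants.vcf")
            sequenced = study.sequenced_affected
            norms, persons = study.norms, study.persons
            measurements, phenotypes = study.measurements, study.phenotypes
            _json_line(
                log,
                "simulate",
                n_sites=table.n_sites,
                affected=study.planted.affected,
                sequenced=sequenced,
                planted=truth_vid,
            )
        else:
            pedigree = read_ped(config.inputs.ped)
            table = read_vcf(config.inputs.vcf)
            sequenced = [
                s for s in table.samples if pedigree[s].affected is True
            ]
            if config.inputs.norms:
                norms = anthro.NormTable.read_tsv(config.inputs.norms)
                persons = pd.read_csv(config.inputs.persons, sep="\t")
                measurements = pd.read_csv(
                    config.inputs.measurements, sep="\t"
                )
            _json_line(
                log, "load", n_sites=table.n_sites, sequenced=sequenced
            )
    except Exception as exc:
        log.close()
        raise PipelineStageError(f"input stage failed: {exc}") from exc

    try:
        analysis = analyze(table, sequenced, config.roh, config.filters)
    except Exception as exc:
        log.close()
        raise PipelineStageError(f"mapping stage failed: {exc}") from exc

    all_regions = [r for regs in analysis.roh_by_sample.values() for r in regs]
    write_roh_tsv(all_regions, outdir / "roh.tsv")
    with open(outdir / "shared_roh.tsv", "w") as fh:
        fh.write("# 1-based inclusive coordinates\nchrom\tstart\tend\n")
        for chrom, lo, hi in analysis.shared:
            fh.write(f"{chrom}\t{lo}\t{hi}\n")
    analysis.filter_report.write_tsv(outdir / "attrition.tsv")
    surviving_idx = np.array(
        [
            i
            for i, vid in enumerate(table.variant_ids)
            if vid in set(analysis.filter_report.surviving_ids)
        ],
        dtype=int,
    )
    write_vcf(table.subset_sites(surviving_idx), outdir / "surviving.vcf")
    (outdir / "candidates.json").write_text(
        json.dumps(analysis.candidates.candidates, indent=1, sort_keys=True)
    )
    _json_line(
        log,
        "mapping",
        n_roh={s: len(r) for s, r in analysis.roh_by_sample.items()},
        n_shared=len(analysis.shared),
        attrition=analysis.filter_report.excluded,
        attrition_conserved=analysis.filter_report.conserved(),
        n_candidates=len(analysis.candidates.candidates),
    )

    segregation = None
    if analysis.candidates.candidates:
        top = analysis.candidates.candidates[0]
        i = table.site_index(top["chrom"], top["pos"])
        typed = _segregation_subset(pedigree, sequenced)
        genotypes = {
            s: int(table.gt[i, table.sample_index(s)]) for s in typed
        }
        res = check_ar_segregation(pedigree, genotypes)
        segregation = {
            "variant": top["id"],
            "typed": typed,
            "genotypes": genotypes,
            "consistent": res.consistent,
            "violations": [list(v) for v in res.violations],
        }
        (outdir / "segregation.json").write_text(
            json.dumps(segregation, indent=1, sort_keys=True)
        )
        _json_line(log, "segregation", consistent=res.consistent)

    hand_comparison = None
    if measurements is not None:
        profiles = anthro.profile_hands(measurements, norms, persons)
        anthro.profiles_frame(profiles).to_csv(
            outdir / "profiles.tsv", sep="\t", index=False
        )
        status = persons.set_index("individual")["affected"]
        aff = [p for p in profiles if bool(status.get(p.individual))]
        unaff = [p for p in profiles if not bool(status.get(p.individual))]
        if aff and unaff:
            comparison = anthro.compare_profiles(
                aff,
                unaff,
                brachydactyly_delta=config.anthro.brachydactyly_delta,
                marked_threshold=config.anthro.marked_threshold,
            )
            hand_comparison = comparison.to_dict()
            (outdir / "hand_comparison.json").write_text(
                json.dumps(hand_comparison, indent=1, sort_keys=True)
            )
            _json_line(
                log,
                "anthropometry",
                difference=comparison.difference,
                brachydactyly=comparison.brachydactyly,
                n_marked=len(comparison.marked_bones),
            )

    phenotype_summary = None
    if phenotypes is not None:
        phenotype_summary = summarize_phenotypes(phenotypes)
        (outdir / "phenotype_summary.json").write_text(
            json.dumps(phenotype_summary, indent=1, sort_keys=True)
        )
        _json_line(
            log,
            "phenotypes",
            mean_height_cm=phenotype_summary["mean_height_cm"],
        )

    log.close()
    return RunResult(
        outdir=outdir,
        analysis=analysis,
        segregation=segregation,
        hand_comparison=hand_comparison,
        phenotype_summary=phenotype_summary,
        truth_variant_id=truth_vid,
    )


def _segregation_subset(
    pedigree: Pedigree, sequenced: list[str]
) -> list[str]:
    """Individuals genotyped at the candidate site.

    Mirrors targeted follow-up genotyping: the mother of the sibship, the
    sequenced affecteds, one additional affected sibling and one
    unaffected sibling.
    """
    typed = list(sequenced)
    try:
        father, mother = sim.focal_couple(pedigree)
    except Exception:
        return typed
    typed.insert(0, mother)
    sibs = [
        c for c in pedigree.children(father) if pedigree[c].mother == mother
    ]
    extra_aff = [
        c for c in sibs if pedigree[c].affected is True and c not in typed
    ]
    unaff = [c for c in sibs if pedigree[c].affected is False]
    if extra_aff:
        typed.append(extra_aff[0])
    if unaff:
        typed.append(unaff[0])
    return typed


# ---------------------------------------------------------------------------
# Replicated recovery experiment
# ---------------------------------------------------------------------------

def recovery_experiment(
    n_runs: int,
    base_seed: int,
    sim_config: SimulationConfig | None = None,
    roh_params: ROHParams = ROHParams(),
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Repeat the simulate→map→filter→prioritize chain over many seeds.

    Returns one row per run: whether the planted variant reached the final
    candidate set, whether the attrition ledger conserved counts, and the
    candidate count.  Seeds are ``base_seed + run`` (kept below 2**31).
    """
    sim_config = sim_config or SimulationConfig()
    rows = []
    for run in range(n_runs):
        seed = int((base_seed + run) % (2**31))
        study = simulate_study(sim_config, seed, include_measurements=False)
        analysis = analyze(
            study.table, study.sequenced_affected, roh_params, thresholds
        )
        rows.append(
            {
                "seed": seed,
                "recovered": study.planted.variant_id
                in analysis.candidates.ids,
                "attrition_conserved": analysis.filter_report.conserved(),
                "n_candidates": len(analysis.candidates.candidates),
            }
        )
    return pd.DataFrame(rows)
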