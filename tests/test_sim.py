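import numpy as np
import pandas as pd
import pytest

from autozyg import pipeline as pl
from autozyg import sim
from autozyg.genome import default_genome_map
from autozyg.pedigree import FEMALE, MALE
from autozyg.vcfio import HET, HOM_ALT, HOM_REF, MISSING


@pytest.fixture(scope="module")
def cousin_child_pedigree():
    return sim.build_pedigree(
        sim.PedigreeSpec(n_children=1, n_affected_target=None)
    )


class TestGeneDrop:
    def test_zero_genetic_length_transmits_whole_haplotypes(self, small_gmap):
        gmap = default_genome_map(
            n_chromosomes=2,
            chrom_length_bp=50_000_000,
            chrom_length_morgans=0.0,
            markers_per_chromosome=50,
            rng=np.random.default_rng(0),
        )
        ped = sim.build_pedigree(
            sim.PedigreeSpec(
                n_children=2, consanguinity=None, n_affected_target=None
            )
        )
        dropper = sim.gene_drop(ped, gmap, seed=3)
        for child in ("C1", "C2"):
            for chrom in gmap.chrom_names:
                pat, mat = dropper.haplotypes[child][chrom]
                parental = [
                    h.labels.tolist()
                    for parent in ("FA", "MO")
                    for h in dropper.haplotypes[parent][chrom]
                ]
                assert pat.labels.tolist() in parental
                assert mat.labels.tolist() in parental
                assert len(pat.labels) == 1  # no crossovers at all

    def test_allele_conservation(self, cousin_child_pedigree, small_gmap):
        """Every transmitted segment label is a founder haplotype label."""
        dropper = sim.gene_drop(cousin_child_pedigree, small_gmap, seed=5)
        valid = set(range(dropper.n_founder_haps))
        for iid in cousin_child_pedigree.ids:
            for chrom in small_gmap.chrom_names:
                for hap in dropper.haplotypes[iid][chrom]:
                    assert set(hap.labels.tolist()) <= valid
                    assert np.all(np.diff(hap.bounds) > 0)
                    assert hap.bounds[-1] == small_gmap.chrom(chrom).length_bp

    def test_founders_are_never_autozygous(self, cousin_child_pedigree, small_gmap):
        dropper = sim.gene_drop(cousin_child_pedigree, small_gmap, seed=6)
        for f in cousin_child_pedigree.founders():
            assert dropper.ibd_segments(f) == []

    def test_first_cousin_offspring_inbreeding(self, cousin_child_pedigree):
        """Mean autozygous fraction approaches the path-counting value 1/16."""
        gmap = default_genome_map(rng=np.random.default_rng(9))
        fractions = sim.estimate_inbreeding(
            cousin_child_pedigree, gmap, "C1", n_replicates=400, seed=11
        )
        se = fractions.std() / np.sqrt(len(fractions))
        assert abs(fractions.mean() - 1 / 16) < 4 * se

    def test_empty_marker_set_rejected(self, cousin_child_pedigree, small_gmap):
        empty = default_genome_map(
            markers_per_chromosome=1, rng=np.random.default_rng(0)
        )
        for c in empty.chrom_names:
            empty.positions[c] = np.array([], dtype=int)
            empty.alt_freqs[c] = np.array([])
        with pytest.raises(ValueError):
            sim.gene_drop(cousin_child_pedigree, empty, seed=0)


class TestPlantVariant:
    def test_full_penetrance_and_target_count(self, noiseless_study):
        planted = noiseless_study.planted
        ped = planted.pedigree
        sibs = [c for c in ped.children("FA")]
        assert len(planted.affected) == 5
        for iid in sibs:
            gt = planted.truth.planted_genotypes[iid]
            assert (ped[iid].affected is True) == (gt == 2)

    def test_planted_site_inside_truth_ibd(self, noiseless_study):
        planted = noiseless_study.planted
        pos = planted.position
        for iid in planted.affected:
            segments = [
                (a, b)
                for chrom, a, b in planted.truth.ibd_segments[iid]
                if chrom == planted.chrom
            ]
            assert any(a < pos <= b for a, b in segments)

    def test_source_must_be_founder(self, small_gmap):
        ped = sim.build_pedigree(sim.PedigreeSpec())
        spec = sim.PlantedVariantSpec(source_ancestor="FA")
        with pytest.raises(Exception, match="founder"):
            sim.plant_variant(ped, small_gmap, spec, np.random.default_rng(0))

    def test_unreachable_target_reports_attempts(self, small_gmap):
        ped = sim.build_pedigree(
            sim.PedigreeSpec(n_children=4, n_affected_target=4)
        )
        with pytest.raises(sim.PlantingError, match="attempts"):
            sim.plant_variant(
                ped,
                small_gmap,
                sim.PlantedVariantSpec(),
                np.random.default_rng(0),
                n_affected_target=4,
                max_attempts=1,
            )


class TestEmitVariants:
    def test_noiseless_emission_equals_truth(self, noiseless_study):
        table = noiseless_study.table
        dropper = noiseless_study.planted.dropper
        _, _, true_gt = dropper.genotype_matrix()
        assert np.array_equal(table.gt, true_gt)

    def test_hom_ref_has_zero_alt_reads_without_error_floor(self, noiseless_study):
        table = noiseless_study.table
        assert np.all(table.ad_alt[table.gt == HOM_REF] == 0)
        assert np.all(
            table.ad_alt[table.gt == HOM_ALT]
            == table.dp[table.gt == HOM_ALT]
        )

    def test_het_allele_balance_matches_binomial_expectation(self, default_study):
        table = default_study.table
        het = table.gt == HET
        alt_fraction = table.ad_alt[het].sum() / table.dp[het].sum()
        n_reads = table.dp[het].sum()
        tol = 4 * np.sqrt(0.25 / n_reads)
        assert abs(alt_fraction - 0.5) < tol

    def test_missingness_rate_is_respected(self, default_study):
        table = default_study.table
        frac = (table.gt == MISSING).mean()
        assert 0.001 < frac < 0.01  # around the configured 0.005


class TestSimulateMeasurements:
    def test_outliers_and_bands_round_trip(self, noiseless_study):
        """Recomputing z from emitted lengths returns the planted values."""
        from autozyg.anthropometry import lookup_norm, z_score

        study = noiseless_study
        persons = study.persons.set_index("individual")
        pinned = {
            (i, s, b): z
            for i, s, b, z in [
                (study.sequenced_affected[0], "right", "PP1", -5.3),
                (study.sequenced_affected[1], "left", "MC1", -7.0),
            ]
        }
        for row in study.measurements.itertuples(index=False):
            sex = int(persons.loc[row.individual, "sex"])
            age = float(persons.loc[row.individual, "age_years"])
            mean, sd = lookup_norm(study.norms, row.bone_id, sex, age)
            z = z_score(row.length_mm, mean, sd)
            key = (row.individual, row.side, row.bone_id)
            if key in pinned:
                assert z == pytest.approx(pinned[key], abs=1e-9)
            elif persons.loc[row.individual, "affected"]:
                assert -3 <= z <= -1
            else:
                assert -1 <= z <= 1

    def test_zero_band_yields_norm_means(self):
        norms = sim.default_norm_table()
        spec = sim.MeasurementSimSpec(
            z_range_unaffected=(0.0, 0.0), z_range_affected=(0.0, 0.0)
        )
        persons = pd.DataFrame(
            {
                "individual": ["X"],
                "sex": [MALE],
                "age_years": [40.0],
                "affected": [False],
            }
        )
        meas = sim.simulate_measurements(
            norms, spec, persons, np.random.default_rng(0)
        )
        for row in meas.itertuples(index=False):
            mean, _ = sim.lookup_norm(norms, row.bone_id, MALE, 40.0)
            assert row.length_mm == pytest.approx(mean)


def test_cohort_phenotypes_requires_five_patients():
    with pytest.raises(ValueError):
        sim.cohort_phenotypes(["a", "b"])
    frame = sim.cohort_phenotypes(["a", "b", "c", "d", "e"])
    assert frame["height_cm"].mean() == pytest.approx(156.5)
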