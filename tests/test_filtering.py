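import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autozyg.filtering import (
    RULE_NAMES,
    FilterThresholds,
    apply_filters,
    compute_allele_frequency,
    format_allele_frequency,
)
from conftest import make_variant_table

SAMPLES = ["aff1", "aff2"]
DEFAULT = FilterThresholds()


def cascade_table():
    """Ten variants engineered so each rule removes a known subset."""
    rows = [
        {"ad_alt": [2, 20]},                       # low_alt_support
        {"exac_af": 0.10},                         # common (AF clause)
        {"inhouse_n": 40},                         # common (in-house clause)
        {"exac_hom": 2},                           # population_homozygote
        {"csqclass": "synonymous"},                # synonymous
        {"csqclass": "utr5"},                      # utr_or_deep_intronic
        {},                                        # survivor: rare missense
        {"csqclass": "utr3"},                      # survivor: 3' UTR retained
        {"csqclass": "intronic_near_splice", "dist2exon": 2},  # survivor
        {"csqclass": "nonsense"},                  # survivor
    ]
    return make_variant_table(rows, SAMPLES)


class TestCascade:
    def test_engineered_counts_and_survivors(self):
        report = apply_filters(cascade_table(), DEFAULT, SAMPLES)
        assert [report.excluded[r] for r in RULE_NAMES] == [1, 2, 1, 1, 1]
        assert report.n_surviving == 4
        assert report.surviving_ids == [
            "chr1:7000",
            "chr1:8000",
            "chr1:9000",
            "chr1:10000",
        ]
        assert report.conserved()

    def test_first_fail_attribution(self):
        """A variant failing several rules is charged only to the first."""
        table = make_variant_table(
            [{"exac_af": 0.10, "exac_hom": 5, "csqclass": "synonymous"}],
            SAMPLES,
        )
        report = apply_filters(table, DEFAULT, SAMPLES)
        assert report.excluded["common_or_recurrent"] == 1
        assert report.excluded["population_homozygote"] == 0
        assert report.excluded["synonymous"] == 0
        assert report.first_fail["chr1:1000"] == "common_or_recurrent"

    def test_rule_order_changes_attribution_not_survivors(self):
        table = cascade_table()
        baseline = apply_filters(table, DEFAULT, SAMPLES)
        for order in itertools.islice(itertools.permutations(RULE_NAMES), 24):
            report = apply_filters(table, DEFAULT, SAMPLES, rule_order=order)
            assert report.surviving_ids == baseline.surviving_ids
            assert report.conserved()

    def test_alt_support_checked_in_every_affected(self):
        """One low-coverage affected sample is enough to exclude."""
        table = make_variant_table(
            [{"ad_alt": [20, 2]}, {"ad_alt": [3, 3]}], SAMPLES
        )
        report = apply_filters(table, DEFAULT, SAMPLES)
        assert report.first_fail == {"chr1:1000": "low_alt_support"}
        assert report.surviving_ids == ["chr1:2000"]

    def test_boundary_values_are_inclusive(self):
        """AF == 0.05, in-house == 30, dist2exon == window all survive."""
        rows = [
            {"exac_af": 0.05},
            {"inhouse_n": 30},
            {"csqclass": "intronic_near_splice", "dist2exon": DEFAULT.splice_window_bp},
        ]
        report = apply_filters(make_variant_table(rows, SAMPLES), DEFAULT, SAMPLES)
        assert report.n_surviving == 3

    def test_unknown_consequence_class_names_variant(self):
        table = make_variant_table([{"csqclass": "mystery"}], SAMPLES)
        with pytest.raises(ValueError, match="chr1:1000"):
            apply_filters(table, DEFAULT, SAMPLES)

    def test_requires_affected_samples(self):
        with pytest.raises(ValueError):
            apply_filters(cascade_table(), DEFAULT, [])

    def test_utr3_switch(self):
        table = make_variant_table([{"csqclass": "utr3"}], SAMPLES)
        strict = FilterThresholds(exclude_utr3=True)
        assert apply_filters(table, DEFAULT, SAMPLES).n_surviving == 1
        assert apply_filters(table, strict, SAMPLES).n_surviving == 0


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_tightening_thresholds_never_adds_survivors(seed):
    rng = np.random.default_rng(seed)
    classes = [
        "missense", "synonymous", "utr5", "utr3",
        "intronic_near_splice", "intronic_deep", "nonsense",
    ]
    rows = []
    for _ in range(30):
        rows.append(
            {
                "csqclass": rng.choice(classes),
                "exac_af": float(rng.uniform(0, 0.1)),
                "exac_hom": int(rng.integers(0, 3)),
                "inhouse_n": int(rng.integers(0, 60)),
                "dist2exon": int(rng.integers(0, 50)),
                "ad_alt": rng.integers(0, 30, size=2).tolist(),
            }
        )
    table = make_variant_table(rows, SAMPLES)
    loose = FilterThresholds(
        min_alt_reads=2, max_pop_af=0.08, max_inhouse=45, splice_window_bp=8
    )
    tight = FilterThresholds(
        min_alt_reads=5, max_pop_af=0.02, max_inhouse=10, splice_window_bp=1
    )
    survive_loose = set(apply_filters(table, loose, SAMPLES).surviving_ids)
    survive_tight = set(apply_filters(table, tight, SAMPLES).surviving_ids)
    assert survive_tight <= survive_loose


class TestAlleleFrequency:
    def test_cohort_example(self):
        pct = compute_allele_frequency(3, 187_624)
        assert pct == pytest.approx(100.0 * 3 / 187_624)
        assert format_allele_frequency(pct) == "0.0016%"

    def test_extremes(self):
        assert compute_allele_frequency(0, 10) == 0.0
        assert format_allele_frequency(0.0) == "0%"
        assert compute_allele_frequency(10, 10) == 100.0
        assert format_allele_frequency(100.0, sig_figs=3) == "100%"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_allele_frequency(1, 0)
        with pytest.raises(ValueError):
            compute_allele_frequency(-1, 10)
        with pytest.raises(ValueError):
            compute_allele_frequency(11, 10)
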