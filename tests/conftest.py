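from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from autozyg import pipeline as pl
from autozyg import sim
from autozyg.genome import default_genome_map
from autozyg.vcfio import VariantTable


@pytest.fixture(scope="session")
def first_cousin_pedigree():
    return sim.build_pedigree(sim.PedigreeSpec())


@pytest.fixture(scope="session")
def small_gmap():
    """Compact map for fast structure tests (2 chromosomes, 200 markers)."""
    return default_genome_map(
        n_chromosomes=2,
        chrom_length_bp=50_000_000,
        chrom_length_morgans=0.5,
        markers_per_chromosome=100,
        rng=np.random.default_rng(42),
    )


@pytest.fixture(scope="session")
def noiseless_study():
    """One default-size study with noise switched off."""
    cfg = pl.SimulationConfig(noise=sim.NOISELESS)
    return pl.simulate_study(cfg, seed=20_001)


@pytest.fixture(scope="session")
def default_study():
    """One default-size study with default noise."""
    return pl.simulate_study(pl.SimulationConfig(), seed=20_002)


def make_variant_table(rows: list[dict], samples: list[str]) -> VariantTable:
    """Hand-built table for filter tests.

    Each row dict may set chrom, pos, csqclass, exac_af, exac_hom,
    inhouse_n, dist2exon, gt (list per sample), ad_alt (list), dp (list).
    """
    n, s = len(rows), len(samples)
    defaults = {
        "chrom": "chr1",
        "csqclass": "missense",
        "exac_af": 1.6e-5,
        "exac_hom": 0,
        "inhouse_n": 0,
        "dist2exon": -1,
        "ref": "A",
        "alt": "G",
    }
    info_rows = []
    gt = np.zeros((n, s), dtype=np.int8)
    ad = np.zeros((n, s), dtype=np.int32)
    dp = np.zeros((n, s), dtype=np.int32)
    for i, row in enumerate(rows):
        merged = {**defaults, "pos": 1000 * (i + 1), **row}
        gt[i] = merged.pop("gt", [2] * s)
        ad[i] = merged.pop("ad_alt", [20] * s)
        dp[i] = merged.pop("dp", [40] * s)
        info_rows.append(merged)
    return VariantTable(
        samples=samples,
        info=pd.DataFrame(info_rows),
        gt=gt,
        ad_alt=ad,
        dp=dp,
    )
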