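"""Multi-sample variant table and VCF 4.2 I/O.

The in-memory container is a :class:`VariantTable`: per-site genotype,
alt-read and depth matrices over an ordered sample list, plus the
annotation payload the filtering cascade consumes (consequence class,
reference-population frequency and homozygote count, in-house carrier
count).  Writing produces plain-text VCF 4.2 with ``FORMAT GT:AD:DP`` and
INFO keys ``CSQCLASS``, ``EXAC_AF``, ``EXAC_HOM``, ``INHOUSE_N``,
``DIST2EXON``; reading goes through cyvcf2.

Genotypes are encoded as integers: 0 hom-ref, 1 het, 2 hom-alt,
-1 missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

_INFO_HEADER = [
    '##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID=EXAC_AF,Number=1,Type=Float,Description='
    '"Reference population alternate allele frequency">',
    '##INFO=<ID=EXAC_HOM,Number=1,Type=Integer,Description='
    '"Reference population homozygote count">',
    '##INFO=<ID=INHOUSE_N,Number=1,Type=Integer,Description='
    '"Carriers seen in the in-house exome cohort">',
    '##INFO=<ID=DIST2EXON,Number=1,Type=Integer,Description='
    '"Distance to nearest exon boundary (bp); -1 if not intronic">',
]
_FORMAT_HEADER = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
    '"Read depth per allele (ref,alt)">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
]


@dataclass
class VariantTable:
    """Bi-allelic sites × samples, with annotations.

    ``info`` is a DataFrame aligned row-for-row with the matrices and must
    carry columns chrom, pos, ref, alt, csqclass, exac_af, exac_hom,
    inhouse_n, dist2exon.
    """

    samples: list[str]
    info: pd.DataFrame
    gt: np.ndarray  # (n_sites, n_samples) int8
    ad_alt: np.ndarray  # (n_sites, n_samples) int32, alt-supporting reads
    dp: np.ndarray  # (n_sites, n_samples) int32
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, s = self.gt.shape
        if len(self.info) != n or len(self.samples) != s:
            raise ValueError("matrix/info/sample shape mismatch")
        if self.ad_alt.shape != (n, s) or self.dp.shape != (n, s):
            raise ValueError("AD/DP shape mismatch")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def variant_ids(self) -> list[str]:
        return [
            f"{c}:{p}" for c, p in zip(self.info["chrom"], self.info["pos"])
        ]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in table") from None

    def sample_calls(self, sample: str, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions, genotype calls) for one sample on one chromosome."""
        mask = (self.info["chrom"] == chrom).to_numpy()
        j = self.sample_index(sample)
        return self.info["pos"].to_numpy()[mask], self.gt[mask, j]

    def site_index(self, chrom: str, pos: int) -> int:
        mask = (self.info["chrom"] == chrom) & (self.info["pos"] == pos)
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) != 1:
            raise KeyError(f"site {chrom}:{pos} not found")
        return int(idx[0])

    def subset_sites(self, row_idx: np.ndarray) -> "VariantTable":
        return VariantTable(
            samples=list(self.samples),
            info=self.info.iloc[row_idx].reset_index(drop=True),
            gt=self.gt[row_idx],
            ad_alt=self.ad_alt[row_idx],
            dp=self.dp[row_idx],
            contig_lengths=dict(self.contig_lengths),
        )


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Emit a plain-text VCF 4.2 file."""
    lines = ["##fileformat=VCFv4.2", "##source=autozyg"]
    contigs = table.contig_lengths or {
        c: int(g["pos"].max()) + 1
        for c, g in table.info.groupby("chrom", sort=False)
    }
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.extend(_INFO_HEADER)
    lines.extend(_FORMAT_HEADER)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples)
    )
    info = table.info
    for i in range(table.n_sites):
        row = info.iloc[i]
        info_str = (
            f"CSQCLASS={row.csqclass};EXAC_AF={row.exac_af:.6g};"
            f"EXAC_HOM={int(row.exac_hom)};INHOUSE_N={int(row.inhouse_n)};"
            f"DIST2EXON={int(row.dist2exon)}"
        )
        calls = [
            f"{_GT_STR[int(g)]}:{d - a},{a}:{d}"
            for g, a, d in zip(table.gt[i], table.ad_alt[i], table.dp[i])
        ]
        lines.append(
            f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
            f"{info_str}\tGT:AD:DP\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> VariantTable:
    """Parse a VCF produced by :func:`write_vcf` (or compatible)."""
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    gts, ads, dps = [], [], []
    contigs: dict[str, int] = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        contigs[name] = int(length)
    for v in vcf:
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "csqclass": v.INFO.get("CSQCLASS"),
                "exac_af": float(v.INFO.get("EXAC_AF", 0.0)),
                "exac_hom": int(v.INFO.get("EXAC_HOM", 0)),
                "inhouse_n": int(v.INFO.get("INHOUSE_N", 0)),
                "dist2exon": int(v.INFO.get("DIST2EXON", -1)),
            }
        )
        gt = v.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING  # cyvcf2 codes unknown as 3 under gts012
        gts.append(gt)
        ad = v.format("AD")
        ads.append(ad[:, 1].astype(np.int32))
        dps.append(v.format("DP")[:, 0].astype(np.int32))
    vcf.close()
    info = pd.DataFrame(rows)
    return VariantTable(
        samples=samples,
        info=info,
        gt=np.vstack(gts) if gts else np.empty((0, len(samples)), np.int8),
        ad_alt=np.vstack(ads) if ads else np.empty((0, len(samples)), np.int32),
        dp=np.vstack(dps) if dps else np.empty((0, len(samples)), np.int32),
        contig_lengths=contigs,
    )
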