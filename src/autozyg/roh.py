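"""Runs-of-homozygosity detection and cross-sample intersection.

A run of homozygosity (ROH) is a span of at least ``min_snps``
non-missing genotype calls containing at most ``max_het`` heterozygous
calls (defaults 25 and 2).  Detection works per sample per chromosome on
position-sorted calls:

* *maximal spans* — qualifying intervals extendable in neither direction
  (any extension would add a disqualifying heterozygote or run off the
  data) — are enumerated exactly;
* overlapping maximal spans are *merged* into reported regions, which
  keep total SNP and heterozygote counts (a merged region may contain
  more than ``max_het`` heterozygotes).

Both layers are available.  Missing calls are skipped entirely: they
neither interrupt a span nor count toward its SNP total.  Coordinates at
the I/O surface are 1-based inclusive base-pair intervals (VCF
convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .vcfio import HET, MISSING, VariantTable


@dataclass(frozen=True)
class ROHParams:
    min_snps: int = 25
    max_het: int = 2

    def __post_init__(self) -> None:
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if self.max_het < 0:
            raise ValueError("max_het must be >= 0")


@dataclass(frozen=True)
class ROHRegion:
    sample: str
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int  # 1-based inclusive
    n_snps: int  # non-missing calls inside the region
    n_het: int


def maximal_runs(
    calls: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int]]:
    """Maximal qualifying spans over one sample's ordered calls.

    ``calls`` uses the package's genotype codes; missing calls are
    skipped.  Returns ``(start_idx, end_idx, n_het)`` tuples where the
    indices refer to the *original* call array (inclusive) and the span
    covers at least ``min_snps`` non-missing calls with at most
    ``max_het`` heterozygotes.
    """
    calls = np.asarray(calls)
    keep = np.flatnonzero(calls != MISSING)
    comp = calls[keep]
    n = len(comp)
    if n == 0:
        return []
    k = params.max_het
    het = np.flatnonzero(comp == HET)
    m = len(het)
    spans: list[tuple[int, int, int]] = []
    if m <= k:
        if n >= params.min_snps:
            spans.append((int(keep[0]), int(keep[-1]), m))
        return spans
    # Each maximal span contains exactly k consecutive heterozygotes
    # het[j] .. het[j+k-1] and extends to (but excludes) the flanking
    # heterozygotes het[j-1] and het[j+k].
    for j in range(m - k + 1):
        left = het[j - 1] + 1 if j > 0 else 0
        right = het[j + k] - 1 if j + k < m else n - 1
        if right - left + 1 >= params.min_snps:
            spans.append((int(keep[left]), int(keep[right]), k))
    return spans


def _merge_spans(
    spans: list[tuple[int, int, int]], calls: np.ndarray
) -> list[tuple[int, int, int]]:
    """Merge overlapping index spans; recompute counts on the union."""
    if not spans:
        return []
    spans = sorted(spans)
    merged: list[list[int]] = [list(spans[0][:2])]
    for a, b, _ in spans[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        window = calls[a : b + 1]
        out.append((a, b, int((window == HET).sum())))
    return out


def call_roh(
    positions: np.ndarray,
    calls: np.ndarray,
    params: ROHParams = ROHParams(),
    sample: str = "",
    chrom: str = "",
    merge: bool = True,
) -> list[ROHRegion]:
    """ROH regions for one sample on one chromosome.

    ``positions`` must be strictly increasing (error otherwise).  With
    ``merge=False`` the raw maximal spans are reported instead of the
    merged regions.
    """
    positions = np.asarray(positions)
    calls = np.asarray(calls)
    if len(positions) != len(calls):
        raise ValueError("positions and calls differ in length")
    if len(positions) > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError(f"{chrom or 'chromosome'}: positions not sorted")
    spans = maximal_runs(calls, params)
    if merge:
        spans = _merge_spans(spans, calls)
    nonmissing = calls != MISSING
    regions = []
    for a, b, n_het in spans:
        regions.append(
            ROHRegion(
                sample=sample,
                chrom=chrom,
                start_bp=int(positions[a]),
                end_bp=int(positions[b]),
                n_snps=int(nonmissing[a : b + 1].sum()),
                n_het=n_het,
            )
        )
    return regions


def call_roh_sample(
    table: VariantTable, sample: str, params: ROHParams = ROHParams()
) -> list[ROHRegion]:
    """ROH regions for one sample across every chromosome of a table."""
    regions: list[ROHRegion] = []
    for chrom in table.info["chrom"].unique():
        pos, calls = table.sample_calls(sample, chrom)
        regions.extend(call_roh(pos, calls, params, sample=sample, chrom=chrom))
    return regions


def _intersect(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two sorted lists of 1-based inclusive intervals."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def shared_roh(
    regions_by_sample: dict[str, list[ROHRegion]],
    samples: list[str],
) -> list[tuple[str, int, int]]:
    """Genomic intervals homozygous in every listed sample.

    Per chromosome, the interval intersection of each sample's (merged)
    ROH regions.  Raises ``KeyError`` naming any sample absent from the
    map.
    """
    if not samples:
        raise ValueError("need at least one sample")
    for s in samples:
        if s not in regions_by_sample:
            raise KeyError(f"sample {s!r} has no ROH call set")
    chroms: list[str] = []
    for s in samples:
        for r in regions_by_sample[s]:
            if r.chrom not in chroms:
                chroms.append(r.chrom)
    out: list[tuple[str, int, int]] = []
    for chrom in chroms:
        current: list[tuple[int, int]] | None = None
        for s in samples:
            ivals = sorted(
                (r.start_bp, r.end_bp)
                for r in regions_by_sample[s]
                if r.chrom == chrom
            )
            current = ivals if current is None else _intersect(current, ivals)
            if not current:
                break
        out.extend((chrom, lo, hi) for lo, hi in current or [])
    return out


# -- TSV I/O -----------------------------------------------------------------

ROH_HEADER = "# 1-based inclusive coordinates\nsample\tchrom\tstart\tend\tn_snps\tn_het\n"


def write_roh_tsv(regions: list[ROHRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(ROH_HEADER)
        for r in regions:
            fh.write(
                f"{r.sample}\t{r.chrom}\t{r.start_bp}\t{r.end_bp}\t"
                f"{r.n_snps}\t{r.n_het}\n"
            )


def read_roh_tsv(path: str | Path) -> list[ROHRegion]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return [
        ROHRegion(
            sample=str(r.sample),
            chrom=str(r.chrom),
            start_bp=int(r.start),
            end_bp=int(r.end),
            n_snps=int(r.n_snps),
            n_het=int(r.n_het),
        )
        for r in frame.itertuples(index=False)
    ]
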