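"""LOH calling, recurrent-region selection, and tumor haplotype inference.

In a tumor region of loss of heterozygosity (LOH) only one parental
chromosome copy remains, so the SNP-array B-allele-frequency (BAF) profile
directly exposes the haplotype of the retained copy without statistical
phasing: the BAF sits near 1 where the B allele is retained and near 0
where the A allele is retained, shifted towards 0.5 by contamination with
normal cells.

Allele-specific copy numbers are consumed as input (from an upstream
segmentation / copy-number model); a segment is called LOH when the copy
number of its minor allele is below 0.5, whatever the copy number of the
retained chromosome — this covers simple deletions as well as copy-neutral
LOH and LOH with gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import ALLELE_A, ALLELE_B, MISSING, BafProfile, HaplotypePanel, Origin

__all__ = [
    "LOH_MINOR_CN_MAX",
    "BAF_B_THRESHOLD",
    "BAF_A_THRESHOLD",
    "AscnSegment",
    "LOHRegion",
    "call_loh",
    "recurrent_loh_regions",
    "infer_tumor_haplotype",
    "drop_unreliable_markers",
    "reconstruct_lost_haplotype",
    "haplotype_error_rate",
    "read_ascn_segments",
]

#: a segment is LOH when the minor-allele copy number is below this value
LOH_MINOR_CN_MAX = 0.5

#: BAF above this calls the B allele; below 1 - this calls the A allele;
#: in between the marker is flagged unreliable
BAF_B_THRESHOLD = 0.65
BAF_A_THRESHOLD = 0.35


@dataclass
class AscnSegment:
    """Allele-specific copy-number segment (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    major_cn: float
    minor_cn: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must not exceed end_bp")
        if self.minor_cn > self.major_cn:
            raise ValueError("minor_cn must not exceed major_cn")
        if self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")


@dataclass
class LOHRegion:
    """A genomic interval of recurrent LOH with its carrier samples."""

    chrom: str
    start_bp: int
    end_bp: int
    carrier_samples: frozenset[str]
    frequency: float


def read_ascn_segments(path) -> list[AscnSegment]:
    """Read an ASCN segment TSV: sample, chrom, start, end, major_cn, minor_cn."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample", "chrom", "start", "end", "major_cn", "minor_cn"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ASCN table is missing columns {missing}")
    return [
        AscnSegment(
            sample_id=str(r["sample"]),
            chrom=str(r["chrom"]),
            start_bp=int(r["start"]),
            end_bp=int(r["end"]),
            major_cn=float(r["major_cn"]),
            minor_cn=float(r["minor_cn"]),
        )
        for _, r in df.iterrows()
    ]


def call_loh(segments: Iterable[AscnSegment]) -> list[AscnSegment]:
    """Segments that have undergone LOH: minor copy number < 0.5."""
    return [s for s in segments if s.minor_cn < LOH_MINOR_CN_MAX]


def recurrent_loh_regions(
    loh_segments: Sequence[AscnSegment],
    n_samples: int,
    min_frequency: float = 0.2,
) -> list[LOHRegion]:
    """Maximal intervals where the fraction of samples with LOH >= min_frequency.

    Carrier counting is per base pair: segment endpoints are swept in
    coordinate order and maximal runs with carrier fraction at or above the
    threshold are merged into regions.  Each region is annotated with every
    sample whose LOH overlaps it.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if not 0 < min_frequency <= 1:
        raise ValueError("min_frequency must lie in (0, 1]")
    regions: list[LOHRegion] = []
    by_chrom: dict[str, list[AscnSegment]] = {}
    for s in loh_segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        segs = by_chrom[chrom]
        # event sweep over compressed coordinates; +1 at start, -1 past end
        events: dict[int, int] = {}
        for s in segs:
            events[s.start_bp] = events.get(s.start_bp, 0) + 1
            events[s.end_bp + 1] = events.get(s.end_bp + 1, 0) - 1
        positions = sorted(events)
        depth = 0
        run_start: int | None = None
        threshold = min_frequency * n_samples - 1e-9
        for k, pos in enumerate(positions):
            depth += events[pos]
            nxt = positions[k + 1] - 1 if k + 1 < len(positions) else None
            if depth >= threshold and run_start is None:
                run_start = pos
            elif depth < threshold and run_start is not None:
                regions.append(_make_region(chrom, run_start, pos - 1, segs, n_samples))
                run_start = None
            if nxt is None and run_start is not None:
                regions.append(_make_region(chrom, run_start, pos - 1, segs, n_samples))
                run_start = None
    return regions


def _make_region(
    chrom: str, start: int, end: int, segs: Sequence[AscnSegment], n_samples: int
) -> LOHRegion:
    carriers = frozenset(
        s.sample_id for s in segs if s.start_bp <= end and s.end_bp >= start
    )
    return LOHRegion(
        chrom=chrom,
        start_bp=start,
        end_bp=end,
        carrier_samples=carriers,
        frequency=len(carriers) / n_samples,
    )


def infer_tumor_haplotype(baf: BafProfile, region: LOHRegion) -> np.ndarray:
    """Haplotype of the retained chromosome copy inside an LOH region.

    Per marker within the region: BAF > 0.65 calls B, BAF < 0.35 calls A,
    and anything in between (or absent) is flagged missing/unreliable.
    Markers outside the region are missing.  Returns an int8 allele vector
    aligned to the profile's marker scaffold.
    """
    m = baf.markers
    hap = np.full(m.n_markers, MISSING, dtype=np.int8)
    inside = (
        (m.chrom == region.chrom)
        & (m.pos_bp >= region.start_bp)
        & (m.pos_bp <= region.end_bp)
    )
    vals = baf.baf
    with np.errstate(invalid="ignore"):
        hap[inside & (vals > BAF_B_THRESHOLD)] = ALLELE_B
        hap[inside & (vals < BAF_A_THRESHOLD)] = ALLELE_A
    return hap


def drop_unreliable_markers(panel: HaplotypePanel) -> HaplotypePanel:
    """Remove every marker that is missing/unreliable in any haplotype.

    A marker with an ambiguous BAF call in even one tumor is untrustworthy
    for exact matching, so the whole column is dropped and the marker
    scaffold subset accordingly.
    """
    keep = ~np.any(panel.alleles == MISSING, axis=0)
    if not np.any(keep):
        raise ValueError("every marker is unreliable in at least one haplotype")
    return panel.subset_markers(np.flatnonzero(keep))


_GENO_AA = 0
_GENO_AB = 1
_GENO_BB = 2


def reconstruct_lost_haplotype(tumor_hap: np.ndarray, constitutive_genotypes) -> np.ndarray:
    """Haplotype of the chromosome copy lost by LOH.

    Compares the retained tumor haplotype with the patient's unphased
    constitutive genotypes (0 = AA, 1 = AB, 2 = BB): at heterozygous
    markers the lost allele is the one not retained; at homozygous markers
    it equals the homozygous allele.  A tumor allele absent from the
    constitutive genotype is inconsistent and yields missing, as does a
    missing tumor call.
    """
    tumor_hap = np.asarray(tumor_hap, dtype=np.int8)
    geno = np.asarray(constitutive_genotypes, dtype=np.int8)
    if tumor_hap.shape != geno.shape:
        raise ValueError("tumor haplotype and constitutive genotypes differ in length")
    lost = np.full(tumor_hap.shape, MISSING, dtype=np.int8)
    het = geno == _GENO_AB
    lost[het & (tumor_hap == ALLELE_A)] = ALLELE_B
    lost[het & (tumor_hap == ALLELE_B)] = ALLELE_A
    lost[(geno == _GENO_AA) & (tumor_hap == ALLELE_A)] = ALLELE_A
    lost[(geno == _GENO_BB) & (tumor_hap == ALLELE_B)] = ALLELE_B
    return lost


def haplotype_error_rate(h1: np.ndarray, h2: np.ndarray) -> float:
    """Fraction of discordant alleles between two haplotypes.

    Positions missing in either haplotype are excluded pairwise; raises if
    no position remains comparable.
    """
    h1 = np.asarray(h1, dtype=np.int8)
    h2 = np.asarray(h2, dtype=np.int8)
    if h1.shape != h2.shape:
        raise ValueError("haplotypes differ in length")
    comparable = (h1 != MISSING) & (h2 != MISSING)
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("no comparable positions between the haplotypes")
    return float(np.sum(h1[comparable] != h2[comparable]) / n)


def loh_regions_to_bed(regions: Sequence[LOHRegion], path) -> None:
    """Write regions as BED (0-based half-open) plus a carrier-list column."""
    rows = []
    for r in regions:
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start_bp - 1,
                "end": r.end_bp,
                "frequency": r.frequency,
                "carriers": ",".join(sorted(r.carrier_samples)),
            }
        )
    pd.DataFrame(rows, columns=["chrom", "start", "end", "frequency", "carriers"]).to_csv(
        path, sep="\t", index=False, header=False
    )
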