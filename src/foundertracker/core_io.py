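"""Marker scaffolds, haplotype containers, and file formats.

The package works on a single ordered scaffold of biallelic SNP markers
(:class:`MarkerMap`), to which every haplotype panel, BAF profile and score
track is aligned.  Alleles follow the Illumina A/B nomenclature and are
stored as a compact ``int8`` matrix (``0`` = A, ``1`` = B, ``-1`` = missing).

Supported interchange formats:

* IMPUTE-style ``.hap`` / ``.legend`` phased reference panels,
* phased VCF (via :mod:`cyvcf2`; unphased or multi-allelic records are
  rejected),
* IMPUTE three-column genetic maps (``position  rate(cM/Mb)  cumulative cM``;
  the cumulative column is authoritative),
* TSV score tracks.

Coordinates are 1-based inclusive base pairs internally and in TSV output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALLELE_A",
    "ALLELE_B",
    "MISSING",
    "Origin",
    "MarkerMap",
    "HaplotypePanel",
    "BafProfile",
    "read_haplotype_panel",
    "read_genetic_map",
    "interpolate_cM",
    "write_score_track",
    "read_score_track",
]

ALLELE_A = np.int8(0)
ALLELE_B = np.int8(1)
MISSING = np.int8(-1)


class Origin(str, Enum):
    """Provenance of a haplotype panel."""

    TUMOR = "tumor"
    REFERENCE = "reference"
    SIMULATED = "simulated"


@dataclass
class MarkerMap:
    """Ordered scaffold of biallelic SNP markers.

    Parameters
    ----------
    marker_id : array of str
        Unique marker identifiers.
    chrom : array of str
        Chromosome of each marker; markers of one chromosome must be
        contiguous.
    pos_bp : array of int
        1-based physical positions, strictly increasing within a chromosome.
    pos_cM : array of float
        Genetic-map positions in centimorgans, non-decreasing within a
        chromosome.
    b_freq : array of float, optional
        Population frequency of the B allele per marker (NaN = unknown).
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cM: np.ndarray
    b_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cM = np.asarray(self.pos_cM, dtype=np.float64)
        if self.b_freq is None:
            self.b_freq = np.full(self.n_markers, np.nan)
        self.b_freq = np.asarray(self.b_freq, dtype=np.float64)
        n = self.n_markers
        for arr, name in [
            (self.chrom, "chrom"),
            (self.pos_bp, "pos_bp"),
            (self.pos_cM, "pos_cM"),
            (self.b_freq, "b_freq"),
        ]:
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
        for lo, hi in self.chrom_blocks():
            bp = self.pos_bp[lo:hi]
            cm = self.pos_cM[lo:hi]
            if np.any(np.diff(bp) <= 0):
                raise ValueError("pos_bp must be strictly increasing within a chromosome")
            if np.any(np.diff(cm) < 0):
                raise ValueError("pos_cM must be non-decreasing within a chromosome")
        with np.errstate(invalid="ignore"):
            bad = (self.b_freq < 0) | (self.b_freq > 1)
        if np.any(bad):
            raise ValueError("b_freq must lie in [0, 1]")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chrom_blocks(self) -> list[tuple[int, int]]:
        """Half-open index ranges [lo, hi) of each chromosome, in order."""
        if self.n_markers == 0:
            return []
        change = np.flatnonzero(self.chrom[1:] != self.chrom[:-1]) + 1
        bounds = np.concatenate([[0], change, [self.n_markers]])
        blocks = [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
        seen = set()
        for lo, _ in blocks:
            c = self.chrom[lo]
            if c in seen:
                raise ValueError(f"markers of chromosome {c!r} are not contiguous")
            seen.add(c)
        return blocks

    def subset(self, index: np.ndarray) -> "MarkerMap":
        """New map restricted to the given marker indices (order preserved)."""
        index = np.asarray(index)
        return MarkerMap(
            marker_id=self.marker_id[index],
            chrom=self.chrom[index],
            pos_bp=self.pos_bp[index],
            pos_cM=self.pos_cM[index],
            b_freq=self.b_freq[index],
        )

    def with_b_freq(self, b_freq: np.ndarray) -> "MarkerMap":
        return replace(self, b_freq=np.asarray(b_freq, dtype=np.float64))


@dataclass
class HaplotypePanel:
    """A set of haplotypes aligned to a :class:`MarkerMap`.

    ``alleles`` is an ``(n_haplotypes, n_markers)`` int8 matrix over
    {0 = A, 1 = B, -1 = missing}.
    """

    markers: MarkerMap
    haplotype_ids: list[str]
    alleles: np.ndarray
    origin: Origin = Origin.REFERENCE

    def __post_init__(self) -> None:
        self.haplotype_ids = list(self.haplotype_ids)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape != (len(self.haplotype_ids), self.markers.n_markers):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"{len(self.haplotype_ids)} haplotypes x {self.markers.n_markers} markers"
            )
        if len(set(self.haplotype_ids)) != len(self.haplotype_ids):
            raise ValueError("haplotype_ids must be unique")
        ok = np.isin(self.alleles, (ALLELE_A, ALLELE_B, MISSING))
        if not np.all(ok):
            raise ValueError("alleles must be 0 (A), 1 (B) or -1 (missing)")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def index_of(self, hap_id: str) -> int:
        try:
            return self.haplotype_ids.index(hap_id)
        except ValueError:
            raise KeyError(f"unknown haplotype id {hap_id!r}") from None

    def subset_markers(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        return HaplotypePanel(
            markers=self.markers.subset(index),
            haplotype_ids=list(self.haplotype_ids),
            alleles=self.alleles[:, index],
            origin=self.origin,
        )

    def subset_haplotypes(self, rows: Sequence[int]) -> "HaplotypePanel":
        rows = np.asarray(rows)
        return HaplotypePanel(
            markers=self.markers,
            haplotype_ids=[self.haplotype_ids[i] for i in rows],
            alleles=self.alleles[rows],
            origin=self.origin,
        )


@dataclass
class BafProfile:
    """Per-marker B-allele frequencies, BAF = B/(A+B), for one sample."""

    markers: MarkerMap
    sample_id: str
    baf: np.ndarray

    def __post_init__(self) -> None:
        self.baf = np.asarray(self.baf, dtype=np.float64)
        if self.baf.shape != (self.markers.n_markers,):
            raise ValueError("baf length does not match marker count")
        with np.errstate(invalid="ignore"):
            bad = (self.baf < 0) | (self.baf > 1)
        if np.any(bad):
            raise ValueError("BAF values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# haplotype panel readers
# ---------------------------------------------------------------------------


def _read_hap_legend(
    hap_path: str | os.PathLike,
    legend_path: str | os.PathLike | None = None,
    chrom: str = "1",
    origin: Origin = Origin.REFERENCE,
) -> HaplotypePanel:
    """Read an IMPUTE-style .hap/.legend pair.

    The .hap file has one row per marker and one 0/1 column per haplotype
    (0 = A, 1 = B); the legend supplies marker ids and positions.
    """
    hap_path = os.fspath(hap_path)
    if legend_path is None:
        base = hap_path[:-4] if hap_path.endswith(".hap") else hap_path
        legend_path = base + ".legend"
        if not os.path.exists(legend_path):
            raise FileNotFoundError(f"no legend file found at {legend_path}")
    legend = pd.read_csv(legend_path, sep=r"\s+")
    cols = {c.lower(): c for c in legend.columns}
    id_col = cols.get("id", legend.columns[0])
    pos_col = cols.get("position", cols.get("pos", legend.columns[1]))
    pos = legend[pos_col].to_numpy(dtype=np.int64)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("legend positions must be sorted and strictly increasing")

    rows: list[np.ndarray] = []
    with open(hap_path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            rows.append(np.array(fields, dtype=np.int8))
    if len(rows) != len(legend):
        raise ValueError(
            f".hap has {len(rows)} marker rows but legend lists {len(legend)} markers"
        )
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValueError(".hap rows have inconsistent haplotype counts")
    alleles = np.vstack(rows).T  # (n_hap, n_markers)
    markers = MarkerMap(
        marker_id=legend[id_col].astype(str).to_numpy(dtype=object),
        chrom=np.full(len(legend), chrom, dtype=object),
        pos_bp=pos,
        pos_cM=np.zeros(len(legend)),
    )
    ids = [f"hap{i + 1}" for i in range(alleles.shape[0])]
    return HaplotypePanel(markers=markers, haplotype_ids=ids, alleles=alleles, origin=origin)


def _read_phased_vcf(path: str | os.PathLike, origin: Origin = Origin.REFERENCE) -> HaplotypePanel:
    """Read a phased, biallelic VCF into a two-haplotypes-per-sample panel."""
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    ids: list[str] = []
    for s in samples:
        ids.extend([f"{s}_1", f"{s}_2"])
    marker_id, chrom, pos = [], [], []
    cols: list[np.ndarray] = []
    last = None
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic record at {v.CHROM}:{v.POS} is not supported")
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[2]
            if not phased:
                raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS}, sample {samples[i]}")
            col[2 * i] = MISSING if a0 < 0 else a0
            col[2 * i + 1] = MISSING if a1 < 0 else a1
        key = (v.CHROM, v.POS)
        if last is not None and last[0] == v.CHROM and v.POS <= last[1]:
            raise ValueError("VCF records must be sorted by position")
        last = key
        marker_id.append(v.ID if v.ID else f"{v.CHROM}:{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        cols.append(col)
    if not cols:
        raise ValueError(f"no variant records in {path}")
    markers = MarkerMap(
        marker_id=np.array(marker_id, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(pos, dtype=np.int64),
        pos_cM=np.zeros(len(pos)),
    )
    return HaplotypePanel(
        markers=markers, haplotype_ids=ids, alleles=np.column_stack(cols), origin=origin
    )


def read_haplotype_panel(
    path: str | os.PathLike,
    format: str = "hap_legend",
    **kwargs,
) -> HaplotypePanel:
    """Load a phased haplotype panel.

    Parameters
    ----------
    path
        For ``format='hap_legend'`` the ``.hap`` file (a sibling ``.legend``
        is looked up unless ``legend_path`` is given); for
        ``format='phased_vcf'`` the VCF file.
    format
        ``'hap_legend'`` or ``'phased_vcf'``.
    """
    if format == "hap_legend":
        return _read_hap_legend(path, **kwargs)
    if format == "phased_vcf":
        return _read_phased_vcf(path, **kwargs)
    raise ValueError(f"unknown panel format {format!r}")


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


def read_genetic_map(path: str | os.PathLike) -> pd.DataFrame:
    """Read an IMPUTE three-column genetic map.

    Columns: physical position (bp), local recombination rate (cM/Mb) and
    cumulative genetic position (cM).  A header line is tolerated.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.shape[1] < 3:
        raise ValueError("genetic map needs 3 columns: position, rate, cumulative cM")
    df = df.iloc[:, :3]
    df.columns = ["position", "rate_cM_Mb", "cM"]
    return df


def interpolate_cM(map_table: pd.DataFrame | str | os.PathLike, positions_bp) -> np.ndarray:
    """Genetic positions (cM) for physical positions by piecewise-linear
    interpolation of the cumulative-cM column.

    Positions outside the map range are extrapolated with the rate of the
    nearest map interval (or the map's own rate column for a single-knot
    map).
    """
    if not isinstance(map_table, pd.DataFrame):
        map_table = read_genetic_map(map_table)
    if len(map_table) == 0:
        raise ValueError("empty genetic map")
    pos = map_table["position"].to_numpy(dtype=np.float64)
    cm = map_table["cM"].to_numpy(dtype=np.float64)
    order = np.argsort(pos)
    pos, cm = pos[order], cm[order]
    q = np.asarray(positions_bp, dtype=np.float64)
    out = np.interp(q, pos, cm)
    if len(pos) >= 2:
        rate_lo = (cm[1] - cm[0]) / (pos[1] - pos[0])
        rate_hi = (cm[-1] - cm[-2]) / (pos[-1] - pos[-2])
    else:
        rate_lo = rate_hi = map_table["rate_cM_Mb"].iloc[0] * 1e-6
    left = q < pos[0]
    right = q > pos[-1]
    out[left] = cm[0] - (pos[0] - q[left]) * rate_lo
    out[right] = cm[-1] + (q[right] - pos[-1]) * rate_hi
    return out


# ---------------------------------------------------------------------------
# score tracks
# ---------------------------------------------------------------------------

_TRACK_COLUMNS = ["marker_id", "chrom", "pos_bp", "pos_cM", "ibd_score", "p_value", "q_value"]


def write_score_track(track, path: str | os.PathLike) -> None:
    """Write a per-marker score track as TSV, ordered by (chrom, pos_bp)."""
    m = track.markers
    df = pd.DataFrame(
        {
            "marker_id": m.marker_id,
            "chrom": m.chrom,
            "pos_bp": m.pos_bp,
            "pos_cM": m.pos_cM,
            "ibd_score": track.ibd_score,
            "p_value": track.p_value,
            "q_value": track.q_value,
        }
    )
    df = df.sort_values(["chrom", "pos_bp"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_score_track(path: str | os.PathLike):
    """Read a score track TSV written by :func:`write_score_track`."""
    from .ibd_score import ScoreTrack

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score track is missing columns {missing}")
    markers = MarkerMap(
        marker_id=df["marker_id"].astype(str).to_numpy(dtype=object),
        chrom=df["chrom"].astype(str).to_numpy(dtype=object),
        pos_bp=df["pos_bp"].to_numpy(dtype=np.int64),
        pos_cM=df["pos_cM"].to_numpy(dtype=np.float64),
    )
    return ScoreTrack(
        markers=markers,
        ibd_score=df["ibd_score"].to_numpy(dtype=np.float64),
        p_value=df["p_value"].to_numpy(dtype=np.float64),
        q_value=df["q_value"].to_numpy(dtype=np.float64),
    )
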