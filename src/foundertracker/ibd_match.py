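"""Pairwise IBD segment detection in phased haplotype panels.

This is a seed-and-extend matcher in the GERMLINE style: each chromosome is
partitioned into fixed, consecutive words of ``bits`` markers; two
haplotypes sharing an identical word are candidate IBD pairs, and every
candidate match is extended marker-by-marker at both flanks while the
alleles remain identical (for the mismatch-free configuration
``err_hom = 0``).  A maximal identical run is reported when its genetic
length reaches ``min_m`` centimorgans.

With ``err_hom = 0`` the reported segments are exactly the maximal
identical allele runs that (a) contain at least one fully aligned word and
(b) span at least ``min_m`` cM.  Whenever ``min_m`` corresponds to at least
``2 * bits - 1`` markers, every run passing the length filter necessarily
contains an aligned word, so the output coincides with the exhaustive scan
implemented by :func:`brute_force_ibd`.

The defaults (``min_m = 0.4`` cM, ``err_hom = 0``, ``bits = 5``) are the
stringent settings appropriate for tumor haplotypes read directly off LOH
regions, where the haplotyping error rate is negligible: short seeds give
accurate segment boundaries and no mismatches need to be tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .core_io import MISSING, HaplotypePanel

__all__ = ["MatchParams", "IBDSegment", "find_pairwise_ibd", "brute_force_ibd"]

_PAIR_CHUNK = 2048


@dataclass(frozen=True)
class MatchParams:
    """Matcher configuration.

    min_m : minimum genetic length of a reported segment, in cM.
    err_hom : number of mismatching markers tolerated inside a match.
    bits : number of markers per exact-matching seed word.
    """

    min_m: float = 0.4
    err_hom: int = 0
    bits: int = 5

    def __post_init__(self) -> None:
        if self.min_m <= 0:
            raise ValueError("min_m must be positive")
        if self.err_hom < 0:
            raise ValueError("err_hom must be non-negative")
        if not 1 <= self.bits <= 62:
            raise ValueError("bits must be in [1, 62]")


@dataclass
class IBDSegment:
    """A maximal identical stretch shared by two haplotypes.

    Marker indices are inclusive and refer to the panel's marker scaffold;
    ``score`` is filled by the scoring stage (NaN until then).
    """

    hap1_id: str
    hap2_id: str
    start_idx: int
    end_idx: int
    length_cM: float
    score: float = field(default=float("nan"))


def _check_panel(panel: HaplotypePanel) -> None:
    if panel.n_haplotypes < 2:
        raise ValueError("need at least two haplotypes to detect pairwise IBD")
    if np.any(panel.alleles == MISSING):
        raise ValueError(
            "panel contains missing alleles; run drop_unreliable_markers first"
        )


def _runs_dense(
    H: np.ndarray,
    cm: np.ndarray,
    pi: np.ndarray,
    pj: np.ndarray,
    params: MatchParams,
    offset: int,
    require_word: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run extraction from the full per-marker equality matrix."""
    m = H.shape[1]
    out_pair, out_a, out_b, out_len = [], [], [], []
    for lo in range(0, len(pi), _PAIR_CHUNK):
        ii = pi[lo : lo + _PAIR_CHUNK]
        jj = pj[lo : lo + _PAIR_CHUNK]
        eq = H[ii] == H[jj]
        padded = np.zeros((len(ii), m + 2), dtype=np.int8)
        padded[:, 1:-1] = eq
        d = np.diff(padded, axis=1)
        rs, cs = np.nonzero(d == 1)
        _, ce = np.nonzero(d == -1)
        # starts/ends interleave consistently in row-major order
        starts = cs
        ends = ce - 1
        lengths = cm[ends] - cm[starts]
        keep = lengths >= params.min_m - 1e-12
        if require_word:
            first_word = -(-starts // params.bits)  # ceil division
            keep &= first_word * params.bits + params.bits - 1 <= ends
        out_pair.append(lo + rs[keep])
        out_a.append(starts[keep] + offset)
        out_b.append(ends[keep] + offset)
        out_len.append(lengths[keep])
    return (
        np.concatenate(out_pair),
        np.concatenate(out_a),
        np.concatenate(out_b),
        np.concatenate(out_len),
    )


def _runs_for_pairs(
    H: np.ndarray,
    cm: np.ndarray,
    pi: np.ndarray,
    pj: np.ndarray,
    params: MatchParams,
    offset: int = 0,
    require_word: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Maximal identical runs for the given haplotype-row pairs.

    Returns (pair_index, start, end, length_cM) arrays with marker indices
    shifted by ``offset``.  ``require_word`` keeps only runs containing at
    least one fully aligned ``bits``-marker word (the seedable runs).

    The seedable path screens at the word level first: any reported run of
    at least ``min_m`` cM must contain K consecutive equal aligned words
    (K derived from the sparsest stretch of the genetic map), so candidate
    word runs are located in the much smaller word-equality matrix and
    only their flanks are inspected marker-by-marker.
    """
    empty = (
        np.array([], dtype=np.int64),
        np.array([], dtype=np.int64),
        np.array([], dtype=np.int64),
        np.array([], dtype=np.float64),
    )
    if len(pi) == 0:
        return empty
    m = H.shape[1]
    bits = params.bits
    nw = m // bits
    if not require_word or nw < 2:
        return _runs_dense(H, cm, pi, pj, params, offset, require_word)

    # minimal marker count of any run spanning min_m cM, over the map
    reach = np.searchsorted(cm, cm + params.min_m - 1e-12, side="left")
    fits = reach < m
    if not np.any(fits):
        return empty  # chromosome is genetically shorter than min_m
    min_markers = int(np.min(reach[fits] - np.flatnonzero(fits))) + 1
    k_words = max(1, (min_markers - 2 * (bits - 1)) // bits)

    word_dtype = np.uint8 if bits <= 8 else np.uint64
    weights = word_dtype(1) << np.arange(bits, dtype=word_dtype)
    V = (H[:, : nw * bits].reshape(H.shape[0], nw, bits).astype(word_dtype) * weights).sum(
        axis=2, dtype=word_dtype
    )

    out_pair, out_a, out_b, out_len = [], [], [], []
    chunk = _PAIR_CHUNK * 8
    for lo in range(0, len(pi), chunk):
        ii = pi[lo : lo + chunk]
        jj = pj[lo : lo + chunk]
        EW = V[ii] == V[jj]
        C = EW.copy()
        for s in range(1, k_words):
            C[:, : nw - s] &= EW[:, s:]
        if k_words > 1:
            C[:, nw - k_words + 1 :] = False
        rs, ws = np.nonzero(C)
        if len(rs) == 0:
            continue
        head = (ws == 0) | ~EW[rs, np.maximum(ws - 1, 0)]
        rs, ws = rs[head], ws[head]
        # word-level right extension of each candidate run
        we = ws + k_words - 1
        act = np.arange(len(rs))
        while len(act):
            can = act[we[act] + 1 < nw]
            if len(can) == 0:
                break
            good = can[EW[rs[can], we[can] + 1]]
            if len(good) == 0:
                break
            we[good] += 1
            act = good
        hap_i = ii[rs]
        hap_j = jj[rs]
        a = ws * bits
        b = we * bits + bits - 1
        # marker-level flank extension (< bits markers each side)
        for _ in range(bits - 1):
            am1 = np.maximum(a - 1, 0)
            ok = (a > 0) & (H[hap_i, am1] == H[hap_j, am1])
            a[ok] -= 1
            bp1 = np.minimum(b + 1, m - 1)
            ok = (b < m - 1) & (H[hap_i, bp1] == H[hap_j, bp1])
            b[ok] += 1
        lengths = cm[b] - cm[a]
        keep = lengths >= params.min_m - 1e-12
        out_pair.append(lo + rs[keep])
        out_a.append(a[keep] + offset)
        out_b.append(b[keep] + offset)
        out_len.append(lengths[keep])
    if not out_pair:
        return empty
    return (
        np.concatenate(out_pair),
        np.concatenate(out_a),
        np.concatenate(out_b),
        np.concatenate(out_len),
    )


def _all_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    pi, pj = np.triu_indices(n, k=1)
    return pi.astype(np.int64), pj.astype(np.int64)


def _exact_segments_arrays(
    panel: HaplotypePanel, params: MatchParams, require_word: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All maximal identical runs >= min_m for every haplotype pair.

    Returns (hap_i, hap_j, start, end, length_cM) with i < j, ordered by
    (i, j, start).  Shared fast path behind :func:`find_pairwise_ibd` and
    the null-distribution machinery.
    """
    H = panel.alleles
    cm = panel.markers.pos_cM
    pi, pj = _all_pairs(panel.n_haplotypes)
    segs_i, segs_j, segs_a, segs_b, segs_l = [], [], [], [], []
    for lo, hi in panel.markers.chrom_blocks():
        p, a, b, ln = _runs_for_pairs(
            H[:, lo:hi], cm[lo:hi], pi, pj, params, offset=lo, require_word=require_word
        )
        segs_i.append(pi[p])
        segs_j.append(pj[p])
        segs_a.append(a)
        segs_b.append(b)
        segs_l.append(ln)
    i = np.concatenate(segs_i) if segs_i else np.array([], dtype=np.int64)
    j = np.concatenate(segs_j) if segs_j else np.array([], dtype=np.int64)
    a = np.concatenate(segs_a) if segs_a else np.array([], dtype=np.int64)
    b = np.concatenate(segs_b) if segs_b else np.array([], dtype=np.int64)
    ln = np.concatenate(segs_l) if segs_l else np.array([], dtype=np.float64)
    order = np.lexsort((a, j, i))
    return i[order], j[order], a[order], b[order], ln[order]


def _segments_from_arrays(
    panel: HaplotypePanel,
    arrays: tuple[np.ndarray, ...],
) -> list[IBDSegment]:
    ids = panel.haplotype_ids
    i, j, a, b, ln = arrays
    return [
        IBDSegment(
            hap1_id=ids[ii],
            hap2_id=ids[jj],
            start_idx=int(aa),
            end_idx=int(bb),
            length_cM=float(ll),
        )
        for ii, jj, aa, bb, ll in zip(i, j, a, b, ln)
    ]


def _sort_key(panel: HaplotypePanel, segs: list[IBDSegment]) -> list[IBDSegment]:
    return sorted(segs, key=lambda s: (s.hap1_id, s.hap2_id, s.start_idx))


def find_pairwise_ibd(panel: HaplotypePanel, params: MatchParams | None = None) -> list[IBDSegment]:
    """Detect pairwise IBD segments by word hashing and flank extension.

    Every maximal identical run containing at least one aligned seed word
    and spanning at least ``params.min_m`` cM is reported exactly once per
    haplotype pair, sorted by (hap1_id, hap2_id, start_idx).

    For ``err_hom > 0`` matches are extended through mismatching markers
    until more than ``err_hom`` mismatches accumulate, and trailing
    mismatches are trimmed back to the outermost matching marker.
    """
    params = params or MatchParams()
    _check_panel(panel)
    if params.err_hom == 0:
        arrays = _exact_segments_arrays(panel, params)
        segs = _segments_from_arrays(panel, arrays)
    else:
        segs = _mismatch_tolerant_segments(panel, params)
    return _sort_key(panel, segs)


def brute_force_ibd(panel: HaplotypePanel, params: MatchParams | None = None) -> list[IBDSegment]:
    """Exhaustive-scan oracle: every maximal identical run >= min_m cM.

    Scans each haplotype pair marker-by-marker with no seeding or hashing;
    intended for small panels as an independent check of
    :func:`find_pairwise_ibd`.
    """
    params = params or MatchParams()
    _check_panel(panel)
    cm = panel.markers.pos_cM
    H = panel.alleles
    ids = panel.haplotype_ids
    segs: list[IBDSegment] = []
    for i in range(panel.n_haplotypes):
        for j in range(i + 1, panel.n_haplotypes):
            for lo, hi in panel.markers.chrom_blocks():
                k = lo
                while k < hi:
                    if H[i, k] == H[j, k]:
                        start = k
                        while k < hi and H[i, k] == H[j, k]:
                            k += 1
                        end = k - 1
                        if cm[end] - cm[start] >= params.min_m - 1e-12:
                            segs.append(
                                IBDSegment(
                                    hap1_id=ids[i],
                                    hap2_id=ids[j],
                                    start_idx=start,
                                    end_idx=end,
                                    length_cM=float(cm[end] - cm[start]),
                                )
                            )
                    else:
                        k += 1
    return _sort_key(panel, segs)


def _mismatch_tolerant_segments(panel: HaplotypePanel, params: MatchParams) -> list[IBDSegment]:
    # Best-effort err_hom > 0 path: merge consecutive identical runs across
    # up to err_hom single-marker mismatches, then trim trailing mismatches.
    cm = panel.markers.pos_cM
    H = panel.alleles
    ids = panel.haplotype_ids
    segs: list[IBDSegment] = []
    for i in range(panel.n_haplotypes):
        for j in range(i + 1, panel.n_haplotypes):
            for lo, hi in panel.markers.chrom_blocks():
                mism = np.flatnonzero(H[i, lo:hi] != H[j, lo:hi]) + lo
                bounds = np.concatenate([[lo - 1], mism, [hi]])
                # window of runs spanning <= err_hom internal mismatches
                n_runs = len(bounds) - 1
                k = 0
                while k < n_runs:
                    k2 = min(k + params.err_hom, n_runs - 1)
                    start = bounds[k] + 1
                    end = bounds[k2 + 1] - 1
                    if start <= end and cm[end] - cm[start] >= params.min_m - 1e-12:
                        segs.append(
                            IBDSegment(
                                hap1_id=ids[i],
                                hap2_id=ids[j],
                                start_idx=int(start),
                                end_idx=int(end),
                                length_cM=float(cm[end] - cm[start]),
                            )
                        )
                        k = k2 + 1
                    else:
                        k += 1
    return segs


def segments_to_dataframe(panel: HaplotypePanel, segments: Iterable[IBDSegment]):
    """GERMLINE .match-like table of segments."""
    import pandas as pd

    m = panel.markers
    rows = []
    for s in segments:
        rows.append(
            {
                "hap1": s.hap1_id,
                "hap2": s.hap2_id,
                "chrom": m.chrom[s.start_idx],
                "start_bp": int(m.pos_bp[s.start_idx]),
                "end_bp": int(m.pos_bp[s.end_idx]),
                "start_idx": s.start_idx,
                "end_idx": s.end_idx,
                "length_cM": s.length_cM,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "hap1",
            "hap2",
            "chrom",
            "start_bp",
            "end_bp",
            "start_idx",
            "end_idx",
            "length_cM",
        ],
    )
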