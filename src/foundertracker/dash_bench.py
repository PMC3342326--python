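"""DASH-style benchmark: cluster shared haplotypes, test tumor enrichment.

This is the frequency-based alternative to the length-aware IBD score: the
chromosome is tiled into fixed genetic-distance windows, haplotypes are
linked whenever a pairwise IBD segment fully spans a window, and each
connected component is a cluster of haplotypes presumed to share one
ancestral segment.  Matching is run on the combined tumor + reference
panel, and each cluster is tested for over-representation of tumor
haplotypes with a one-sided Fisher's exact test, BH-corrected across
clusters.  The test sees only cluster membership counts — the length of
the shared haplotype plays no role, which is exactly the property the
length-aware IBD score is designed to improve on.

The published DASH algorithm refines clusters with density thresholds and
windowed re-phasing; here connected components with a minimum size stand
in for that machinery, which is sufficient for a frequency-only benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .core_io import HaplotypePanel, MarkerMap, Origin
from .ibd_score import ScoreTrack, bh_qvalues
from .ibd_match import IBDSegment, MatchParams, _exact_segments_arrays

__all__ = ["HaplotypeCluster", "dash_clusters", "fisher_enrichment", "dash_scan"]

DEFAULT_WINDOW_CM = 0.2
DEFAULT_MIN_CLUSTER = 2


@dataclass
class HaplotypeCluster:
    """A set of haplotypes sharing an identical stretch over >= 1 window."""

    window: tuple[int, int]  # inclusive marker-index span of the window run
    members: frozenset[str]
    n_tumor: int = 0
    n_reference: int = 0
    p_value: float = field(default=float("nan"))
    q_value: float = field(default=float("nan"))


def _connected_components(e1: np.ndarray, e2: np.ndarray) -> list[list[int]]:
    """Connected components of an edge list, by min-label propagation."""
    nodes, inv = np.unique(np.concatenate([e1, e2]), return_inverse=True)
    a, b = inv[: len(e1)], inv[len(e1) :]
    lab = np.arange(len(nodes))
    while True:
        m = np.minimum(lab[a], lab[b])
        np.minimum.at(lab, a, m)
        np.minimum.at(lab, b, m)
        new = lab[lab]  # pointer jumping
        if np.array_equal(new, lab):
            break
        lab = new
    order = np.argsort(lab, kind="stable")
    bounds = np.flatnonzero(np.diff(lab[order])) + 1
    return [nodes[idx].tolist() for idx in np.split(order, bounds)]


def _cluster_windows(
    markers: MarkerMap,
    seg_i: np.ndarray,
    seg_j: np.ndarray,
    seg_a: np.ndarray,
    seg_b: np.ndarray,
    window_cM: float,
    min_cluster: int,
) -> list[tuple[int, int, frozenset[int]]]:
    """Connected-component clusters per window, merged across adjacent
    windows when the member sets are identical.

    Returns (marker_lo, marker_hi, member_row_set) tuples.
    """
    cm = markers.pos_cM
    out: list[tuple[int, int, frozenset[int]]] = []
    for lo, hi in markers.chrom_blocks():
        base, top = cm[lo], cm[hi - 1]
        n_win = int(np.floor((top - base) / window_cM))
        if n_win < 1:
            continue
        in_block = (seg_a >= lo) & (seg_b < hi)
        a_cm = cm[seg_a[in_block]]
        b_cm = cm[seg_b[in_block]]
        ii = seg_i[in_block]
        jj = seg_j[in_block]
        w_first = np.ceil((a_cm - base) / window_cM - 1e-9).astype(np.int64)
        w_last = np.floor((b_cm - base) / window_cM + 1e-9).astype(np.int64) - 1
        w_first = np.maximum(w_first, 0)
        w_last = np.minimum(w_last, n_win - 1)
        span = w_last - w_first + 1
        valid = span > 0
        if not np.any(valid):
            continue
        reps = span[valid]
        wins = np.repeat(w_first[valid], reps) + _ranges(reps)
        ei = np.repeat(ii[valid], reps)
        ej = np.repeat(jj[valid], reps)
        order = np.argsort(wins, kind="stable")
        wins, ei, ej = wins[order], ei[order], ej[order]
        bounds = np.searchsorted(wins, np.arange(n_win + 1))

        prev: dict[frozenset[int], int] = {}  # member set -> first window of run
        for w in range(n_win):
            s, e = bounds[w], bounds[w + 1]
            current: dict[frozenset[int], int] = {}
            if e > s:
                for nodes in _connected_components(ei[s:e], ej[s:e]):
                    if len(nodes) >= min_cluster:
                        key = frozenset(nodes)
                        current[key] = prev.get(key, w)
            for key, w0 in prev.items():
                if key not in current:
                    out.append(_emit(markers, lo, base, window_cM, w0, w - 1, key))
            prev = current
        for key, w0 in prev.items():
            out.append(_emit(markers, lo, base, window_cM, w0, n_win - 1, key))
    return out


def _ranges(counts: np.ndarray) -> np.ndarray:
    # concatenation of arange(c) for each c in counts
    total = int(counts.sum())
    starts = np.repeat(np.cumsum(counts) - counts, counts)
    return np.arange(total) - starts


def _emit(markers, lo, base, window_cM, w0, w1, key):
    cm = markers.pos_cM
    cm_lo = base + w0 * window_cM
    cm_hi = base + (w1 + 1) * window_cM
    m_lo = lo + int(np.searchsorted(cm[lo:], cm_lo - 1e-9, side="left"))
    m_hi = lo + int(np.searchsorted(cm[lo:], cm_hi + 1e-9, side="right")) - 1
    return (m_lo, m_hi, key)


def dash_clusters(
    segments: Sequence[IBDSegment],
    combined_panel: HaplotypePanel,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    window_cM: float = DEFAULT_WINDOW_CM,
    tumor_ids: set[str] | None = None,
) -> list[HaplotypeCluster]:
    """Cluster haplotypes that share identical segments across windows.

    The chromosome is tiled into consecutive ``window_cM`` windows; two
    haplotypes are linked in a window iff one of their pairwise segments
    fully spans it, clusters are the connected components of size
    >= ``min_cluster``, and clusters with identical membership in adjacent
    windows are merged.  ``tumor_ids`` fills the tumor/reference member
    counts (all members count as reference when omitted).
    """
    idx = {h: k for k, h in enumerate(combined_panel.haplotype_ids)}
    n = len(segments)
    seg_i = np.fromiter((idx[s.hap1_id] for s in segments), dtype=np.int64, count=n)
    seg_j = np.fromiter((idx[s.hap2_id] for s in segments), dtype=np.int64, count=n)
    seg_a = np.fromiter((s.start_idx for s in segments), dtype=np.int64, count=n)
    seg_b = np.fromiter((s.end_idx for s in segments), dtype=np.int64, count=n)
    raw = _cluster_windows(
        combined_panel.markers, seg_i, seg_j, seg_a, seg_b, window_cM, min_cluster
    )
    ids = combined_panel.haplotype_ids
    tumor_ids = tumor_ids or set()
    clusters = []
    for m_lo, m_hi, rows in raw:
        members = frozenset(ids[r] for r in rows)
        n_tum = sum(1 for h in members if h in tumor_ids)
        clusters.append(
            HaplotypeCluster(
                window=(m_lo, m_hi),
                members=members,
                n_tumor=n_tum,
                n_reference=len(members) - n_tum,
            )
        )
    clusters.sort(key=lambda c: (c.window, sorted(c.members)))
    return clusters


def fisher_enrichment(
    cluster: HaplotypeCluster, n_tumor_total: int, n_ref_total: int
) -> float:
    """One-sided Fisher's exact p for tumor over-representation in a cluster.

    Upper hypergeometric tail of the 2x2 table (in-cluster vs out) x
    (tumor vs reference): the probability of drawing at least the observed
    number of tumor haplotypes when sampling the cluster's size from the
    combined panel.
    """
    if cluster.n_tumor > n_tumor_total or cluster.n_reference > n_ref_total:
        raise ValueError("cluster counts exceed the stated panel totals")
    size = cluster.n_tumor + cluster.n_reference
    total = n_tumor_total + n_ref_total
    if size == 0:
        return 1.0
    return float(hypergeom.sf(cluster.n_tumor - 1, total, n_tumor_total, size))


def dash_scan(
    tumors: HaplotypePanel,
    reference: HaplotypePanel,
    params: MatchParams | None = None,
    q_threshold: float = 0.01,
    window_cM: float = DEFAULT_WINDOW_CM,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
) -> tuple[ScoreTrack, list[HaplotypeCluster]]:
    """Full benchmark scan: combined matching, clustering, Fisher, BH.

    Returns a per-marker track whose ``p_value``/``q_value`` are the
    minimum Fisher p / BH q over the clusters whose window covers each
    marker (1 where none; ``ibd_score`` is the number of covering
    clusters), together with the tested clusters.  ``q_threshold`` is the
    conventional cutoff used downstream to call significant markers.
    """
    params = params or MatchParams()
    if tumors.markers.n_markers != reference.markers.n_markers or not np.array_equal(
        tumors.markers.marker_id, reference.markers.marker_id
    ):
        raise ValueError("tumor and reference panels must share one marker scaffold")
    t_ids = [f"tumor:{h}" for h in tumors.haplotype_ids]
    r_ids = [f"ref:{h}" for h in reference.haplotype_ids]
    combined = HaplotypePanel(
        markers=tumors.markers,
        haplotype_ids=t_ids + r_ids,
        alleles=np.vstack([tumors.alleles, reference.alleles]),
        origin=Origin.REFERENCE,
    )
    i, j, a, b, _ = _exact_segments_arrays(combined, params)
    raw = _cluster_windows(combined.markers, i, j, a, b, window_cM, min_cluster)
    n_tumor = tumors.n_haplotypes
    clusters: list[HaplotypeCluster] = []
    ids = combined.haplotype_ids
    for m_lo, m_hi, rows in raw:
        n_tum = sum(1 for r in rows if r < n_tumor)
        clusters.append(
            HaplotypeCluster(
                window=(m_lo, m_hi),
                members=frozenset(ids[r] for r in rows),
                n_tumor=n_tum,
                n_reference=len(rows) - n_tum,
            )
        )
    m = combined.markers.n_markers
    n_cover = np.zeros(m)
    p_track = np.ones(m)
    q_track = np.ones(m)
    if clusters:
        sizes = np.array([c.n_tumor + c.n_reference for c in clusters])
        tum_counts = np.array([c.n_tumor for c in clusters])
        total = n_tumor + reference.n_haplotypes
        pvals = hypergeom.sf(tum_counts - 1, total, n_tumor, sizes)
        qvals = bh_qvalues(pvals)
        for c, p, q in zip(clusters, pvals, qvals):
            c.p_value = float(p)
            c.q_value = float(q)
            lo, hi = c.window
            n_cover[lo : hi + 1] += 1
            np.minimum(p_track[lo : hi + 1], p, out=p_track[lo : hi + 1])
            np.minimum(q_track[lo : hi + 1], q, out=q_track[lo : hi + 1])
    track = ScoreTrack(
        markers=tumors.markers, ibd_score=n_cover, p_value=p_track, q_value=q_track
    )
    return track, clusters


def clusters_to_dataframe(clusters: Sequence[HaplotypeCluster], markers: MarkerMap):
    import pandas as pd

    rows = []
    for c in clusters:
        lo, hi = c.window
        rows.append(
            {
                "chrom": markers.chrom[lo],
                "window_start_bp": int(markers.pos_bp[lo]),
                "window_end_bp": int(markers.pos_bp[hi]),
                "n_tumor": c.n_tumor,
                "n_reference": c.n_reference,
                "p": c.p_value,
                "q": c.q_value,
                "members": ",".join(sorted(c.members)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "window_start_bp",
            "window_end_bp",
            "n_tumor",
            "n_reference",
            "p",
            "q",
            "members",
        ],
    )
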