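"""Per-SNP IBD scoring and significance against a resampled Gumbel null.

A pairwise IBD segment sharing haplotype ``H`` over markers ``i`` is scored

    S = -2 * sum_i ln f(H_i),      f(H_i) = Bfreq_i if H_i = B else 1 - Bfreq_i

i.e. the negative log of the probability that two independent haplotypes
both carry the observed allele at every SNP of the segment: long segments
of rare alleles score high, and a run of common alleles scores low even
when physically long.  The per-SNP IBD score is the sum of S over all
pairwise segments covering that SNP, so it grows with both the length and
the recurrence of sharing.

Linkage disequilibrium inflates IBD scores systematically in high-LD
regions, so raw scores are not comparable across the genome.  The null
distribution at each SNP is therefore built empirically: many subsets of
the same size as the tumor panel are sampled from a reference panel of
phased haplotypes, the full scoring pipeline is run on each subset, and a
Gumbel (type-I extreme value) distribution is fitted per SNP to the subset
scores.  The Gumbel is used rather than a Gaussian because per-SNP scores
are sums over the few largest sharing events and are strongly
right-skewed; it also yields more conservative tail p-values.  P-values
are the fitted upper-tail probabilities and q-values follow by
Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_io import ALLELE_B, HaplotypePanel, MarkerMap, MISSING
from .ibd_match import IBDSegment, MatchParams, _exact_segments_arrays

__all__ = [
    "FREQ_CLAMP",
    "ScoreTrack",
    "GumbelNull",
    "SignificantRegion",
    "segment_score",
    "score_segments",
    "per_snp_scores",
    "estimate_b_freqs",
    "fit_gumbel",
    "build_null",
    "score_pvalues",
    "bh_qvalues",
    "significant_regions",
    "estimate_generations",
    "foundertracker_scan",
]

#: allele frequencies are clamped to [FREQ_CLAMP, 1 - FREQ_CLAMP] so that
#: monomorphic markers cannot contribute infinite scores
FREQ_CLAMP = 1e-4

#: scale assigned to markers whose null scores are constant across subsets
_DEGENERATE_BETA = 1e-8

_EULER_GAMMA = 0.5772156649015329


@dataclass
class ScoreTrack:
    """Per-marker IBD score with Gumbel-null p-value and BH q-value."""

    markers: MarkerMap
    ibd_score: np.ndarray
    p_value: np.ndarray | None = None
    q_value: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = self.markers.n_markers
        self.ibd_score = np.asarray(self.ibd_score, dtype=np.float64)
        if self.ibd_score.shape != (m,):
            raise ValueError("ibd_score length does not match marker count")
        if self.p_value is None:
            self.p_value = np.full(m, np.nan)
        if self.q_value is None:
            self.q_value = np.full(m, np.nan)
        self.p_value = np.asarray(self.p_value, dtype=np.float64)
        self.q_value = np.asarray(self.q_value, dtype=np.float64)


@dataclass
class GumbelNull:
    """Per-marker Gumbel null fitted to resampled reference subset scores.

    Markers whose subset scores were constant (typically all zero: never
    covered by any IBD segment in any subset) are flagged ``degenerate``;
    for those the observed constant is kept and the scale is a token
    epsilon.
    """

    markers: MarkerMap
    mu: np.ndarray
    beta: np.ndarray
    degenerate: np.ndarray
    n_subsets: int
    subset_size: int

    def __post_init__(self) -> None:
        m = self.markers.n_markers
        for name in ("mu", "beta"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
            if arr.shape != (m,):
                raise ValueError(f"{name} length does not match marker count")
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if np.any(self.beta <= 0):
            raise ValueError("beta must be positive at every marker")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "marker_id": self.markers.marker_id,
                "mu": self.mu,
                "beta": self.beta,
                "degenerate": self.degenerate.astype(int),
            }
        )


@dataclass
class SignificantRegion:
    """A maximal run of consecutive markers at or below a q-value cutoff."""

    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    start_cM: float
    end_cM: float
    min_q: float


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _clamped_freqs(markers: MarkerMap, lo: int | None = None, hi: int | None = None) -> np.ndarray:
    f = markers.b_freq[lo:hi]
    if np.any(np.isnan(f)):
        raise ValueError("b_freq is undefined for scored markers; run estimate_b_freqs")
    return np.clip(f, FREQ_CLAMP, 1.0 - FREQ_CLAMP)


def _marker_costs(panel: HaplotypePanel, markers: MarkerMap) -> np.ndarray:
    """-2 ln f(H_i) for every haplotype and marker (the scoring increments)."""
    f = _clamped_freqs(markers)
    is_b = panel.alleles == ALLELE_B
    return -2.0 * np.where(is_b, np.log(f), np.log1p(-f))


def segment_score(
    segment: IBDSegment, panel: HaplotypePanel, markers: MarkerMap | None = None
) -> float:
    """Score one pairwise IBD segment: S = -2 sum ln f(H_i) over its markers."""
    markers = markers if markers is not None else panel.markers
    row = panel.alleles[panel.index_of(segment.hap1_id)]
    a, b = segment.start_idx, segment.end_idx
    if not 0 <= a <= b < markers.n_markers:
        raise ValueError("segment marker indices out of range")
    f = _clamped_freqs(markers, a, b + 1)
    alleles = row[a : b + 1]
    if np.any(alleles == MISSING):
        raise ValueError("cannot score a segment containing missing alleles")
    is_b = alleles == ALLELE_B
    return float(-2.0 * np.sum(np.where(is_b, np.log(f), np.log1p(-f))))


def score_segments(
    segments: Sequence[IBDSegment], panel: HaplotypePanel, markers: MarkerMap | None = None
) -> list[IBDSegment]:
    """Fill ``score`` on every segment (in place) and return the list."""
    markers = markers if markers is not None else panel.markers
    if not segments:
        return list(segments)
    cum = np.concatenate(
        [np.zeros((panel.n_haplotypes, 1)), np.cumsum(_marker_costs(panel, markers), axis=1)],
        axis=1,
    )
    idx = {h: i for i, h in enumerate(panel.haplotype_ids)}
    for s in segments:
        r = idx[s.hap1_id]
        s.score = float(cum[r, s.end_idx + 1] - cum[r, s.start_idx])
    return list(segments)


def per_snp_scores(segments: Iterable[IBDSegment], markers: MarkerMap) -> ScoreTrack:
    """Per-SNP IBD score: sum of S over all segments covering each SNP."""
    m = markers.n_markers
    delta = np.zeros(m + 1)
    for s in segments:
        if math.isnan(s.score):
            raise ValueError("segments must be scored before aggregation")
        delta[s.start_idx] += s.score
        delta[s.end_idx + 1] -= s.score
    return ScoreTrack(markers=markers, ibd_score=np.cumsum(delta[:m]))


def _per_marker_scores_arrays(
    n_markers: int, starts: np.ndarray, ends: np.ndarray, scores: np.ndarray
) -> np.ndarray:
    delta = np.zeros(n_markers + 1)
    np.add.at(delta, starts, scores)
    np.add.at(delta, ends + 1, -scores)
    return np.cumsum(delta[:n_markers])


def estimate_b_freqs(reference: HaplotypePanel) -> MarkerMap:
    """Empirical B-allele frequency per marker from a reference panel."""
    if reference.n_haplotypes < 2:
        raise ValueError("need at least two reference haplotypes")
    known = reference.alleles != MISSING
    n_known = known.sum(axis=0)
    if np.any(n_known == 0):
        raise ValueError("marker with no called alleles in the reference panel")
    n_b = (reference.alleles == ALLELE_B).sum(axis=0)
    return reference.markers.with_b_freq(n_b / n_known)


# ---------------------------------------------------------------------------
# Gumbel null
# ---------------------------------------------------------------------------


def _fit_gumbel_batch(x: np.ndarray, max_iter: int = 200, tol: float = 1e-12):
    """Column-wise maximum-likelihood Gumbel fit.

    ``x`` has one sample per row; columns must be non-degenerate.  The scale
    is found by the standard ML fixed point initialised at the
    method-of-moments value beta = s * sqrt(6) / pi, then
    mu = -beta * log(mean(exp(-x / beta))).
    """
    x = np.asarray(x, dtype=np.float64)
    n, m = x.shape
    mean = x.mean(axis=0)
    beta = x.std(axis=0, ddof=1) * math.sqrt(6.0) / math.pi
    beta = np.maximum(beta, 1e-12)
    xmin = x.min(axis=0)
    xc = x - xmin  # shift for stable exponentials; cancels in the fixed point
    for _ in range(max_iter):
        w = np.exp(-xc / beta)
        sw = w.sum(axis=0)
        new_beta = mean - (x * w).sum(axis=0) / sw
        new_beta = np.maximum(new_beta, 1e-12)
        if np.all(np.abs(new_beta - beta) <= tol * np.maximum(1.0, beta)):
            beta = new_beta
            break
        beta = new_beta
    w = np.exp(-xc / beta)
    mu = xmin - beta * np.log(w.mean(axis=0))
    return mu, beta


def fit_gumbel(values) -> tuple[float, float]:
    """Maximum-likelihood Gumbel(mu, beta) fit to a sample.

    Uses a method-of-moments initialisation (beta = s sqrt(6)/pi,
    mu = mean - gamma * beta) refined by the ML fixed point.  Raises on
    constant samples, for which the scale is not identifiable.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least two values to fit a Gumbel distribution")
    if np.ptp(x) == 0:
        raise ValueError("cannot fit a Gumbel distribution to a constant sample")
    mu, beta = _fit_gumbel_batch(x[:, None])
    return float(mu[0]), float(beta[0])


def subset_null_scores(
    reference: HaplotypePanel,
    tumor_panel_size: int,
    params: MatchParams | None = None,
    n_subsets: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-SNP IBD scores of random reference subsets, one row per subset.

    Each subset draws ``tumor_panel_size`` haplotypes without replacement
    from the reference and is scored with the full matching + scoring
    pipeline.  Because pairwise matching is local to each haplotype pair,
    the segments of a subset are exactly the reference-wide pairwise
    segments restricted to pairs inside the subset, so matching is run once
    on the whole reference and segments are reused across subsets.
    """
    params = params or MatchParams()
    if n_subsets < 2:
        raise ValueError("need at least two reference subsets")
    n_ref = reference.n_haplotypes
    if n_ref < tumor_panel_size:
        raise ValueError(
            f"reference panel ({n_ref}) is smaller than the tumor panel ({tumor_panel_size})"
        )
    markers = reference.markers
    if np.any(np.isnan(markers.b_freq)):
        markers = estimate_b_freqs(reference)
        reference = HaplotypePanel(
            markers=markers,
            haplotype_ids=reference.haplotype_ids,
            alleles=reference.alleles,
            origin=reference.origin,
        )
    i, j, a, b, _ = _exact_segments_arrays(reference, params)
    cum = np.concatenate(
        [np.zeros((n_ref, 1)), np.cumsum(_marker_costs(reference, markers), axis=1)], axis=1
    )
    seg_scores = cum[i, b + 1] - cum[i, a]

    rng = np.random.default_rng(seed)
    m = markers.n_markers
    out = np.empty((n_subsets, m))
    member = np.zeros(n_ref, dtype=bool)
    for s in range(n_subsets):
        chosen = rng.choice(n_ref, size=tumor_panel_size, replace=False)
        member[:] = False
        member[chosen] = True
        keep = member[i] & member[j]
        out[s] = _per_marker_scores_arrays(m, a[keep], b[keep], seg_scores[keep])
    return out


def build_null(
    reference: HaplotypePanel,
    tumor_panel_size: int,
    params: MatchParams | None = None,
    n_subsets: int = 100,
    seed: int = 0,
) -> GumbelNull:
    """Fit the per-SNP Gumbel null from resampled reference subsets.

    Markers whose subset scores are constant (usually all zero) are marked
    degenerate: they keep the constant as location and get an epsilon
    scale; :func:`score_pvalues` treats them specially.
    """
    scores = subset_null_scores(reference, tumor_panel_size, params, n_subsets, seed)
    m = scores.shape[1]
    spread = scores.max(axis=0) - scores.min(axis=0)
    degenerate = spread == 0
    mu = np.empty(m)
    beta = np.full(m, _DEGENERATE_BETA)
    mu[degenerate] = scores[0, degenerate]
    if np.any(~degenerate):
        mu_f, beta_f = _fit_gumbel_batch(scores[:, ~degenerate])
        mu[~degenerate] = mu_f
        beta[~degenerate] = np.maximum(beta_f, _DEGENERATE_BETA)
    return GumbelNull(
        markers=reference.markers,
        mu=mu,
        beta=beta,
        degenerate=degenerate,
        n_subsets=n_subsets,
        subset_size=tumor_panel_size,
    )


def _check_scaffold(a: MarkerMap, b: MarkerMap) -> None:
    if a.n_markers != b.n_markers or not np.array_equal(a.marker_id, b.marker_id):
        raise ValueError("marker scaffolds do not match")


def score_pvalues(track: ScoreTrack, null: GumbelNull) -> ScoreTrack:
    """Upper-tail Gumbel p-value per marker: P(null score > observed).

    p = 1 - exp(-exp(-(score - mu) / beta)).  At degenerate markers the
    comparison is direct: p = 0 if the observed score exceeds the null's
    constant value, else 1.
    """
    _check_scaffold(track.markers, null.markers)
    s = track.ibd_score
    z = np.zeros_like(s)
    nd = ~null.degenerate
    z[nd] = (s[nd] - null.mu[nd]) / null.beta[nd]
    with np.errstate(over="ignore"):
        p = -np.expm1(-np.exp(-z))
    p[null.degenerate & (s > null.mu)] = 0.0
    p[null.degenerate & (s <= null.mu)] = 1.0
    return ScoreTrack(markers=track.markers, ibd_score=s, p_value=p)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_regions(track: ScoreTrack, q_threshold: float = 0.01) -> list[SignificantRegion]:
    """Maximal runs of consecutive markers with q <= q_threshold."""
    q = track.q_value
    if np.any(np.isnan(q)):
        raise ValueError("q-values are not filled")
    m = track.markers
    regions: list[SignificantRegion] = []
    for lo, hi in m.chrom_blocks():
        sig = q[lo:hi] <= q_threshold
        padded = np.zeros(len(sig) + 2, dtype=np.int8)
        padded[1:-1] = sig
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1) + lo
        ends = np.flatnonzero(d == -1) - 1 + lo
        for a, b in zip(starts, ends):
            regions.append(
                SignificantRegion(
                    chrom=str(m.chrom[a]),
                    start_idx=int(a),
                    end_idx=int(b),
                    start_bp=int(m.pos_bp[a]),
                    end_bp=int(m.pos_bp[b]),
                    start_cM=float(m.pos_cM[a]),
                    end_cM=float(m.pos_cM[b]),
                    min_q=float(q[a : b + 1].min()),
                )
            )
    return regions


def estimate_generations(mean_length_cM: float) -> float:
    """Age of a founder event, in generations, from mean pairwise IBD length.

    Pairwise IBD segments are expected to span 1/(2n) Morgans after n
    generations, so n = 1 / (2 * length_in_Morgans).
    """
    if mean_length_cM <= 0:
        raise ValueError("mean IBD length must be positive")
    return 1.0 / (2.0 * mean_length_cM / 100.0)


# ---------------------------------------------------------------------------
# end-to-end scan
# ---------------------------------------------------------------------------


def foundertracker_scan(
    tumors: HaplotypePanel,
    reference: HaplotypePanel,
    params: MatchParams | None = None,
    n_null_subsets: int = 100,
    seed: int = 0,
) -> ScoreTrack:
    """Full recurrent-IBD scan of a tumor haplotype panel.

    Pairwise IBD segments are detected in the tumor panel, scored with
    allele frequencies estimated from the reference panel, aggregated into
    per-SNP IBD scores, and compared with the resampled Gumbel null built
    from reference subsets of the same size as the tumor panel.  Returns a
    complete :class:`ScoreTrack` (scores, p-values and BH q-values).
    """
    params = params or MatchParams()
    _check_scaffold(tumors.markers, reference.markers)
    freq_map = estimate_b_freqs(reference)
    tumors = HaplotypePanel(
        markers=freq_map,
        haplotype_ids=tumors.haplotype_ids,
        alleles=tumors.alleles,
        origin=tumors.origin,
    )
    reference = HaplotypePanel(
        markers=freq_map,
        haplotype_ids=reference.haplotype_ids,
        alleles=reference.alleles,
        origin=reference.origin,
    )
    i, j, a, b, _ = _exact_segments_arrays(tumors, params)
    cum = np.concatenate(
        [np.zeros((tumors.n_haplotypes, 1)), np.cumsum(_marker_costs(tumors, freq_map), axis=1)],
        axis=1,
    )
    seg_scores = cum[i, b + 1] - cum[i, a]
    scores = _per_marker_scores_arrays(freq_map.n_markers, a, b, seg_scores)
    null = build_null(
        reference, tumors.n_haplotypes, params, n_subsets=n_null_subsets, seed=seed
    )
    track = score_pvalues(ScoreTrack(markers=freq_map, ibd_score=scores), null)
    track.q_value = bh_qvalues(track.p_value)
    return track
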