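"""Synthetic panels, planted conserved haplotypes, and power evaluation.

The synthetic reference panel is a founder-mosaic (Li-Stephens-like)
model: a small set of founder haplotypes is drawn with per-marker B-allele
probabilities from a frequency law, and every panel haplotype is a mosaic
of founders with Poisson-distributed switch points along the genetic map
plus a small per-marker allele-flip (mutation/genotyping-error) rate.
This preserves the two features the scan's empirical null must absorb —
an allele-frequency spectrum and block-structured linkage disequilibrium
with abundant short identical-by-state sharing — while remaining cheap and
fully seeded.

Power experiments plant a conserved haplotype: a focal position is chosen,
a set of carrier haplotypes is selected, and each carrier's alleles are
overwritten with the first carrier's alleles over a segment containing the
focal position, the segment length being drawn from a Gumbel distribution
with location and scale both equal to the desired mean length — the shape
that reproduces the natural spread of pairwise IBD lengths around a real
founder mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import HaplotypePanel, MarkerMap, Origin
from .dash_bench import dash_scan
from .ibd_match import MatchParams
from .ibd_score import foundertracker_scan

__all__ = [
    "PanelGenConfig",
    "PlantConfig",
    "SimulationResult",
    "MethodPerformance",
    "generate_reference_panel",
    "plant_conserved_haplotype",
    "run_power_study",
]

_SEED_MASK = 0x7FFFFFFF  # derived seeds stay below 2**31


@dataclass(frozen=True)
class PanelGenConfig:
    """Founder-mosaic panel generator settings.

    n_haplotypes : panel size.
    n_markers / chrom_length_cM : marker grid, uniformly spaced in cM
        (default density 100 markers/cM; physical scale 1 cM = 1 Mb).
    n_founders : number of founder haplotypes behind the mosaic; sets the
        background relatedness of the population.  The default (548, the
        size of a two-half population panel of 274 + 274) makes a random
        pair of haplotypes copy the same founder at ~0.2% of positions, so
        that across a few hundred haplotypes every genomic position is
        covered by chance identical segments long enough to pass the
        matcher — giving every marker a non-trivial empirical null, the
        analogue of pervasive LD — while any single pair shares far less
        than carriers of a planted founder haplotype, and the two halves
        of a split panel remain statistically exchangeable (which the
        resampled null requires for calibrated tail p-values).
    switch_rate_per_cM : Poisson rate of founder switches along the map.
    flip_rate : per-marker allele flip probability (error/mutation).
    freq_law : (low, high) bounds of the uniform founder B-allele
        frequency law.
    """

    n_haplotypes: int = 100
    n_markers: int = 10_000
    chrom_length_cM: float = 100.0
    n_founders: int = 548
    switch_rate_per_cM: float = 1.0
    flip_rate: float = 0.002
    freq_law: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least two founders")
        if not 0 <= self.flip_rate < 1:
            raise ValueError("flip_rate must lie in [0, 1)")
        if self.switch_rate_per_cM <= 0 or self.chrom_length_cM <= 0:
            raise ValueError("rates and lengths must be positive")


@dataclass(frozen=True)
class PlantConfig:
    """Planted conserved-haplotype settings.

    prevalence : fraction of haplotypes carrying the conserved segment.
    mean_length_cM : desired mean segment length; per-carrier lengths are
        drawn from Gumbel(location=mean, scale=mean) and truncated to
        (0.1 cM, chromosome span].
    """

    prevalence: float = 0.05
    mean_length_cM: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must lie in (0, 1]")
        if self.mean_length_cM <= 0:
            raise ValueError("mean_length_cM must be positive")


@dataclass
class SimulationResult:
    """Planted-region ground truth for one simulated tumor panel."""

    carrier_indices: np.ndarray
    carrier_ids: list[str]
    segments: list[tuple[int, int]]  # inclusive marker-index span per carrier
    focal_idx: int
    truth: np.ndarray  # per-marker flag: inside the union of planted segments
    detections: dict[str, bool] = field(default_factory=dict)


@dataclass
class MethodPerformance:
    """Pooled detection performance of one method over replicates."""

    method: str
    power: float
    fdr: float
    n_reps: int
    n_detected: int
    n_sig_inside: int
    n_sig_outside: int
    roc: pd.DataFrame  # columns: q_threshold, tpr, fpr (means over reps)


def _marker_grid(n_markers: int, length_cM: float) -> MarkerMap:
    cm = np.arange(n_markers) * (length_cM / n_markers)
    bp = np.round(cm * 1e6).astype(np.int64) + 1
    ids = np.array([f"snp{k + 1}" for k in range(n_markers)], dtype=object)
    return MarkerMap(
        marker_id=ids,
        chrom=np.full(n_markers, "1", dtype=object),
        pos_bp=bp,
        pos_cM=cm,
    )


def generate_reference_panel(
    config: PanelGenConfig,
    markers: MarkerMap | None = None,
    origin: Origin = Origin.SIMULATED,
    id_prefix: str = "sim",
) -> HaplotypePanel:
    """Draw a founder-mosaic haplotype panel.

    Deterministic for a fixed ``config.seed``.  Passing ``markers`` reuses
    an existing grid (it must have the configured marker count) so that
    independently generated panels share one scaffold.
    """
    rng = np.random.default_rng(config.seed)
    if markers is None:
        markers = _marker_grid(config.n_markers, config.chrom_length_cM)
    elif markers.n_markers != config.n_markers:
        raise ValueError("supplied marker grid does not match n_markers")
    m = config.n_markers
    cm = markers.pos_cM
    span = config.chrom_length_cM
    lo, hi = config.freq_law
    founder_freq = rng.uniform(lo, hi, size=m)
    founders = (rng.random((config.n_founders, m)) < founder_freq).astype(np.int8)
    alleles = np.empty((config.n_haplotypes, m), dtype=np.int8)
    col = np.arange(m)
    for h in range(config.n_haplotypes):
        n_switch = rng.poisson(config.switch_rate_per_cM * span)
        breaks = np.sort(rng.uniform(0.0, span, size=n_switch))
        fidx = rng.integers(0, config.n_founders, size=n_switch + 1)
        per_marker = fidx[np.searchsorted(breaks, cm, side="right")]
        row = founders[per_marker, col]
        if config.flip_rate > 0:
            flips = rng.random(m) < config.flip_rate
            row = row ^ flips
        alleles[h] = row
    ids = [f"{id_prefix}{k + 1}" for k in range(config.n_haplotypes)]
    return HaplotypePanel(markers=markers, haplotype_ids=ids, alleles=alleles, origin=origin)


def plant_conserved_haplotype(
    tumor_panel: HaplotypePanel, plant: PlantConfig
) -> tuple[HaplotypePanel, SimulationResult]:
    """Plant a conserved haplotype shared by a fraction of the panel.

    A focal genetic position is drawn uniformly on the chromosome; the
    carriers (always including the first haplotype, whose alleles are the
    source) each receive a segment of Gumbel-distributed length placed so
    the focal position falls at a uniform fraction of the segment, clipped
    to the chromosome.  Carrier alleles are overwritten with the first
    haplotype's alleles over their segment.
    """
    rng = np.random.default_rng(plant.seed)
    n = tumor_panel.n_haplotypes
    n_carriers = int(round(plant.prevalence * n))
    if n_carriers < 1:
        raise ValueError("prevalence yields zero carriers")
    cm = tumor_panel.markers.pos_cM
    lo_cm, hi_cm = float(cm[0]), float(cm[-1])
    span = hi_cm - lo_cm
    if span <= 0.1:
        raise ValueError("chromosome too short for a planted haplotype")
    carriers = np.concatenate(
        [[0], rng.choice(np.arange(1, n), size=n_carriers - 1, replace=False)]
    ).astype(np.int64)
    focal_cm = rng.uniform(lo_cm, hi_cm)
    focal_idx = int(np.argmin(np.abs(cm - focal_cm)))
    alleles = tumor_panel.alleles.copy()
    source = alleles[0].copy()
    segments: list[tuple[int, int]] = []
    truth = np.zeros(tumor_panel.n_markers, dtype=bool)
    for c in carriers:
        length = rng.gumbel(plant.mean_length_cM, plant.mean_length_cM)
        length = float(np.clip(length, 0.1, span))
        u = rng.uniform()
        start_cm = max(lo_cm, focal_cm - u * length)
        end_cm = min(hi_cm, start_cm + length)
        a = int(np.searchsorted(cm, start_cm, side="left"))
        b = int(np.searchsorted(cm, end_cm, side="right")) - 1
        a = min(a, focal_idx)
        b = max(b, focal_idx)
        alleles[c, a : b + 1] = source[a : b + 1]
        segments.append((a, b))
        truth[a : b + 1] = True
    planted = HaplotypePanel(
        markers=tumor_panel.markers,
        haplotype_ids=list(tumor_panel.haplotype_ids),
        alleles=alleles,
        origin=Origin.TUMOR,
    )
    result = SimulationResult(
        carrier_indices=carriers,
        carrier_ids=[tumor_panel.haplotype_ids[c] for c in carriers],
        segments=segments,
        focal_idx=focal_idx,
        truth=truth,
    )
    return planted, result


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0]) & _SEED_MASK


_DEFAULT_ROC_GRID = np.concatenate([np.logspace(-15, -0.0001, 40), [1.0]])


def run_power_study(
    panel_cfg: PanelGenConfig,
    plant_cfg: PlantConfig | None,
    params: MatchParams | None = None,
    n_reps: int = 100,
    n_null_subsets: int = 100,
    q_threshold: float = 0.01,
    methods: Iterable[str] = ("foundertracker", "dash"),
    seed: int = 0,
    n_reference: int = 274,
    roc_grid: Sequence[float] | None = None,
) -> dict[str, MethodPerformance]:
    """Detection power, pooled FDR and mean ROC for one simulated condition.

    Per replicate one founder-mosaic population of ``2 * n_reference``
    haplotypes is generated and split in two halves: one half is the
    reference panel and the simulated tumor set is drawn as a random
    subset of the other half.  The two halves share founders, so the tumor
    panel has the same allele-frequency and LD landscape the resampled
    null absorbs, and — like the null's reference subsets — the tumor set
    is a subset of a fixed pool, so its sampling variance matches the
    null's.  A conserved haplotype is then planted in the tumor set
    (unless ``plant_cfg`` is None, the no-signal calibration case) and
    each requested method is run.
    Detection means at least one marker with q <= ``q_threshold`` inside
    the union of planted segments; the FDR pools significant markers
    outside planted segments over all significant markers across
    replicates (0 when none are significant); the ROC averages per-marker
    TPR/FPR over a grid of q thresholds.
    """
    params = params or MatchParams()
    methods = list(methods)
    unknown = set(methods) - {"foundertracker", "dash"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    grid = np.asarray(roc_grid if roc_grid is not None else _DEFAULT_ROC_GRID)

    stats = {
        m: {
            "detected": 0,
            "inside": 0,
            "outside": 0,
            "tpr": np.zeros(len(grid)),
            "fpr": np.zeros(len(grid)),
            "roc_reps": 0,
        }
        for m in methods
    }
    n_tumors = panel_cfg.n_haplotypes
    pool_size = max(n_reference, n_tumors)
    master = np.random.SeedSequence(seed)
    for rep_ss in master.spawn(n_reps):
        s_panel, s_pick, s_plant, s_null = (_child_seed(c) for c in rep_ss.spawn(4))
        combined = generate_reference_panel(
            replace(panel_cfg, n_haplotypes=n_reference + pool_size, seed=s_panel),
            id_prefix="hap",
        )
        ref = combined.subset_haplotypes(np.arange(n_reference))
        ref.origin = Origin.REFERENCE
        pick = np.random.default_rng(s_pick).choice(pool_size, size=n_tumors, replace=False)
        tum_src = combined.subset_haplotypes(n_reference + np.sort(pick))
        tum_src.origin = Origin.TUMOR
        if plant_cfg is not None:
            tumors, sim = plant_conserved_haplotype(
                tum_src, replace(plant_cfg, seed=s_plant)
            )
            truth = sim.truth
        else:
            tumors = tum_src
            truth = np.zeros(tum_src.n_markers, dtype=bool)
        n_truth = int(truth.sum())
        n_out = truth.size - n_truth
        for method in methods:
            if method == "foundertracker":
                track = foundertracker_scan(
                    tumors, ref, params, n_null_subsets=n_null_subsets, seed=s_null
                )
            else:
                track, _ = dash_scan(tumors, ref, params, q_threshold=q_threshold)
            q = track.q_value
            sig = q <= q_threshold
            st = stats[method]
            if n_truth and np.any(sig & truth):
                st["detected"] += 1
            st["inside"] += int(np.sum(sig & truth))
            st["outside"] += int(np.sum(sig & ~truth))
            if n_truth and n_out:
                sig_grid = q[None, :] <= grid[:, None]
                st["tpr"] += sig_grid[:, truth].mean(axis=1)
                st["fpr"] += sig_grid[:, ~truth].mean(axis=1)
                st["roc_reps"] += 1

    out: dict[str, MethodPerformance] = {}
    for method in methods:
        st = stats[method]
        n_sig = st["inside"] + st["outside"]
        nr = max(st["roc_reps"], 1)
        roc = pd.DataFrame(
            {"q_threshold": grid, "tpr": st["tpr"] / nr, "fpr": st["fpr"] / nr}
        )
        out[method] = MethodPerformance(
            method=method,
            power=st["detected"] / n_reps,
            fdr=(st["outside"] / n_sig) if n_sig else 0.0,
            n_reps=n_reps,
            n_detected=st["detected"],
            n_sig_inside=st["inside"],
            n_sig_outside=st["outside"],
            roc=roc,
        )
    return out
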