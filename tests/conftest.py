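import numpy as np
import pytest

from foundertracker import (
    HaplotypePanel,
    MarkerMap,
    Origin,
    PanelGenConfig,
    PlantConfig,
    run_power_study,
)


def make_markers(n: int, spacing_cM: float = 0.01, chrom: str = "1", b_freq=None) -> MarkerMap:
    """Uniform marker grid: `spacing_cM` between markers, 1 cM = 1 Mb."""
    cm = np.arange(n) * spacing_cM
    return MarkerMap(
        marker_id=np.array([f"snp{i}" for i in range(n)], dtype=object),
        chrom=np.full(n, chrom, dtype=object),
        pos_bp=np.round(cm * 1e6).astype(np.int64) + 1,
        pos_cM=cm,
        b_freq=b_freq,
    )


def make_panel(alleles, spacing_cM: float = 0.01, b_freq=None, origin=Origin.REFERENCE):
    alleles = np.asarray(alleles, dtype=np.int8)
    markers = make_markers(alleles.shape[1], spacing_cM, b_freq=b_freq)
    ids = [f"h{i}" for i in range(alleles.shape[0])]
    return HaplotypePanel(markers=markers, haplotype_ids=ids, alleles=alleles, origin=origin)


@pytest.fixture(scope="session")
def study_conditions():
    """The scaled-down power-study grid shared by the acceptance tests.

    100 tumor haplotypes drawn from a 274-haplotype pool, 274 reference
    haplotypes, 10,000 markers over 100 cM, 50 null subsets, 25 replicates
    per condition, detection at q <= 0.01.
    """
    panel_cfg = PanelGenConfig(n_haplotypes=100, n_markers=10_000, chrom_length_cM=100.0)
    grid = {
        (5.0, 0.07): ["foundertracker"],
        (1.0, 0.50): ["foundertracker"],
        (5.0, 0.05): ["foundertracker", "dash"],
        (2.0, 0.15): ["foundertracker", "dash"],
        (1.0, 0.15): ["foundertracker"],
        (5.0, 0.15): ["foundertracker"],
    }
    results = {}
    for (length, prev), methods in grid.items():
        results[(length, prev)] = run_power_study(
            panel_cfg,
            PlantConfig(prevalence=prev, mean_length_cM=length),
            n_reps=25,
            n_null_subsets=50,
            q_threshold=0.01,
            methods=methods,
            seed=20120502,
        )
    return results
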