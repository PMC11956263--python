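import sys
from pathlib import Path

import numpy as np
import pytest

# make scripts/acceptance.py importable for the acceptance suite
sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))

from ataqtl.synthdata import (  # noqa: E402
    SimConfig,
    plant_caqtl_effects,
    simulate_cohort,
    simulate_panel,
    simulate_peaks,
    simulate_reads,
)


@pytest.fixture(scope="session")
def tiny_cfg():
    return SimConfig(
        n_hap=24,
        n_sites=200,
        n_donors=8,
        dup_k_max=2,
        n_peaks=20,
        peak_length=250,
        chrom_length=100_000,
        sites_per_peak=2,
        peak_depth_mean=4.0,
        background_depth_mean=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_cfg):
    """Small end-to-end simulation shared by unit tests (read-only)."""
    peaks = simulate_peaks(tiny_cfg)
    panel = simulate_panel(tiny_cfg, peaks)
    truth = simulate_cohort(panel, tiny_cfg)
    truth = plant_caqtl_effects(truth, peaks, panel, tiny_cfg)
    pileup, counts = simulate_reads(truth, peaks, tiny_cfg, panel)
    return {
        "cfg": tiny_cfg,
        "peaks": peaks,
        "panel": panel,
        "truth": truth,
        "pileup": pileup,
        "counts": counts,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
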