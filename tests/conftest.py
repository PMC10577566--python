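import warnings

import numpy as np
import pytest

from pioneerdyn import synthetic as syn

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def cfg():
    """Default study conditions, fixed seed."""
    return syn.SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_bundle(cfg):
    """Full synthetic dataset: genes, peaks, time-course counts, DEG labels."""
    genes = syn.simulate_annotation(cfg)
    peaks, counts, truth = syn.simulate_peaks_and_timecourse(cfg, genes)
    labels = syn.simulate_deg_link(cfg, genes, peaks, truth)
    return {
        "cfg": cfg,
        "genes": genes,
        "peaks": peaks,
        "counts": counts,
        "truth": truth,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
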