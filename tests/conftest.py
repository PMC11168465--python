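import numpy as np
import pytest
from scipy.spatial.distance import cdist

from telotrace import synthetic, spots


@pytest.fixture(scope="session")
def default_scene():
    """The default synthetic scene at SNR ~10 (shared, read-only)."""
    cfg = synthetic.SceneConfig(seed=7, poisson_gain=1.0, read_sigma=3.0,
                                n_rna_channels=2)
    stack, truth = synthetic.generate_fish_scene(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def default_scene_analysis(default_scene):
    """Nuclei + detected foci for the default scene."""
    _cfg, stack, _truth = default_scene
    nuclei = spots.segment_nuclei(stack)
    tel = spots.detect_foci(stack, 1, nuclei=nuclei)
    rna_a = spots.detect_foci(stack, 2, nuclei=nuclei)
    rna_b = spots.detect_foci(stack, 3, nuclei=nuclei)
    return nuclei, tel, rna_a, rna_b


def match_detections(detected, truth_df, tol_um=0.5):
    """(recall, precision, match index per detected focus)."""
    det = np.array([f.centroid_um for f in detected]).reshape(-1, 3)
    tru = truth_df[["z_um", "y_um", "x_um"]].to_numpy()
    if len(det) == 0 or len(tru) == 0:
        return 0.0, 0.0, np.array([], dtype=int)
    d = cdist(tru, det)
    recall = float((d.min(axis=1) < tol_um).mean())
    precision = float((d.min(axis=0) < tol_um).mean())
    return recall, precision, d.argmin(axis=0)
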