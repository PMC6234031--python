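import numpy as np
import pytest

from smaddyn import synth


@pytest.fixture(scope="session")
def adaptive_model():
    return synth.ResponseModel(kind="adaptive")


@pytest.fixture(scope="session")
def stable_model():
    return synth.ResponseModel(kind="stable", f0=0.15, P_max=0.40, K=2.0, tau_on=1.0)


@pytest.fixture(scope="session")
def clean_artifacts():
    """No vignette, no background, no noise: rendered values are exact."""
    return synth.ImagingArtifacts(
        vignette_amplitude=0.0, background_offset=0.0, photon_scale=0.0,
        read_noise_sd=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def noisy_colony(adaptive_model):
    """A realistic small colony time-lapse (noise SD ~20% of the H2B amplitude)."""
    layout = synth.ColonyLayout.random(
        n_cells=120, colony_radius_um=150, nucleus_radius_um=8, rng=42
    )
    artifacts = synth.ImagingArtifacts(
        vignette_amplitude=0.2, background_offset=50.0, photon_scale=1.0,
        read_noise_sd=40.0, seed=43,
    )
    stack, truth = synth.generate_colony_timelapse(
        layout, adaptive_model, artifacts, times_hr=[2.0], dose_ng_ml=10.0
    )
    return layout, stack, truth


def greedy_match_f1(detected_rc, true_rc, radius):
    """Detection F1 by greedy nearest matching within a radius (px)."""
    from scipy.spatial import cKDTree

    detected_rc = np.asarray(detected_rc, dtype=float).reshape(-1, 2)
    true_rc = np.asarray(true_rc, dtype=float).reshape(-1, 2)
    if len(detected_rc) == 0 or len(true_rc) == 0:
        return 0.0
    tree = cKDTree(true_rc)
    dist, idx = tree.query(detected_rc)
    used = set()
    tp = 0
    for d, i in sorted(zip(dist, idx)):
        if d <= radius and i not in used:
            used.add(i)
            tp += 1
    fp = len(detected_rc) - tp
    fn = len(true_rc) - tp
    return 2 * tp / (2 * tp + fp + fn)


@pytest.fixture(scope="session")
def f1_matcher():
    return greedy_match_f1
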