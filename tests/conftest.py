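"""Shared desk-scale fixtures: trained models are expensive, so they are
built once per session and reused across unit and acceptance tests."""

import numpy as np
import pytest

from pam.grids import AffineTransform
from pam.localizer import LocalizerConfig, calibrate_landmarks, train_localizer
from pam.phantom import FieldSpec, PhantomSpec, make_phantom, make_warped_pair
from pam.tracker import TrackerConfig, train_tracker


@pytest.fixture(scope="session")
def gradient_scans():
    """Phantoms whose structure varies monotonically head to toe."""
    return [make_phantom(PhantomSpec(shape=(48, 32, 32), seed=s))
            for s in range(12)]


@pytest.fixture(scope="session")
def trained_localizer(gradient_scans):
    cfg = LocalizerConfig(iterations=1500, seed=0)
    return train_localizer(gradient_scans, cfg)


@pytest.fixture(scope="session")
def landmark_targets(trained_localizer):
    """Landmark scores calibrated on annotated phantom fixtures."""
    cfg = trained_localizer.config
    calib = []
    for i in range(3):
        spec = PhantomSpec(shape=(48, 32, 32), seed=200 + i)
        calib.append((make_phantom(spec), spec.landmark_planes))
    return calibrate_landmarks(trained_localizer, calib, cfg)


@pytest.fixture(scope="session")
def registration_fixtures():
    """Four 32^3 scan pairs with known affine + smooth deformable warps."""
    pairs, truths = [], []
    for s in range(4):
        spec = PhantomSpec(shape=(32, 32, 32), seed=s,
                           lesions=[((20, 16 + s, 16), 3.0, 0.0)],
                           organ_blobs=[((22, 12, 16 + s), 5.0, 0.6)])
        pair, truth = make_warped_pair(
            spec, AffineTransform(np.eye(3), [0, 0, 3]),
            FieldSpec(amplitude=2.0, smoothness=6.0, seed=100 + s))
        pair.patient_id = str(s + 1)
        pairs.append(pair)
        truths.append(truth)
    return pairs, truths


@pytest.fixture(scope="session")
def trained_tracker(registration_fixtures):
    """Desk-configured tracker (32^3 volumes, 200 steps, batch 2)."""
    pairs, _ = registration_fixtures
    return train_tracker(pairs, TrackerConfig(steps=200, batch_size=2,
                                              seed=0))


@pytest.fixture(scope="session")
def e2e_result():
    """Full synthetic end-to-end run (harmonize -> localize -> track ->
    features -> classify) on a seeded cohort."""
    from pam.pipeline import EndToEndConfig, run_end_to_end

    return run_end_to_end(EndToEndConfig(seed=1))
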