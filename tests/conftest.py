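import os

# single-threaded BLAS: the workloads are small-matrix bound and thread
# pools only add scheduling overhead (must be set before numpy loads)
for _v in ("OPENBLAS_NUM_THREADS", "OMP_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

import eegcorrcam as ec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def zeros_recording():
    """A silent 3-minute, 500 Hz, 12-channel recording (shape checks only)."""
    data = np.zeros((12, 90_000))
    return ec.Recording(data, 500.0, ec.io.DEFAULT_MONTAGE, "sub-0", "ADHD")


@pytest.fixture(scope="session")
def scaled_study():
    """The scaled-down simulation study shared by the end-to-end tests.

    Three classes x 20 recordings (12 channels, 250 Hz, 64 s) with distinct
    planted channel pairs at coupling 0.85, segmented at 21.25 s and
    transformed with a 20-scale CWT into 240 x 240 correlation images.
    """
    classes = (
        ec.ClassSpec("ADHD", ("Fp2", "P4"), coupling=0.85),
        ec.ClassSpec("ADHD+CD", ("F3", "T4"), coupling=0.85),
        ec.ClassSpec("CD", ("Fp1", "F8"), coupling=0.85),
    )
    cfg = ec.SimConfig(fs=250.0, duration=64.0, n_per_class=20,
                       classes=classes, seed=42)
    recordings = ec.simulate_dataset(cfg)
    epochs = [e for r in recordings for e in ec.segment(r, 21.25)]
    transformer = ec.CWTCorrelation(scales=tuple(range(1, 21)))
    X = transformer.fit_transform(np.stack([e.data for e in epochs]))
    label_names = [c.label for c in classes]
    y = np.array([label_names.index(e.label) for e in epochs])
    subjects = np.array([e.source_subject for e in epochs])
    planted = {i: c.planted_pair for i, c in enumerate(classes)}
    return {
        "X": X, "y": y, "subjects": subjects, "montage": cfg.montage,
        "n_scales": 20, "label_names": label_names, "planted": planted,
    }
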