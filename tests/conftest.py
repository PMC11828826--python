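"""Shared fixtures: synthetic sessions at two scales.

The default-scale session (two phases, ~50 emotion windows) covers most
functional checks; the large planted-signal session (13 phases, >=300
windows) backs the end-to-end classification, ablation and importance
recovery checks and is built once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from emovmd.features import extract_features
from emovmd.modeling import CVSpec, ModelSpec, SplitSpec
from emovmd.preprocess import bandpass_zero_phase, ica_remove_ocular, sg_detrend
from emovmd.synth import ParadigmSpec, generate_recording


@pytest.fixture(scope="session")
def default_session():
    """(recording, ground_truth) at the paradigm defaults, with artifacts."""
    return generate_recording(ParadigmSpec(), seed=20240717)


@pytest.fixture(scope="session")
def planted_dataset():
    """Large preprocessed session plus its feature matrix and ground truth.

    13 phases of the default paradigm give >= 300 single-emotion windows at
    the default 3 s / 50% overlap window geometry.
    """
    spec = ParadigmSpec(n_phases=13)
    recording, truth = generate_recording(spec, seed=91)
    cleaned = sg_detrend(bandpass_zero_phase(recording))
    cleaned, _report = ica_remove_ocular(cleaned, seed=92)
    features = extract_features(cleaned)
    return recording, truth, features


@pytest.fixture
def eval_specs():
    """One consistent (model, split, cv) trio for evaluation tests."""
    return (
        ModelSpec(kind="RF", seed=5),
        SplitSpec(seed=5),
        CVSpec(seed=5),
    )
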