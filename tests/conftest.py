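import warnings

import numpy as np
import pytest

from laryngovibro import assemble_lvg, compute_gaw, generate_sequence
from laryngovibro.builder import prepare_landmarks
from laryngovibro.synthetic import (
    healthy_spec,
    onset_spec,
    overshoot_spec,
    polyp_spec,
    symmetric_spec,
)

warnings.filterwarnings("ignore", message=".*connected components.*")


@pytest.fixture(scope="session")
def symmetric_bundle():
    """Perfectly symmetric unperturbed phonation, 600 frames at 4000 fps."""
    seq, manifest = generate_sequence(symmetric_spec(0, n_frames=600))
    gaw = compute_gaw(seq)
    lm, axes, _ = prepare_landmarks(seq)
    M = assemble_lvg(seq, lm, axes)
    return {"seq": seq, "manifest": manifest, "gaw": gaw, "lm": lm,
            "axes": axes, "lvg": M}


@pytest.fixture(scope="session")
def healthy_bundle():
    """Healthy scenario with mild perturbations, 1200 frames."""
    seq, manifest = generate_sequence(healthy_spec(7, n_frames=1200))
    gaw = compute_gaw(seq)
    lm, axes, _ = prepare_landmarks(seq)
    M = assemble_lvg(seq, lm, axes)
    return {"seq": seq, "manifest": manifest, "gaw": gaw, "lm": lm,
            "axes": axes, "lvg": M}


@pytest.fixture(scope="session")
def polyp_bundle():
    seq, manifest = generate_sequence(polyp_spec(3, n_frames=400))
    gaw = compute_gaw(seq)
    lm, axes, _ = prepare_landmarks(seq)
    M = assemble_lvg(seq, lm, axes)
    return {"seq": seq, "manifest": manifest, "gaw": gaw, "lm": lm,
            "axes": axes, "lvg": M}


@pytest.fixture(scope="session")
def overshoot_bundle():
    seq, manifest = generate_sequence(
        overshoot_spec(5, n_frames=400, amp_jitter=0.0, period_jitter=0.0))
    M = assemble_lvg(seq)
    return {"seq": seq, "manifest": manifest, "lvg": M}


@pytest.fixture(scope="session")
def onset_bundle():
    """Normal voice onset (adduction ramp then phonation with closure
    after four open cycles)."""
    seq, manifest = generate_sequence(onset_spec(11, hard=False))
    return {"seq": seq, "manifest": manifest}
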