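import numpy as np
import pytest

from rorqualfmr import synthetic


def match_events(detected, truth, tol_s=1.0):
    """Greedy one-to-one matching of detected to true event times.

    Returns (n_true_positive, recall, precision).
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(detected.size, dtype=bool)
    tp = 0
    for t in truth:
        if detected.size == 0:
            break
        d = np.abs(detected - t)
        d[used] = np.inf
        i = int(np.argmin(d))
        if d[i] <= tol_s:
            used[i] = True
            tp += 1
    recall = tp / truth.size if truth.size else 1.0
    precision = tp / detected.size if detected.size else 1.0
    return tp, recall, precision


@pytest.fixture(scope="session")
def blue_2h():
    """A two-hour blue-whale record with ground truth (shared, read-only)."""
    sim = synthetic.SimConfig(seed=7, duration=7200.0)
    return synthetic.simulate_deployment(synthetic.SPECIES_PRESETS["blue"], sim)


@pytest.fixture(scope="session")
def blue_6h():
    """The six-hour record used for detection-fidelity checks."""
    sim = synthetic.SimConfig(seed=42, duration=21600.0)
    return synthetic.simulate_deployment(synthetic.SPECIES_PRESETS["blue"], sim)
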