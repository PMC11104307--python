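import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from fearsim import (
    Design,
    ModelParams,
    Stage,
    StimulusCatalog,
    TrialSpec,
    build_basis,
    step,
)
from fearsim.models import LearnerState


def identity_basis(n_features: int):
    """Elemental-only basis whose featurize is the identity embedding.

    Built over a catalog of n_features-1 discrete cues plus one context;
    the feature order equals the stimulus order, so arbitrary 0/1 vectors
    (including all-zero delay steps) can be fed straight through.
    """
    cat = StimulusCatalog(
        tuple(f"S{i}" for i in range(n_features - 1)), ("CTX",)
    )
    return build_basis(cat, include_configural=False)


def run_steps(f_seq, y_seq, params: ModelParams):
    """Drive fearsim.step over raw activation vectors; return trajectories."""
    basis = identity_basis(len(f_seq[0]))
    state = LearnerState.zeros(basis)
    y_hats, w_hist, n_hist, eta_hist = [], [], [], []
    for f, y in zip(f_seq, y_seq):
        rec, state = step(state, np.asarray(f), float(y), basis, params)
        y_hats.append(rec.y_hat)
        w_hist.append(state.w.copy())
        n_hist.append(state.n.copy())
        eta_hist.append(state.eta.copy())
    return {
        "y_hat": np.asarray(y_hats),
        "w": np.asarray(w_hist),
        "n": np.asarray(n_hist),
        "eta": np.asarray(eta_hist),
    }


def random_sequences(rng, n_seq, max_steps=20, max_features=5):
    """Random short binary schedules (occasionally all-zero steps)."""
    out = []
    for _ in range(n_seq):
        k = int(rng.integers(2, max_features + 1))
        s = int(rng.integers(3, max_steps + 1))
        f = (rng.random((s, k)) < 0.6).astype(int)
        y = (rng.random(s) < 0.4).astype(int)
        out.append((f.tolist(), y.tolist()))
    return out


@pytest.fixture
def simple_design():
    """10-trial conditioning then 30-trial extinction, single context."""
    cat = StimulusCatalog(("CS",), ("A",))
    trials = {
        "CS+": TrialSpec("CS+", {"CS"}, 1),
        "CS-": TrialSpec("CS-", {"CS"}, 0),
    }
    return Design(
        cat,
        trials,
        {
            "main": (
                Stage("conditioning", "A", ("CS+",) * 10),
                Stage("extinction", "A", ("CS-",) * 30),
            )
        },
    )
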