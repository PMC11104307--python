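"""Rescorla-Wagner-family learners: prediction and update rules.

Five variants share one step interface.  All predict the US as a
(positively rectified) weighted sum of active features and learn from the
prediction error ``y - y_hat``:

``basic``
    Fixed learning rate: ``w_i += lam * f_i * (y - y_hat)``.
``configural``
    Identical rule; meant to be run over a basis that includes configural
    features (the rule itself does not depend on the basis).
``decay``
    Adds decay of inhibition: ``w_i += lam * f_i * (y - y_hat)
    - I[w_i < 0] * rho * w_i``.  Only *negative* (inhibitory) weights
    decay, on every time step, whether or not the feature is present —
    this is what turns long retention intervals into spontaneous
    recovery while leaving excitatory memories intact.
``familiarity``
    Feature-specific learning rates that fall off with the number of
    times a feature has been observed:
    ``lam_i = lam_min + 0.5 * (n_i + 1) ** -p`` (count incremented
    before the rate is computed).  Produces the CS pre-exposure effect.
``compact``
    Revised CompAct: competitive attention.  Each feature carries a
    salience ``eta_i``; attention gains ``g = eta * f`` are normalized
    by their m-norm into attention weights ``a`` which rescale both
    prediction and learning.  Salience follows gradient descent on
    squared prediction error.  Also keeps rectified prediction,
    familiarity rates and decay of inhibition.

Prediction is rectified (``max(.., 0)``) by default because shocks are
never negative; this single detail is what protects conditioned
inhibitors (safety signals) from extinction.  ``rectify=False`` restores
the original linear rule for demonstrating that failure mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .features import FeatureBasis, build_basis
from .schedule import Design, TimeStepSeq, expand

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "ModelParams",
    "LearnerState",
    "StepRecord",
    "Trajectory",
    "predict",
    "attention_weights",
    "familiarity_rate",
    "salience_update",
    "step",
    "run",
]

VARIANTS = ("basic", "configural", "decay", "familiarity", "compact")

#: figure-caption parameter sets used throughout the simulations
_VARIANT_DEFAULTS: dict[str, dict[str, float]] = {
    "basic": {"lam": 0.3},
    "configural": {"lam": 0.2},
    "decay": {"lam": 0.3, "rho": 0.002},
    "familiarity": {"lam_min": 0.1, "p": 1.5},
    "compact": {"rho": 0.01, "mu": 1.5, "lam_min": 0.15, "m": 8.0, "p": 0.5},
}

#: which parameters are meaningful for each variant (others are ignored)
_VARIANT_PARAMS: dict[str, tuple[str, ...]] = {
    "basic": ("lam", "rectify"),
    "configural": ("lam", "rectify"),
    "decay": ("lam", "rho", "rectify"),
    "familiarity": ("lam_min", "p", "rectify"),
    "compact": ("lam_min", "p", "rho", "mu", "m", "rectify", "eta_floor"),
}


@dataclass(frozen=True)
class ModelParams:
    """Variant choice plus every tunable constant.

    lam       fixed learning-rate parameter (basic / configural / decay)
    rho       per-step decay rate of negative weights (decay / compact)
    lam_min   asymptotic minimum learning rate (familiarity / compact)
    p         familiarity exponent: how fast lam_i falls with n_i
    mu        salience step size (compact)
    m         attention-norm order; lower m = fiercer competition (compact)
    rectify   clip the US prediction at zero (on everywhere in the
              reported simulations; off reproduces the linear-prediction
              failure on inhibitor exposure)
    eta_floor lower clip for salience, keeping the m-norm well defined
    """

    variant: str = "basic"
    lam: float = 0.3
    rho: float = 0.002
    lam_min: float = 0.1
    p: float = 1.5
    mu: float = 1.5
    m: float = 8.0
    rectify: bool = True
    eta_floor: float = 1e-4

    @classmethod
    def defaults(cls, variant: str, **overrides) -> "ModelParams":
        """The per-variant defaults used by the simulation battery."""
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        known = set(cls.__dataclass_fields__) - {"variant"}
        bad = set(overrides) - known
        if bad:
            raise ValueError(f"unknown parameter names: {sorted(bad)}")
        kw = dict(_VARIANT_DEFAULTS[variant])
        kw.update(overrides)
        return cls(variant=variant, **kw).validated()

    def validated(self) -> "ModelParams":
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        checks = [
            (0.0 < self.lam < 1.0, "lam must be in (0, 1)"),
            (0.0 <= self.rho < 1.0, "rho must be in [0, 1)"),
            (self.lam_min > 0.0, "lam_min must be positive"),
            (self.p > 0.0, "p must be positive"),
            (self.mu > 0.0, "mu must be positive"),
            (self.m >= 1.0, "m must be >= 1"),
            (self.eta_floor > 0.0, "eta_floor must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        return self

    @property
    def uses_decay(self) -> bool:
        return self.variant in ("decay", "compact")

    @property
    def uses_familiarity(self) -> bool:
        return self.variant in ("familiarity", "compact")

    @property
    def wants_configural_basis(self) -> bool:
        return self.variant in ("configural", "compact")

    def relevant(self) -> dict[str, object]:
        """Only the parameters this variant actually reads."""
        return {k: getattr(self, k) for k in _VARIANT_PARAMS[self.variant]}


@dataclass
class LearnerState:
    """Everything the learner carries between steps, per feature.

    w    association weight to the US (negative = conditioned inhibitor)
    n    observation count (familiarity / compact)
    eta  salience (compact); starts equal across features
    """

    w: np.ndarray
    n: np.ndarray
    eta: np.ndarray

    @classmethod
    def zeros(cls, basis: FeatureBasis) -> "LearnerState":
        k = basis.n_features
        return cls(
            w=np.zeros(k), n=np.zeros(k, dtype=np.int64), eta=np.ones(k)
        )

    def copy(self) -> "LearnerState":
        return LearnerState(self.w.copy(), self.n.copy(), self.eta.copy())


@dataclass(frozen=True)
class StepRecord:
    """Per-step transients: prediction, error, rates and attention."""

    y_hat: float
    prediction_error: float
    f: np.ndarray
    lam_i: np.ndarray | None = None
    a: np.ndarray | None = None
    g_norm: float | None = None


def attention_weights(
    eta: np.ndarray, f: np.ndarray, m: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Attention gains ``g = eta * f`` and their m-norm-normalized weights.

    Undefined (raises) when no feature is active; the step routine skips
    attention entirely on such steps.
    """
    g = eta * f
    if not np.any(g > 0):
        raise ValueError("attention undefined: no features are active")
    g_norm = float(np.sum(np.abs(g) ** m) ** (1.0 / m))
    return g, g / g_norm, g_norm


def familiarity_rate(n: np.ndarray | int, lam_min: float, p: float) -> np.ndarray:
    """lam_i = lam_min + 0.5 (n_i + 1)^-p, n_i already incremented."""
    return lam_min + 0.5 * (np.asarray(n, dtype=np.float64) + 1.0) ** (-p)


def predict(state: LearnerState, f: np.ndarray, params: ModelParams) -> float:
    """Predicted US value for an activation vector under a variant."""
    if params.variant == "compact":
        if not np.any(f > 0):
            return 0.0
        _, a, _ = attention_weights(state.eta, f, params.m)
        raw = float(np.dot(a * f, state.w))
    else:
        raw = float(np.dot(f, state.w))
    return max(raw, 0.0) if params.rectify else raw


def salience_update(
    eta: np.ndarray,
    w: np.ndarray,
    f: np.ndarray,
    a: np.ndarray,
    g_norm: float,
    y_hat: float,
    y: float,
    params: ModelParams,
) -> np.ndarray:
    """Gradient step on squared prediction error with respect to salience.

    eta_i += mu * f_i * ||g||^-1 * (y - y_hat) * (w_i f_i - a_i^(m-1) y_hat),
    then clipped at ``eta_floor`` (negative salience would break the m-norm).
    """
    grad = f / g_norm * (y - y_hat) * (w * f - a ** (params.m - 1.0) * y_hat)
    new_eta = eta + params.mu * grad
    if np.any(new_eta < params.eta_floor):
        logger.info(
            "salience clipped at floor %.1e for %d feature(s)",
            params.eta_floor,
            int(np.sum(new_eta < params.eta_floor)),
        )
        new_eta = np.maximum(new_eta, params.eta_floor)
    return new_eta


def step(
    state: LearnerState,
    x: np.ndarray,
    y: float,
    basis: FeatureBasis,
    params: ModelParams,
) -> tuple[StepRecord, LearnerState]:
    """One observe-predict-learn cycle; returns the record and new state.

    Order of operations (matters, and is fixed): featurize; attention
    (compact, skipped when nothing is active); predict; increment counts
    and compute familiarity rates; salience update; weight update.  The
    salience and weight updates both use the pre-update prediction and
    the attention weights computed at the top of the step.
    """
    for arr in (state.w, state.eta):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError("non-finite value in learner state")

    state = state.copy()
    f = basis.featurize(x)
    present = f > 0
    any_present = bool(present.any())

    a = None
    g = None
    g_norm = None
    if params.variant == "compact" and any_present:
        g, a, g_norm = attention_weights(state.eta, f, params.m)

    if params.variant == "compact":
        raw = float(np.dot(a * f, state.w)) if any_present else 0.0
    else:
        raw = float(np.dot(f, state.w))
    y_hat = max(raw, 0.0) if params.rectify else raw
    pe = float(y) - y_hat

    lam_i = None
    if params.uses_familiarity:
        state.n = state.n + present.astype(np.int64)
        lam_i = familiarity_rate(state.n, params.lam_min, params.p)

    if params.variant == "compact" and any_present:
        state.eta = salience_update(
            state.eta, state.w, f, a, g_norm, y_hat, float(y), params
        )

    w = state.w
    if params.variant in ("basic", "configural"):
        w = w + params.lam * f * pe
    elif params.variant == "decay":
        w = w + params.lam * f * pe - (w < 0) * params.rho * w
    elif params.variant == "familiarity":
        w = w + lam_i * f * pe
    elif params.variant == "compact":
        learn = lam_i * a * f * pe if any_present else 0.0
        w = w + learn - (w < 0) * params.rho * w
    state.w = w

    record = StepRecord(
        y_hat=y_hat, prediction_error=pe, f=f, lam_i=lam_i, a=a, g_norm=g_norm
    )
    return record, state


# ---------------------------------------------------------------------------
# full-sequence runner


@dataclass
class Trajectory:
    """Per-step records plus full state snapshots for one group's run.

    Array shapes: scalars are (S,), per-feature arrays (S, F) where S is
    the number of time steps and F the basis size.  ``w``/``n``/``eta``
    are post-update snapshots; ``a`` and ``lam_i`` are NaN where the
    variant does not define them.
    """

    seq: TimeStepSeq
    basis: FeatureBasis
    params: ModelParams
    y_hat: np.ndarray
    prediction_error: np.ndarray
    w: np.ndarray
    n: np.ndarray
    eta: np.ndarray
    a: np.ndarray
    lam_i: np.ndarray
    initial_state: LearnerState
    final_state: LearnerState

    def __len__(self) -> int:
        return len(self.seq)

    def feature_index(self, feature_id: str) -> int:
        return self.basis.index(feature_id)

    def weight(self, feature_id: str, at_step: int = -1) -> float:
        """Post-update weight of a feature at a step (default: final)."""
        return float(self.w[at_step, self.feature_index(feature_id)])

    def trial_mask(
        self, stage: str | None = None, trial_name: str | None = None
    ) -> np.ndarray:
        mask = self.seq.is_trial.copy()
        if stage is not None:
            mask &= self.seq.stage == stage
        if trial_name is not None:
            mask &= self.seq.trial_name == trial_name
        return mask

    def trial_y_hat(
        self, stage: str | None = None, trial_name: str | None = None
    ) -> np.ndarray:
        """Predicted US values on (filtered) trial steps, in order."""
        return self.y_hat[self.trial_mask(stage, trial_name)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (step, feature)."""
        S, F = self.w.shape
        steps = np.repeat(np.arange(S), F)
        df = pd.DataFrame(
            {
                "step": steps,
                "stage": np.repeat(self.seq.stage, F),
                "kind": np.repeat(self.seq.kind, F),
                "is_trial": np.repeat(self.seq.is_trial, F),
                "trial_name": np.repeat(self.seq.trial_name, F),
                "y": np.repeat(self.seq.y, F),
                "y_hat": np.repeat(self.y_hat, F),
                "feature": np.tile(np.asarray(self.basis.ids, dtype=object), S),
                "f": np.concatenate([self.basis.featurize(row) for row in self.seq.x])
                if S
                else np.array([]),
                "w": self.w.ravel(),
                "n": self.n.ravel(),
                "eta": self.eta.ravel(),
                "a": self.a.ravel(),
                "lambda_i": self.lam_i.ravel(),
            }
        )
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        """Compact JSON-friendly summary: final state and per-trial y_hat."""
        return {
            "variant": self.params.variant,
            "params": self.params.relevant(),
            "n_steps": len(self),
            "final_w": {fid: float(v) for fid, v in zip(self.basis.ids, self.final_state.w)},
            "trial_y_hat": [
                {
                    "step": int(i),
                    "stage": str(self.seq.stage[i]),
                    "trial_name": str(self.seq.trial_name[i]),
                    "y": int(self.seq.y[i]),
                    "y_hat": float(self.y_hat[i]),
                }
                for i in np.flatnonzero(self.seq.is_trial)
            ],
        }


def run(
    design: Design,
    group: str,
    params: ModelParams,
    basis: FeatureBasis | None = None,
    initial_state: LearnerState | None = None,
) -> Trajectory:
    """Expand a group's schedule and apply ``step`` to every time step.

    The basis defaults to elemental-only, or elemental + configural for
    the configural and compact variants.  Weights start at zero (novel
    stimuli carry no associations), counts at zero, saliences at one.
    """
    params.validated()
    if basis is None:
        basis = build_basis(
            design.catalog, include_configural=params.wants_configural_basis
        )
    seq = expand(design, group)
    state = (initial_state or LearnerState.zeros(basis)).copy()
    initial = state.copy()

    S, F = len(seq), basis.n_features
    y_hat = np.zeros(S)
    pe = np.zeros(S)
    w = np.zeros((S, F))
    n = np.zeros((S, F), dtype=np.int64)
    eta = np.zeros((S, F))
    a = np.full((S, F), np.nan)
    lam_i = np.full((S, F), np.nan)

    for i in range(S):
        rec, state = step(state, seq.x[i], float(seq.y[i]), basis, params)
        y_hat[i] = rec.y_hat
        pe[i] = rec.prediction_error
        w[i] = state.w
        n[i] = state.n
        eta[i] = state.eta
        if rec.a is not None:
            a[i] = rec.a
        if rec.lam_i is not None:
            lam_i[i] = rec.lam_i

    return Trajectory(
        seq=seq,
        basis=basis,
        params=params,
        y_hat=y_hat,
        prediction_error=pe,
        w=w,
        n=n,
        eta=eta,
        a=a,
        lam_i=lam_i,
        initial_state=initial,
        final_state=state,
    )
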