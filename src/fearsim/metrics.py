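"""Test-stage response summaries and ordinal contrast evaluation.

The simulations make ordinal claims ("the group tested in a different
context responds more"), not quantitative fits, so the unit of evidence
is a *contrast*: two response summaries and a direction.  A response
summary is the mean predicted US value over trial steps (ITIs and delays
excluded) of one stage, optionally filtered by trial type and/or
restricted to the last ``tail`` trials (e.g. "the final extinction
trial").  A side may also be a difference of two such cells, which is
how delay-by-context interactions are expressed.

Groups are deterministic average-behaviour runs; there is no subject
level sampling and therefore no inferential statistics — margins exist
only to keep float noise from counting as an effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .models import Trajectory

__all__ = [
    "Cell",
    "CellDifference",
    "ContrastSpec",
    "ContrastResult",
    "test_response",
    "cell_value",
    "evaluate",
    "renewal_magnitude",
    "results_table",
    "all_passed",
]

GREATER = "greater"
LESS = "less"
APPROX_EQUAL = "approx_equal"
RELATIONS = (GREATER, LESS, APPROX_EQUAL)

DEFAULT_MARGIN = 0.01
DEFAULT_TOLERANCE = 0.02


def test_response(
    trajectory: Trajectory,
    stage: str,
    trial_name: str | None = None,
    tail: int | None = None,
) -> float:
    """Mean predicted US value over a stage's trial steps.

    ``trial_name`` restricts to one trial type; ``tail`` keeps only the
    last so-many matching trials.  Raises if nothing matches.
    """
    vals = trajectory.trial_y_hat(stage=stage, trial_name=trial_name)
    if tail is not None:
        vals = vals[-int(tail):]
    if len(vals) == 0:
        raise ValueError(
            f"no trial steps match stage={stage!r}, trial_name={trial_name!r}"
        )
    return float(np.mean(vals))


@dataclass(frozen=True)
class Cell:
    """One response summary: (group, stage[, trial type][, last-k trials])."""

    group: str
    stage: str
    trial_name: str | None = None
    tail: int | None = None

    def describe(self) -> str:
        parts = [self.group, self.stage]
        if self.trial_name:
            parts.append(self.trial_name)
        if self.tail:
            parts.append(f"last {self.tail}")
        return "/".join(parts)


@dataclass(frozen=True)
class CellDifference:
    """The difference of two cells (value = a - b)."""

    a: Cell
    b: Cell

    def describe(self) -> str:
        return f"({self.a.describe()} - {self.b.describe()})"


Side = Union[Cell, CellDifference]


@dataclass(frozen=True)
class ContrastSpec:
    """An ordinal claim: left <relation> right, with an effect margin.

    ``greater``/``less`` require the difference to reach ``margin``;
    ``approx_equal`` requires |left - right| <= ``tolerance``.
    """

    label: str
    left: Side
    right: Side
    relation: str
    margin: float = DEFAULT_MARGIN
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.left == self.right:
            raise ValueError(f"contrast {self.label!r}: left and right are identical")

    def flipped(self) -> "ContrastSpec":
        inverse = {GREATER: LESS, LESS: GREATER, APPROX_EQUAL: APPROX_EQUAL}
        return replace(
            self, left=self.right, right=self.left, relation=inverse[self.relation]
        )


@dataclass(frozen=True)
class ContrastResult:
    label: str
    left_value: float
    right_value: float
    relation: str
    margin: float
    passed: bool

    def describe(self) -> str:
        sym = {GREATER: ">", LESS: "<", APPROX_EQUAL: "~"}[self.relation]
        flag = "PASS" if self.passed else "FAIL"
        return (
            f"[{flag}] {self.label}: {self.left_value:.4f} {sym} "
            f"{self.right_value:.4f} (margin {self.margin:g})"
        )


def cell_value(side: Side, trajectories: Mapping[str, Trajectory]) -> float:
    if isinstance(side, CellDifference):
        return cell_value(side.a, trajectories) - cell_value(side.b, trajectories)
    if side.group not in trajectories:
        raise KeyError(
            f"no trajectory for group {side.group!r}; have {sorted(trajectories)}"
        )
    return test_response(
        trajectories[side.group], side.stage, side.trial_name, side.tail
    )


def _holds(relation: str, left: float, right: float, margin: float, tol: float) -> bool:
    if relation == GREATER:
        return (left - right) >= margin
    if relation == LESS:
        return (right - left) >= margin
    return abs(left - right) <= tol


def evaluate(
    contrasts: Sequence[ContrastSpec], trajectories: Mapping[str, Trajectory]
) -> list[ContrastResult]:
    """Evaluate every contrast against a dict of per-group trajectories."""
    results = []
    for c in contrasts:
        left = cell_value(c.left, trajectories)
        right = cell_value(c.right, trajectories)
        results.append(
            ContrastResult(
                label=c.label,
                left_value=left,
                right_value=right,
                relation=c.relation,
                margin=c.margin if c.relation != APPROX_EQUAL else c.tolerance,
                passed=_holds(c.relation, left, right, c.margin, c.tolerance),
            )
        )
    return results


def renewal_magnitude(
    trajectory: Trajectory, test_stage: str = "test", ext_stage: str = "extinction"
) -> float:
    """Degree of renewal: test response minus the final extinction trial."""
    return test_response(trajectory, test_stage) - test_response(
        trajectory, ext_stage, tail=1
    )


def results_table(results: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contrast": r.label,
                "left": r.left_value,
                "right": r.right_value,
                "relation": r.relation,
                "margin": r.margin,
                "passed": r.passed,
            }
            for r in results
        ]
    )


def all_passed(results: Sequence[ContrastResult]) -> bool:
    return all(r.passed for r in results)
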