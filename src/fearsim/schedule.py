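"""Declarative conditioning designs and their expansion into time steps.

A conditioning experiment is written down the way it appears in a methods
section: a catalog of discrete cues (CSs) and contexts, a dictionary of
trial types (which cues are present, whether the shock occurs), and per
group an ordered list of stages.  ``expand`` turns a design into the flat
sequence of discrete time steps the learner actually experiences: every
trial occupies one step and is preceded by a run of context-only steps
representing the inter-trial interval (ITI), because the learner keeps
updating its context associations between trials.  Pure-delay stages
(time spent in the home cage between sessions) emit steps with no
stimuli at all.

Expansion is fully deterministic; there is no stochastic element anywhere
in the simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StimulusCatalog",
    "TrialSpec",
    "Stage",
    "Design",
    "TimeStepSeq",
    "validate_design",
    "expand",
    "round_robin",
    "design_to_dict",
    "design_from_dict",
    "load_design",
    "save_design",
]

DEFAULT_ITI = 5  # context-only steps preceding each trial


@dataclass(frozen=True)
class StimulusCatalog:
    """All stimuli of an experiment: discrete cues plus contexts.

    Contexts are ordinary stimuli as far as the learner is concerned; they
    are listed separately only so the schedule can place exactly one of
    them on every non-delay step.
    """

    cs_labels: tuple[str, ...]
    context_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cs_labels", tuple(self.cs_labels))
        object.__setattr__(self, "context_labels", tuple(self.context_labels))

    @property
    def stimuli(self) -> tuple[str, ...]:
        """CS labels followed by context labels; the cue-vector axis."""
        return self.cs_labels + self.context_labels

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    def index(self, label: str) -> int:
        return self.stimuli.index(label)


@dataclass(frozen=True)
class TrialSpec:
    """One trial type: the cues present on the trial step and the US value.

    ``cues`` may be empty: with ``us=1`` this is an unsignalled shock
    (context + US only), with ``us=0`` a plain context exposure trial.
    """

    name: str
    cues: frozenset[str]
    us: int

    def __init__(self, name: str, cues: Iterable[str] = (), us: int = 0):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "cues", frozenset(cues))
        object.__setattr__(self, "us", int(us))


@dataclass(frozen=True)
class Stage:
    """A contiguous block of the experiment in a single context.

    Either ``trials`` is nonempty (an ordinary session: each listed trial
    is preceded by ``iti_steps`` context-only steps) or ``delay_steps`` is
    positive (a featureless retention interval), never both.
    """

    label: str
    context: str | None
    trials: tuple[str, ...] = ()
    iti_steps: int = DEFAULT_ITI
    delay_steps: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))


@dataclass(frozen=True)
class Design:
    """A full between-groups experiment."""

    catalog: StimulusCatalog
    trial_specs: Mapping[str, TrialSpec]
    groups: Mapping[str, tuple[Stage, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trial_specs", dict(self.trial_specs))
        object.__setattr__(
            self, "groups", {g: tuple(stages) for g, stages in self.groups.items()}
        )

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(self.groups)


def round_robin(counts: Mapping[str, int] | Sequence[tuple[str, int]]) -> tuple[str, ...]:
    """Interleave trial types by cycling through them until counts run out.

    ``round_robin({"A+": 2, "A.X-": 2})`` -> ``("A+", "A.X-", "A+", "A.X-")``.
    Used for intermixed training such as conditioned-inhibition schedules.
    """
    items = list(counts.items()) if isinstance(counts, Mapping) else list(counts)
    remaining = {name: int(c) for name, c in items}
    order = [name for name, _ in items]
    out: list[str] = []
    while any(remaining[name] > 0 for name in order):
        for name in order:
            if remaining[name] > 0:
                out.append(name)
                remaining[name] -= 1
    return tuple(out)


# ---------------------------------------------------------------------------
# validation


def validate_design(design: Design) -> list[str]:
    """Check every design invariant; return human-readable violations.

    Never raises: an empty return value means the design is well formed.
    """
    v: list[str] = []
    cat = design.catalog
    labels = list(cat.cs_labels) + list(cat.context_labels)
    dupes = {s for s in labels if labels.count(s) > 1}
    if dupes:
        v.append(f"duplicate stimulus labels: {sorted(dupes)}")
    if not cat.context_labels:
        v.append("catalog has no context labels (at least one is required)")

    for name, spec in design.trial_specs.items():
        if spec.name != name:
            v.append(f"trial spec keyed {name!r} has mismatched name {spec.name!r}")
        unknown = spec.cues - set(cat.cs_labels)
        if unknown:
            v.append(f"trial {name!r} references undefined cues: {sorted(unknown)}")
        if spec.us not in (0, 1):
            v.append(f"trial {name!r} has non-binary us value {spec.us!r}")

    if not design.groups:
        v.append("design has no groups")
    for group, stages in design.groups.items():
        if not stages:
            v.append(f"group {group!r} has no stages")
        seen = set()
        for stage in stages:
            tag = f"group {group!r} stage {stage.label!r}"
            if stage.label in seen:
                v.append(f"{tag}: duplicate stage label within group")
            seen.add(stage.label)
            has_trials = len(stage.trials) > 0
            if has_trials and stage.delay_steps > 0:
                v.append(f"{tag}: has both trials and delay_steps > 0")
            if not has_trials and stage.delay_steps <= 0:
                v.append(f"{tag}: has neither trials nor delay_steps > 0")
            if stage.iti_steps < 0:
                v.append(f"{tag}: negative iti_steps")
            if stage.delay_steps < 0:
                v.append(f"{tag}: negative delay_steps")
            if has_trials:
                if stage.context is None:
                    v.append(f"{tag}: trial stage must name a context")
                elif stage.context not in cat.context_labels:
                    v.append(f"{tag}: undefined context {stage.context!r}")
                for tname in stage.trials:
                    if tname not in design.trial_specs:
                        v.append(f"{tag}: undefined trial type {tname!r}")
    return v


# ---------------------------------------------------------------------------
# expansion

KIND_TRIAL = "trial"
KIND_ITI = "iti"
KIND_DELAY = "delay"


@dataclass
class TimeStepSeq:
    """The flat step-by-step stimulus sequence one group experiences.

    ``x`` holds one 0/1 cue-presence row per step over ``catalog.stimuli``
    (contexts included as cues); ``y`` is the US indicator.  Annotation
    arrays record the stage, the step kind (trial / iti / delay), the trial
    type name, and a running trial index within the stage (-1 off-trial).
    """

    catalog: StimulusCatalog
    x: np.ndarray
    y: np.ndarray
    stage: np.ndarray
    kind: np.ndarray
    trial_name: np.ndarray
    trial_index: np.ndarray

    def __len__(self) -> int:
        return len(self.y)

    @property
    def is_trial(self) -> np.ndarray:
        return self.kind == KIND_TRIAL

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: step, stage, kind, one 0/1 column per stimulus, y."""
        df = pd.DataFrame(
            {
                "step": np.arange(len(self), dtype=int),
                "stage": self.stage,
                "kind": self.kind,
                "is_trial": self.is_trial,
                "trial_name": self.trial_name,
            }
        )
        for j, label in enumerate(self.catalog.stimuli):
            df[label] = self.x[:, j].astype(int)
        df["y"] = self.y.astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def expand(design: Design, group: str) -> TimeStepSeq:
    """Deterministically expand one group's stages into time steps.

    Each trial contributes ``iti_steps`` context-only steps followed by one
    trial step; delay stages contribute ``delay_steps`` featureless steps.
    Raises ``ValueError`` for an unknown group or an invalid design.
    """
    if group not in design.groups:
        raise ValueError(
            f"unknown group {group!r}; available: {sorted(design.groups)}"
        )
    violations = validate_design(design)
    if violations:
        raise ValueError("invalid design: " + "; ".join(violations))

    cat = design.catalog
    rows_x: list[np.ndarray] = []
    rows_y: list[int] = []
    ann_stage: list[str] = []
    ann_kind: list[str] = []
    ann_trial: list[object] = []
    ann_idx: list[int] = []

    for stage in design.groups[group]:
        if stage.delay_steps > 0:
            zero = np.zeros(cat.n_stimuli, dtype=np.int8)
            for _ in range(stage.delay_steps):
                rows_x.append(zero)
                rows_y.append(0)
                ann_stage.append(stage.label)
                ann_kind.append(KIND_DELAY)
                ann_trial.append(None)
                ann_idx.append(-1)
            continue
        ctx_row = np.zeros(cat.n_stimuli, dtype=np.int8)
        ctx_row[cat.index(stage.context)] = 1
        for t_idx, tname in enumerate(stage.trials):
            spec = design.trial_specs[tname]
            for _ in range(stage.iti_steps):
                rows_x.append(ctx_row)
                rows_y.append(0)
                ann_stage.append(stage.label)
                ann_kind.append(KIND_ITI)
                ann_trial.append(None)
                ann_idx.append(-1)
            trial_row = ctx_row.copy()
            for cue in spec.cues:
                trial_row[cat.index(cue)] = 1
            rows_x.append(trial_row)
            rows_y.append(spec.us)
            ann_stage.append(stage.label)
            ann_kind.append(KIND_TRIAL)
            ann_trial.append(tname)
            ann_idx.append(t_idx)

    n = len(rows_y)
    x = np.vstack(rows_x) if n else np.zeros((0, cat.n_stimuli), dtype=np.int8)
    return TimeStepSeq(
        catalog=cat,
        x=x,
        y=np.asarray(rows_y, dtype=np.int8),
        stage=np.asarray(ann_stage, dtype=object),
        kind=np.asarray(ann_kind, dtype=object),
        trial_name=np.asarray(ann_trial, dtype=object),
        trial_index=np.asarray(ann_idx, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# serialization (JSON, with YAML accepted as an equivalent dialect)


def design_to_dict(design: Design) -> dict:
    return {
        "catalog": {
            "cs": list(design.catalog.cs_labels),
            "contexts": list(design.catalog.context_labels),
        },
        "trials": {
            name: {"cues": sorted(spec.cues), "us": spec.us}
            for name, spec in design.trial_specs.items()
        },
        "groups": {
            group: [
                {
                    "label": s.label,
                    "context": s.context,
                    "trials": list(s.trials),
                    "iti_steps": s.iti_steps,
                    "delay_steps": s.delay_steps,
                }
                for s in stages
            ]
            for group, stages in design.groups.items()
        },
    }


def _stage_trials(raw) -> tuple[str, ...]:
    # accept ["A+", "A+"] or [["A+", 2], ["X-", 1]]
    out: list[str] = []
    for item in raw:
        if isinstance(item, str):
            out.append(item)
        else:
            name, count = item
            out.extend([name] * int(count))
    return tuple(out)


def design_from_dict(d: dict) -> Design:
    cat = StimulusCatalog(tuple(d["catalog"]["cs"]), tuple(d["catalog"]["contexts"]))
    trials = {
        name: TrialSpec(name, spec.get("cues", ()), spec.get("us", 0))
        for name, spec in d["trials"].items()
    }
    groups = {
        group: tuple(
            Stage(
                label=s["label"],
                context=s.get("context"),
                trials=_stage_trials(s.get("trials", [])),
                iti_steps=int(s.get("iti_steps", DEFAULT_ITI)),
                delay_steps=int(s.get("delay_steps", 0)),
            )
            for s in stages
        )
        for group, stages in d["groups"].items()
    }
    return Design(catalog=cat, trial_specs=trials, groups=groups)


def load_design(path) -> Design:
    text = open(path).read()
    if str(path).endswith((".yml", ".yaml")):
        return design_from_dict(yaml.safe_load(text))
    return design_from_dict(json.loads(text))


def save_design(design: Design, path) -> None:
    d = design_to_dict(design)
    with open(path, "w") as fh:
        if str(path).endswith((".yml", ".yaml")):
            yaml.safe_dump(d, fh, sort_keys=False)
        else:
            json.dump(d, fh, indent=2)
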