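"""Stimulus representation: elemental and configural feature bases.

The learner never sees raw cues; it sees *features*.  Elemental features
fire when their stimulus is present (one per CS, one per context — the
"main effects").  Configural features fire when two stimuli co-occur (the
"interaction terms"); they let a context modulate the meaning of a CS,
which is what occasion setting requires.  Configural features are built
for every CS x CS and CS x context pair; context x context pairs are
omitted because two contexts never co-occur in a schedule, so such
features would stay inert anyway.

``build_basis(..., include_contexts=False)`` produces a context-blind
representation (no features for context stimuli at all) — the
impoverished learner that treats extinction as pure unlearning.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .schedule import StimulusCatalog

__all__ = ["Feature", "FeatureBasis", "build_basis", "featurize"]

ELEMENTAL = "elemental"
CONFIGURAL = "configural"


@dataclass(frozen=True)
class Feature:
    """A single feature: one stimulus, or an unordered pair of stimuli."""

    id: str
    kind: str
    constituents: tuple[str, ...]


def _pair_id(a: str, b: str) -> str:
    return f"{a}*{b}"


@dataclass(frozen=True)
class FeatureBasis:
    """Ordered feature list plus precomputed catalog indices for activation."""

    catalog: StimulusCatalog
    features: tuple[Feature, ...]
    include_configural: bool

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.features)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def index(self, feature_id: str) -> int:
        return self.ids.index(feature_id)

    def _constituent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        i1, i2 = [], []
        for f in self.features:
            a = f.constituents[0]
            b = f.constituents[-1]  # == a for elemental features
            i1.append(self.catalog.index(a))
            i2.append(self.catalog.index(b))
        return np.asarray(i1, dtype=np.intp), np.asarray(i2, dtype=np.intp)

    def __post_init__(self) -> None:
        i1, i2 = self._constituent_indices()
        object.__setattr__(self, "_i1", i1)
        object.__setattr__(self, "_i2", i2)

    def featurize(self, x: np.ndarray) -> np.ndarray:
        """Activation vector for one cue-presence vector (0/1 entries).

        Elemental activation is the stimulus presence; configural
        activation is the product of its two constituents' presences.
        """
        x = np.asarray(x)
        if x.shape != (self.catalog.n_stimuli,):
            raise ValueError(
                f"cue vector has shape {x.shape}, expected "
                f"({self.catalog.n_stimuli},) over {self.catalog.stimuli}"
            )
        return (x[self._i1] * x[self._i2]).astype(np.float64)


def build_basis(
    catalog: StimulusCatalog,
    include_configural: bool = False,
    include_contexts: bool = True,
) -> FeatureBasis:
    """Enumerate the feature basis for a catalog in a stable order.

    Order: elemental CS features, elemental context features, then
    configural CS x CS pairs followed by CS x context pairs.
    """
    if catalog.n_stimuli == 0:
        raise ValueError("cannot build a feature basis for an empty catalog")
    feats: list[Feature] = [
        Feature(cs, ELEMENTAL, (cs,)) for cs in catalog.cs_labels
    ]
    if include_contexts:
        feats += [Feature(c, ELEMENTAL, (c,)) for c in catalog.context_labels]
    if include_configural:
        for a, b in combinations(catalog.cs_labels, 2):
            feats.append(Feature(_pair_id(a, b), CONFIGURAL, (a, b)))
        if include_contexts:
            for cs in catalog.cs_labels:
                for ctx in catalog.context_labels:
                    feats.append(Feature(_pair_id(cs, ctx), CONFIGURAL, (cs, ctx)))
    return FeatureBasis(
        catalog=catalog, features=tuple(feats), include_configural=include_configural
    )


def featurize(x: np.ndarray, basis: FeatureBasis) -> np.ndarray:
    """Functional alias for ``basis.featurize(x)``."""
    return basis.featurize(x)
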