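import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearsim import (
    Design,
    Stage,
    StimulusCatalog,
    TrialSpec,
    design_from_dict,
    design_to_dict,
    expand,
    load_design,
    round_robin,
    save_design,
    validate_design,
)


def make_design(groups, cs=("CS",), contexts=("A", "B"), trials=None):
    trials = trials or {
        "CS+": TrialSpec("CS+", {"CS"}, 1),
        "CS-": TrialSpec("CS-", {"CS"}, 0),
    }
    return Design(StimulusCatalog(cs, contexts), trials, groups)


@pytest.fixture
def aba_design():
    cond = Stage("cond", "A", ("CS+",) * 2)
    ext = Stage("ext", "B", ("CS-",) * 3)
    return make_design({"Same": (cond,), "Different": (cond, ext)})


class TestValidation:
    def test_well_formed_design_has_no_violations(self, aba_design):
        assert validate_design(aba_design) == []

    @pytest.mark.parametrize(
        "design, fragment",
        [
            (  # undefined context
                make_design({"g": (Stage("s", "Z", ("CS+",)),)}),
                "'Z'",
            ),
            (  # trials and delay together
                make_design(
                    {"g": (Stage("s", "A", ("CS+",), delay_steps=100),)}
                ),
                "both trials and delay",
            ),
            (  # neither trials nor delay
                make_design({"g": (Stage("s", "A", ()),)}),
                "neither trials nor delay",
            ),
            (  # undefined trial type
                make_design({"g": (Stage("s", "A", ("NOPE",)),)}),
                "'NOPE'",
            ),
            (  # duplicate labels across cs and contexts
                make_design(
                    {"g": (Stage("s", "A", ("CS+",)),)}, cs=("A",), contexts=("A",)
                ),
                "duplicate",
            ),
            (  # no context labels at all
                make_design(
                    {"g": (Stage("s", None, (), delay_steps=5),)}, contexts=()
                ),
                "no context labels",
            ),
            (  # empty group
                make_design({"g": ()}),
                "no stages",
            ),
        ],
    )
    def test_violations_are_reported_not_raised(self, design, fragment):
        violations = validate_design(design)
        assert violations, "expected at least one violation"
        assert any(fragment in v for v in violations)

    def test_trial_referencing_undefined_cue(self):
        d = make_design(
            {"g": (Stage("s", "A", ("bad",)),)},
            trials={"bad": TrialSpec("bad", {"GHOST"}, 0)},
        )
        assert any("GHOST" in v for v in validate_design(d))


class TestExpansion:
    def test_two_trials_iti5_gives_twelve_steps(self):
        d = make_design({"g": (Stage("s", "A", ("CS+", "CS+"), iti_steps=5),)})
        seq = expand(d, "g")
        assert len(seq) == 12
        # trials at positions 6 and 12, 1-based
        assert list(np.flatnonzero(seq.is_trial)) == [5, 11]

    def test_delay_stage_emits_featureless_steps(self):
        d = make_design(
            {"g": (Stage("pause", None, (), delay_steps=1000),)}
        )
        seq = expand(d, "g")
        assert len(seq) == 1000
        assert not seq.x.any()
        assert not seq.y.any()
        assert (seq.kind == "delay").all()

    def test_iti_steps_carry_only_the_stage_context(self, aba_design):
        seq = expand(aba_design, "Different")
        iti = seq.kind == "iti"
        ext_iti = iti & (seq.stage == "ext")
        b_col = aba_design.catalog.index("B")
        assert (seq.x[ext_iti].sum(axis=1) == 1).all()
        assert (seq.x[ext_iti, b_col] == 1).all()
        assert not seq.y[iti].any()

    def test_us_steps_equal_reinforced_trial_count(self, aba_design):
        seq = expand(aba_design, "Different")
        assert seq.y.sum() == 2  # two CS+ trials
        assert (seq.y[~seq.is_trial] == 0).all()

    def test_expansion_is_deterministic(self, aba_design):
        a = expand(aba_design, "Different")
        b = expand(aba_design, "Different")
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert (a.stage == b.stage).all()

    def test_unknown_group_error_names_the_label(self, aba_design):
        with pytest.raises(ValueError, match="ghost"):
            expand(aba_design, "ghost")

    def test_invalid_design_is_rejected(self):
        d = make_design({"g": (Stage("s", "Z", ("CS+",)),)})
        with pytest.raises(ValueError, match="invalid design"):
            expand(d, "g")


@settings(max_examples=50, deadline=None)
@given(
    n_trials=st.integers(0, 6),
    iti=st.integers(0, 7),
    delay=st.integers(1, 50),
)
def test_expansion_length_and_context_invariants(n_trials, iti, delay):
    """Total length is trials*(iti+1) + delay; one context on non-delay steps."""
    stages = []
    if n_trials:
        stages.append(Stage("s", "A", ("CS+",) * n_trials, iti_steps=iti))
    stages.append(Stage("d", None, (), delay_steps=delay))
    d = make_design({"g": tuple(stages)})
    seq = expand(d, "g")
    assert len(seq) == n_trials * (iti + 1) + delay
    ctx_cols = [d.catalog.index(c) for c in d.catalog.context_labels]
    n_ctx = seq.x[:, ctx_cols].sum(axis=1)
    assert (n_ctx[seq.kind != "delay"] == 1).all()
    assert (n_ctx[seq.kind == "delay"] == 0).all()
    assert seq.y.sum() == n_trials


def test_round_robin_interleaves_in_order():
    assert round_robin({"A+": 2, "A.X-": 2}) == ("A+", "A.X-", "A+", "A.X-")
    assert round_robin({"a": 3, "b": 1}) == ("a", "b", "a", "a")


class TestSerialization:
    def test_json_round_trip(self, aba_design, tmp_path):
        path = tmp_path / "design.json"
        save_design(aba_design, path)
        loaded = load_design(path)
        assert design_to_dict(loaded) == design_to_dict(aba_design)
        assert np.array_equal(
            expand(loaded, "Different").x, expand(aba_design, "Different").x
        )

    def test_yaml_round_trip(self, aba_design, tmp_path):
        path = tmp_path / "design.yaml"
        save_design(aba_design, path)
        loaded = load_design(path)
        assert design_to_dict(loaded) == design_to_dict(aba_design)

    def test_counted_trial_shorthand(self):
        d = design_from_dict(
            {
                "catalog": {"cs": ["CS"], "contexts": ["A"]},
                "trials": {"CS+": {"cues": ["CS"], "us": 1}},
                "groups": {"g": [{"label": "s", "context": "A", "trials": [["CS+", 3]]}]},
            }
        )
        assert d.groups["g"][0].trials == ("CS+",) * 3

    def test_timestep_export_columns(self, aba_design):
        df = expand(aba_design, "Different").to_frame()
        for col in ("step", "stage", "is_trial", "trial_name", "CS", "A", "B", "y"):
            assert col in df.columns
        assert df["y"].sum() == 2
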