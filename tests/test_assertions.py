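"""Assertion engine: detection, testing, fold change, confidence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import exocube as xc
from exocube.errors import FormatError, InputError

from oracles import welch_p


CFG = xc.AssertionConfig(detection_threshold=10.0)


class TestDetectPresence:
    def test_all_below_threshold(self):
        assert not xc.detect_presence([0, 0, 0], CFG)

    def test_min_replicate_count(self):
        cfg = xc.AssertionConfig(detection_threshold=10.0, min_detected_replicates=2)
        assert xc.detect_presence([50, 60, 0], cfg)
        assert not xc.detect_presence([50, 0, 0], cfg)

    def test_strict_inequality_at_threshold(self):
        assert not xc.detect_presence([11], xc.AssertionConfig(detection_threshold=11.0))

    def test_empty_or_bad_input(self):
        with pytest.raises(InputError):
            xc.detect_presence([], CFG)
        with pytest.raises(InputError):
            xc.detect_presence([1.0, float("nan")], CFG)
        with pytest.raises(InputError):
            xc.detect_presence([1.0, -2.0], CFG)


class TestAssertAction:
    def test_undetected_on_both_sides_is_not_investigated(self):
        res = xc.assert_action([0, 0, 0], [0, 0, 0], CFG)
        assert res.action is xc.ActionCode.NOT_INVESTIGATED
        assert res.confidence == 0.0 and res.log2fc is None and res.p_value is None

    def test_fourfold_increase_with_welch_oracle(self):
        control, spent = [100, 110, 90], [400, 380, 420]
        res = xc.assert_action(control, spent, CFG)
        assert res.action is xc.ActionCode.INCREASED
        assert res.log2fc == pytest.approx(2.0)  # log2(400/100)
        assert res.confidence == pytest.approx(2.0)
        assert res.p_value == pytest.approx(welch_p(spent, control), rel=1e-9)

    def test_identical_distributions_are_no_change(self):
        res = xc.assert_action([100, 101, 99], [100, 99, 101], CFG)
        assert res.action is xc.ActionCode.NO_CHANGE
        assert res.confidence == 0.0

    def test_one_sided_detection_gets_the_cap_exactly(self):
        res = xc.assert_action([0, 0, 0], [500, 520, 480], CFG)
        assert res.action is xc.ActionCode.INCREASED
        assert res.confidence == xc.CONFIDENCE_CAP
        assert res.log2fc is None
        # and the mirrored disappearance
        res = xc.assert_action([500, 520, 480], [0, 0, 0], CFG)
        assert res.action is xc.ActionCode.DECREASED
        assert res.confidence == xc.CONFIDENCE_CAP

    def test_degenerate_equal_constants_are_no_change(self):
        res = xc.assert_action([50, 50, 50], [50, 50, 50], CFG)
        assert res.action is xc.ActionCode.NO_CHANGE

    def test_degenerate_distinct_constants_are_significant(self):
        res = xc.assert_action([50, 50, 50], [100, 100, 100], CFG)
        assert res.action is xc.ActionCode.INCREASED
        assert res.log2fc == pytest.approx(1.0)

    def test_mann_whitney_alternative(self):
        cfg = xc.AssertionConfig(detection_threshold=10.0, test="mann_whitney")
        res = xc.assert_action([100, 110, 90, 95], [400, 380, 420, 410], cfg)
        assert res.action is xc.ActionCode.INCREASED

    def test_confidence_never_exceeds_cap(self):
        res = xc.assert_action([100, 101, 99], [101000, 99000, 100000], CFG)
        assert res.action is xc.ActionCode.INCREASED
        assert res.log2fc == pytest.approx(math.log2(1000), rel=1e-6)
        assert res.confidence == xc.CONFIDENCE_CAP


positive_reps = st.lists(
    st.floats(min_value=20.0, max_value=1e6, allow_nan=False), min_size=2, max_size=6
)


class TestProperties:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(control=positive_reps, spent=positive_reps)
    def test_swapping_pools_mirrors_the_call(self, control, spent):
        fwd = xc.assert_action(control, spent, CFG)
        rev = xc.assert_action(spent, control, CFG)
        mirror = {
            xc.ActionCode.INCREASED: xc.ActionCode.DECREASED,
            xc.ActionCode.DECREASED: xc.ActionCode.INCREASED,
            xc.ActionCode.NO_CHANGE: xc.ActionCode.NO_CHANGE,
            xc.ActionCode.NOT_INVESTIGATED: xc.ActionCode.NOT_INVESTIGATED,
        }
        assert rev.action is mirror[fwd.action]
        if fwd.log2fc is not None:
            assert rev.log2fc == pytest.approx(-fwd.log2fc)
        assert rev.confidence == pytest.approx(fwd.confidence)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(control=positive_reps, spent=positive_reps,
           scale=st.sampled_from([0.25, 3.0, 1000.0]))
    def test_scaling_units_leaves_the_call_unchanged(self, control, spent, scale):
        base = xc.assert_action(control, spent, CFG)
        scaled_cfg = xc.AssertionConfig(detection_threshold=CFG.detection_threshold * scale)
        scaled = xc.assert_action(
            [v * scale for v in control], [v * scale for v in spent], scaled_cfg
        )
        assert scaled.action is base.action
        if base.log2fc is not None:
            assert scaled.log2fc == pytest.approx(base.log2fc)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(control=positive_reps, spent=positive_reps)
    def test_confidence_bounds_and_zero_pairing(self, control, spent):
        res = xc.assert_action(control, spent, CFG)
        assert 0.0 <= res.confidence <= xc.CONFIDENCE_CAP
        if res.action in (xc.ActionCode.INCREASED, xc.ActionCode.DECREASED):
            assert res.confidence > 0.0
            if res.log2fc is not None:
                assert res.confidence == min(abs(res.log2fc), xc.CONFIDENCE_CAP)
        else:
            assert res.confidence == 0.0


class TestProcessExperiment:
    def test_spiked_directions_recovered(self):
        rng = np.random.default_rng(5)
        base = {"up": (1000.0, 4000.0), "down": (4000.0, 1000.0), "null": (2000.0, 2000.0)}
        abundances = {
            met: (
                (rng.lognormal(np.log(c), 0.05, 5)).tolist(),
                (rng.lognormal(np.log(s), 0.05, 5)).tolist(),
            )
            for met, (c, s) in base.items()
        }
        exp = xc.ReplicateExperiment("R2A", "OrgA", abundances)
        batch = xc.process_experiment(exp, CFG)
        actions = {
            o.metabolite: o.action
            for o in batch.observations
            if o.organism == "OrgA"
        }
        assert actions == {
            "up": xc.ActionCode.INCREASED,
            "down": xc.ActionCode.DECREASED,
            "null": xc.ActionCode.NO_CHANGE,
        }
        controls = {
            o.metabolite: o.action
            for o in batch.observations
            if o.organism == xc.CONTROL_NAME
        }
        assert set(controls.values()) == {xc.ActionCode.DETECTED}

    def test_everything_below_threshold(self):
        exp = xc.ReplicateExperiment(
            "R2A", "OrgA", {"a": ([0, 1], [2, 0]), "b": ([3, 3], [1, 1])}
        )
        batch = xc.process_experiment(exp, CFG)
        organism_actions = {o.action for o in batch.observations if o.organism == "OrgA"}
        control_actions = {o.action for o in batch.observations if o.organism != "OrgA"}
        assert organism_actions == {xc.ActionCode.NOT_INVESTIGATED}
        assert control_actions == {xc.ActionCode.NOT_DETECTED}

    def test_benjamini_hochberg_matches_hand_computed_step_up(self):
        # weak effects, so raw calls flip under correction
        rng = np.random.default_rng(9)
        abundances = {}
        for i in range(20):
            mean = 1000.0 * (1.12 if i < 6 else 1.0)
            abundances[f"m{i:02d}"] = (
                rng.lognormal(np.log(1000.0), 0.1, 5).tolist(),
                rng.lognormal(np.log(mean), 0.1, 5).tolist(),
            )
        exp = xc.ReplicateExperiment("R2A", "OrgA", abundances)
        raw = xc.process_experiment(exp, CFG)
        bh = xc.process_experiment(
            exp, xc.AssertionConfig(detection_threshold=10.0, mtc="benjamini_hochberg")
        )
        raw_p = sorted(
            o.p_value for o in raw.observations if o.organism == "OrgA"
        )
        m = len(raw_p)
        # hand-computed BH step-up threshold: largest k with p_(k) <= k/m * alpha
        passing = [k for k in range(1, m + 1) if raw_p[k - 1] <= k / m * 0.05]
        expected_calls = max(passing) if passing else 0
        bh_calls = sum(
            o.action in (xc.ActionCode.INCREASED, xc.ActionCode.DECREASED)
            for o in bh.observations
            if o.organism == "OrgA"
        )
        assert bh_calls == expected_calls
        raw_calls = sum(
            o.action in (xc.ActionCode.INCREASED, xc.ActionCode.DECREASED)
            for o in raw.observations
            if o.organism == "OrgA"
        )
        assert bh_calls <= raw_calls

    def test_per_metabolite_errors_collected_not_fatal(self):
        exp = xc.ReplicateExperiment(
            "R2A", "OrgA", {"good": ([100, 110], [400, 380]), "bad": ([], [1, 2])}
        )
        batch = xc.process_experiment(exp, CFG)
        assert "bad" in batch.errors
        assert {o.metabolite for o in batch.observations} == {"good"}
        assert batch.config["alpha"] == 0.05  # provenance snapshot

    def test_batch_builds_a_valid_datacube(self):
        exp, _ = xc.generate_experiment(xc.ExperimentSpec(n_metabolites=30, seed=3))
        batch = xc.process_experiment(exp, CFG)
        assert xc.validate(batch.to_datacube()) == []


class TestConfigIO:
    def test_flat_key_value_file(self, tmp_path):
        f = tmp_path / "assert.cfg"
        f.write_text(
            "# pipeline settings\n"
            "detection_threshold = 25.5\n"
            "test = mann_whitney\n"
            "alpha = 0.01\n"
            "mtc = benjamini_hochberg\n"
            "min_detected_replicates = 2\n"
        )
        cfg = xc.read_config(f)
        assert cfg.detection_threshold == 25.5
        assert cfg.test == "mann_whitney"
        assert cfg.alpha == 0.01
        assert cfg.mtc == "benjamini_hochberg"
        assert cfg.min_detected_replicates == 2

    def test_unknown_key_rejected(self, tmp_path):
        f = tmp_path / "assert.cfg"
        f.write_text("fudge_factor = 2\n")
        with pytest.raises(FormatError, match="fudge_factor"):
            xc.read_config(f)

    def test_bad_parameters_rejected(self):
        with pytest.raises(InputError):
            xc.AssertionConfig(alpha=1.5)
        with pytest.raises(InputError):
            xc.AssertionConfig(test="anova")
        with pytest.raises(InputError):
            xc.AssertionConfig(detection_threshold=-1)
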