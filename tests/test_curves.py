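"""QC, imputation, aggregation, normalization, mapping and anchoring."""

import numpy as np
import pytest
from scipy.stats import binomtest

import satbench as sb
from satbench import (
    ExperimentDesign,
    ObserverSpec,
    SATCurve,
    add_chance_anchor,
    compute_curve,
    discard_warmup,
    filter_observers,
    impute_missing,
    map_timesteps,
    normalize_curve,
    simulate_observer,
    to_family,
    untimed_accuracy,
)

from conftest import make_trial, make_training_trial


def observer_block(observer_id, rts, latency=500):
    """One observer's timed trials with the given response times (None = miss)."""
    return [
        make_trial(
            observer_id=observer_id,
            beep_latency_ms=latency,
            response_time_ms=rt,
            response_category=None if rt is None else "cat",
            trial_index=i + 1,
        )
        for i, rt in enumerate(rts)
    ]


class TestFilterObservers:
    def test_on_beep_kept_all_missing_excluded(self, design):
        trials = observer_block("good", [500.0] * 10) + observer_block("bad", [None] * 10)
        kept, excluded = filter_observers(trials, design)
        assert excluded == ["bad"]
        assert {t.observer_id for t in kept} == {"good"}
        assert kept == [t for t in trials if t.observer_id == "good"]

    def test_half_outside_boundary_is_inclusive(self, design):
        # exactly 50% outside the +/-100 ms window -> excluded
        rts = [500.0] * 5 + [700.0] * 5
        _, excluded = filter_observers(observer_block("edge", rts), design)
        assert excluded == ["edge"]
        # just under 50% -> kept
        rts = [500.0] * 6 + [700.0] * 4
        _, excluded = filter_observers(observer_block("ok", rts), design)
        assert excluded == []

    def test_window_edge_is_within(self, design):
        rts = [600.0] * 10  # exactly +100 ms: inside the window
        _, excluded = filter_observers(observer_block("edge", rts), design)
        assert excluded == []

    def test_training_trials_ignored_for_qc(self, design):
        trials = [make_training_trial(observer_id="o")] + observer_block("o", [500.0] * 4)
        kept, excluded = filter_observers(trials, design)
        assert excluded == [] and len(kept) == 5


class TestDiscardWarmup:
    def test_block_of_210_keeps_200(self, design):
        trials = [make_trial(trial_index=i) for i in range(1, 211)]
        kept = discard_warmup(trials, design)
        assert len(kept) == 200
        assert min(t.trial_index for t in kept) == 11

    def test_zero_discard_is_identity(self):
        d = ExperimentDesign(warmup_discard=0)
        trials = [make_trial(trial_index=i) for i in range(1, 6)]
        assert discard_warmup(trials, d) == trials

    def test_short_block_empties_with_warning(self, design, caplog):
        trials = [make_trial(trial_index=i) for i in range(1, 6)]
        with caplog.at_level("WARNING"):
            assert discard_warmup(trials, design) == []
        assert "warm-up" in caplog.text

    def test_training_untouched(self, design):
        trials = [make_training_trial(trial_index=1)]
        assert discard_warmup(trials, design) == trials

    def test_commutes_with_observer_filter(self, design):
        """On sessions away from the exclusion boundary, QC order does not
        matter: filter-then-discard equals discard-then-filter."""
        specs = sb.sample_observer_specs(3, seed=17)
        trials = [t for s in specs for t in simulate_observer(s, design)]
        a = discard_warmup(filter_observers(trials, design)[0], design)
        b = filter_observers(discard_warmup(trials, design), design)[0]
        assert a == b


class TestImputeMissing:
    def test_identity_when_nothing_missing(self):
        trials = [make_trial(trial_index=i) for i in range(1, 5)]
        assert impute_missing(trials, "random", 0) == trials
        assert impute_missing(trials, "drop") == trials

    def test_drop_removes_all_missing(self):
        trials = observer_block("o", [None] * 6)
        assert impute_missing(trials, "drop") == []

    def test_random_imputation_hits_chance(self, design):
        trials = observer_block("o", [None] * 1600)
        imputed = impute_missing(trials, "random", seed=3, design=design)
        assert not any(t.missing for t in imputed)
        k = sum(t.correct for t in imputed)
        ci = binomtest(k, len(imputed)).proportion_ci(0.999)
        assert ci.low <= 1 / 16 <= ci.high

    def test_seeded_and_mode_validated(self):
        trials = observer_block("o", [None] * 5)
        assert impute_missing(trials, "random", 1) == impute_missing(trials, "random", 1)
        with pytest.raises(ValueError):
            impute_missing(trials, "majority")


class TestComputeCurve:
    def test_accuracy_and_binomial_se(self):
        trials = [
            make_trial(trial_index=i, response_category="cat" if i <= 150 else "dog")
            for i in range(1, 201)
        ]
        (curve,) = compute_curve(trials)
        assert curve.accuracies == (0.75,)
        assert curve.n_trials == (200,)
        assert curve.se[0] == pytest.approx(np.sqrt(0.75 * 0.25 / 200))

    def test_all_correct_has_zero_se(self):
        (curve,) = compute_curve([make_trial(trial_index=i) for i in range(1, 11)])
        assert curve.accuracies == (1.0,) and curve.se == (0.0,)

    def test_category_partition_conserves_counts(self, design):
        trials = simulate_observer(ObserverSpec(seed=5), design)
        trials = impute_missing(discard_warmup(trials, design), "random", 0)
        pooled = compute_curve(trials, group=("observer_id",))
        by_cat = compute_curve(trials, group=("true_category",))
        assert len(by_cat) == 16
        for j, t in enumerate(pooled[0].times):
            total = sum(c.n_trials[j] for c in by_cat)
            assert total == pooled[0].n_trials[j]

    def test_missing_responses_rejected(self):
        with pytest.raises(ValueError, match="impute"):
            compute_curve(observer_block("o", [None]))


class TestUntimedAccuracy:
    def test_fraction_correct(self):
        trials = [
            make_training_trial(trial_index=i, response_category="cat" if i <= 40 else "dog")
            for i in range(1, 51)
        ]
        assert untimed_accuracy(trials) == pytest.approx(0.8)

    def test_per_experiment_partition(self):
        trials = [
            make_training_trial(trial_index=1, experiment="gray_noise"),
            make_training_trial(
                trial_index=2, experiment="color_blur", perturbation_kind="blur",
                perturbation_level=1.5, response_category="dog",
            ),
        ]
        out = untimed_accuracy(trials, per_experiment=True)
        assert out == {"gray_noise": 1.0, "color_blur": 0.0}

    def test_error_without_training(self):
        with pytest.raises(ValueError, match="training"):
            untimed_accuracy([make_trial()])


class TestNormalizeCurve:
    curve = SATCurve(
        label={"perturbation_level": 0.0},
        times=(500, 900),
        accuracies=(0.2, 0.4),
        se=(0.02, 0.04),
    )

    def test_arithmetic_and_se_scaling(self):
        out = normalize_curve(self.curve, 0.8)
        assert out.accuracies == (0.25, 0.5)
        assert out.se == pytest.approx((0.025, 0.05))
        assert out.normalized and out.baseline == 0.8

    def test_unit_baseline_identity(self):
        out = normalize_curve(self.curve, 1.0)
        assert out.accuracies == self.curve.accuracies

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_curve(self.curve, 0.0)


class TestMapTimesteps:
    def model_curve(self, acc=(0.1, 0.3, 0.5, 0.7, 0.8)):
        return SATCurve(label={"perturbation_level": 0.0}, times=(1, 2, 3, 4, 5),
                        accuracies=acc)

    def test_index_mapping_assigns_design_latencies(self, design):
        out = map_timesteps(self.model_curve(), design)
        assert out.times == (500.0, 900.0, 1100.0, 1300.0, 1500.0)
        assert out.accuracies == self.model_curve().accuracies

    def test_index_mapping_length_mismatch(self, design):
        short = SATCurve(label={}, times=(1, 2, 3), accuracies=(0.1, 0.2, 0.3))
        with pytest.raises(ValueError, match="index-mapped"):
            map_timesteps(short, design)

    def test_affine_recovers_known_linear_map(self):
        """With latencies affine in the timestep index and a reference equal
        to the index-mapped curve, the affine fit recovers that mapping."""
        d = ExperimentDesign(beep_latencies_ms=(500, 750, 1000, 1250, 1500))
        mc = self.model_curve()
        ref = map_timesteps(mc, d, mode="index")
        out = map_timesteps(mc, d, mode="affine", reference=ref)
        assert np.allclose(out.times, ref.times, atol=5.0)

    def test_flat_reference_falls_back_to_index(self, design, caplog):
        ref = SATCurve(label={}, times=(500, 900, 1100, 1300, 1500),
                       accuracies=(0.5,) * 5)
        with caplog.at_level("WARNING"):
            out = map_timesteps(self.model_curve(), design, mode="affine", reference=ref)
        assert out.times == (500.0, 900.0, 1100.0, 1300.0, 1500.0)
        assert "index" in caplog.text


class TestChanceAnchor:
    def test_sixteen_way_anchor(self, design):
        curve = SATCurve(label={}, times=(500, 900), accuracies=(0.3, 0.5))
        out = add_chance_anchor(curve, design)
        assert out.anchored
        assert out.times[0] == 0.0
        assert out.accuracies[0] == pytest.approx(0.0625)

    def test_two_way_anchor(self):
        d = ExperimentDesign(n_categories=2, categories=("cat", "dog"))
        curve = SATCurve(label={}, times=(500,), accuracies=(0.9,))
        assert add_chance_anchor(curve, d).accuracies[0] == pytest.approx(0.5)

    def test_normalized_anchor_scales_by_baseline(self, design):
        curve = normalize_curve(
            SATCurve(label={}, times=(500,), accuracies=(0.4,)), 0.8
        )
        out = add_chance_anchor(curve, design)
        assert out.accuracies[0] == pytest.approx(0.0625 / 0.8)

    def test_metrics_ignore_anchor(self, design):
        a = SATCurve(label={"perturbation_level": 0.0}, times=(500, 900, 1100),
                     accuracies=(0.2, 0.4, 0.6))
        b = SATCurve(label={"perturbation_level": 0.0}, times=(500, 900, 1100),
                     accuracies=(0.3, 0.5, 0.6))
        plain = sb.rmse_fit_error(to_family([a]), to_family([b]))
        anchored = sb.rmse_fit_error(
            to_family([add_chance_anchor(a, design)]),
            to_family([add_chance_anchor(b, design)]),
        )
        assert anchored == plain

    def test_double_anchor_rejected(self, design):
        curve = SATCurve(label={}, times=(500,), accuracies=(0.4,))
        with pytest.raises(ValueError, match="anchored"):
            add_chance_anchor(add_chance_anchor(curve, design), design)


class TestToFamily:
    def level_curve(self, level, acc):
        return SATCurve(label={"perturbation_level": level},
                        times=(500, 900, 1100, 1300, 1500), accuracies=acc)

    def test_stacks_in_level_order(self):
        curves = [
            self.level_curve(0.08, (0.1, 0.2, 0.3, 0.4, 0.5)),
            self.level_curve(0.0, (0.2, 0.4, 0.6, 0.7, 0.8)),
            self.level_curve(0.04, (0.15, 0.3, 0.4, 0.5, 0.6)),
        ]
        fam = to_family(curves)
        assert fam.shape == (3, 5)
        assert fam.perturbation_levels == (0.0, 0.04, 0.08)
        assert fam.c[0, 0] == 0.2

    def test_missing_level_zero_rejected(self):
        with pytest.raises(ValueError, match="level-0"):
            to_family([self.level_curve(0.04, (0.1, 0.2, 0.3, 0.4, 0.5))])

    def test_duplicate_level_rejected(self):
        c = self.level_curve(0.0, (0.1, 0.2, 0.3, 0.4, 0.5))
        with pytest.raises(ValueError, match="duplicate"):
            to_family([c, c])

    def test_mismatched_times_rejected(self):
        a = self.level_curve(0.0, (0.1, 0.2, 0.3, 0.4, 0.5))
        b = SATCurve(label={"perturbation_level": 0.04}, times=(1, 2, 3),
                     accuracies=(0.1, 0.2, 0.3))
        with pytest.raises(ValueError, match="time axes"):
            to_family([a, b])

    def test_single_level_family(self):
        fam = to_family([self.level_curve(0.0, (0.1, 0.2, 0.3, 0.4, 0.5))])
        assert fam.shape == (1, 5)
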