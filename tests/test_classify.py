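import numpy as np
import pytest

from nanodst.classify import (
    SplitAssignment,
    evaluate,
    exposure_sweep,
    fit,
    forward_select,
    prevalence_baseline,
    score_and_classify,
    stratified_split,
)
from nanodst.features import FeatureDescriptor, FeatureMatrix


def make_matrix(values, labels):
    values = np.asarray(values, dtype=float)
    descriptors = [
        FeatureDescriptor("band_power", (float(j), float(j) + 1.0), 0.5, (0.0, 10.0), 50.0)
        for j in range(values.shape[1])
    ]
    return FeatureMatrix(
        values=values,
        descriptors=descriptors,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        labels=list(labels),
    )


def labeled_matrix(n_pos, n_neg, n_features=5, informative=0, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = ["positive"] * n_pos + ["negative"] * n_neg
    X = rng.standard_normal((n_pos + n_neg, n_features))
    X[:n_pos, informative] += sep
    return make_matrix(X, labels)


class TestStratifiedSplit:
    @pytest.mark.parametrize(
        "n,expected",
        [(34, (22, 5, 7)), (24, (16, 4, 4)), (38, (25, 6, 7)), (36, (24, 6, 6)), (6, (4, 1, 1))],
    )
    def test_floor_remainder_rule(self, n, expected):
        split = stratified_split(["x"] * n, seed=0)
        counts = split.counts()
        assert (counts["train"], counts["validation"], counts["test"]) == expected

    def test_both_printed_split_tables(self):
        # treated/untreated 34/24 and susceptible/resistant 38/36
        for sizes, per_stratum in [
            ((34, 24), {(34, "p"): (22, 5, 7), (24, "n"): (16, 4, 4)}),
            ((38, 36), {(38, "p"): (25, 6, 7), (36, "n"): (24, 6, 6)}),
        ]:
            labels = ["p"] * sizes[0] + ["n"] * sizes[1]
            split = stratified_split(labels, seed=3)
            for (n, lab), expected in per_stratum.items():
                c = split.counts(stratum=lab)
                assert (c["train"], c["validation"], c["test"]) == expected

    def test_every_sample_assigned_once(self):
        split = stratified_split(["a"] * 17 + ["b"] * 9, seed=5)
        assert set(split.subsets) <= {"train", "validation", "test"}
        assert len(split.subsets) == 26

    def test_membership_randomized_but_deterministic(self):
        labels = ["x"] * 30
        a = stratified_split(labels, seed=1)
        b = stratified_split(labels, seed=1)
        c = stratified_split(labels, seed=2)
        assert list(a.subsets) == list(b.subsets)
        assert list(a.subsets) != list(c.subsets)

    def test_tiny_stratum_warns(self):
        with pytest.warns(UserWarning, match="only 2 samples"):
            stratified_split(["a"] * 2 + ["b"] * 12, seed=0)

    def test_concentration_strata(self):
        labels = ["p"] * 12 + ["n"] * 12
        conc = ([0.01] * 6 + [10.0] * 6) * 2
        split = stratified_split(labels, strata=list(zip(labels, conc)), seed=0)
        for stratum in set(zip(labels, conc)):
            c = split.counts(stratum=stratum)
            assert (c["train"], c["validation"], c["test"]) == (4, 1, 1)


class TestForwardSelect:
    def test_perfectly_separating_feature_chosen_first(self):
        fm = labeled_matrix(10, 10, n_features=6, informative=3, sep=8.0)
        split = stratified_split(fm.labels, seed=0)
        selected = forward_select(fm, split, max_features=2)
        assert selected[0].name == fm.descriptors[3].name

    def test_cap_at_max_features(self):
        fm = labeled_matrix(12, 12, n_features=8, sep=0.5)
        split = stratified_split(fm.labels, seed=1)
        assert len(forward_select(fm, split, max_features=2)) <= 2

    def test_greedy_first_pick_matches_exhaustive_oracle(self):
        """On a small grammar the first greedy pick must equal the argmax of
        brute-force single-feature accuracies."""
        from nanodst.classify import _accuracy, _fit_logistic, _standardize

        fm = labeled_matrix(15, 12, n_features=12, informative=7, sep=1.5, seed=4)
        split = stratified_split(fm.labels, seed=2)
        y = np.array([l == "positive" for l in fm.labels])
        tr = split.indices("train")
        pool = split.indices("train", "validation")
        best = None
        for i in range(fm.values.shape[1]):
            m, s = _standardize(fm.values[np.ix_(tr, [i])])
            clf = _fit_logistic((fm.values[np.ix_(tr, [i])] - m) / s, y[tr], 1000.0)
            scores = ((fm.values[np.ix_(pool, [i])] - m) / s) @ clf.coef_[0] + clf.intercept_[0]
            acc = _accuracy(scores, y[pool])
            if best is None or acc > best[0] or (acc == best[0] and fm.names[i] < fm.names[best[1]]):
                best = (acc, i)
        selected = forward_select(fm, split, max_features=2)
        assert selected[0].name == fm.names[best[1]]

    def test_zero_variance_features_skipped(self):
        fm = labeled_matrix(10, 10, n_features=4, informative=2, sep=6.0)
        fm.values[:, 0] = 1.0  # constant column
        split = stratified_split(fm.labels, seed=0)
        selected = forward_select(fm, split)
        assert fm.descriptors[0].name not in [d.name for d in selected]


class TestFitAndScore:
    def test_refit_is_deterministic(self):
        fm = labeled_matrix(10, 8)
        split = stratified_split(fm.labels, seed=0)
        sel = [fm.descriptors[0], fm.descriptors[1]]
        a, b = fit(fm, split, sel), fit(fm, split, sel)
        np.testing.assert_array_equal(a.coef, b.coef)
        assert a.intercept == b.intercept

    def test_label_swap_negates_scores(self):
        fm = labeled_matrix(10, 10, sep=2.0)
        split = stratified_split(fm.labels, seed=0)
        sel = [fm.descriptors[0]]
        model = fit(fm, split, sel)
        flipped = make_matrix(
            fm.values, ["negative" if l == "positive" else "positive" for l in fm.labels]
        )
        model_f = fit(flipped, split, sel)
        np.testing.assert_allclose(
            model_f.scores(fm), -model.scores(fm), atol=1e-6
        )

    def test_separable_feature_reproduces_training_labels(self):
        fm = labeled_matrix(8, 8, n_features=1, informative=0, sep=10.0)
        split = stratified_split(fm.labels, seed=0)
        model = fit(fm, split, [fm.descriptors[0]])
        _, predicted = score_and_classify(model, fm)
        tr = split.indices("train")
        y = np.array([l == "positive" for l in fm.labels])
        assert np.all(predicted[tr] == y[tr])

    def test_boundary_score_zero_is_positive(self):
        from nanodst.classify import TrainedClassifier

        fm = labeled_matrix(1, 0, n_features=1)
        fm.values[0, 0] = 0.0
        model = TrainedClassifier(
            selected=[fm.descriptors[0]],
            means=np.array([0.0]),
            scales=np.array([1.0]),
            coef=np.array([2.0]),
            intercept=0.0,
        )
        scores, predicted = score_and_classify(model, fm)
        assert scores[0] == 0.0
        assert bool(predicted[0]) is True

    def test_score_sign_invariant_to_positive_rescaling(self):
        from nanodst.classify import TrainedClassifier

        fm = labeled_matrix(5, 5, n_features=1, sep=3.0)
        base = TrainedClassifier(
            selected=[fm.descriptors[0]],
            means=np.array([0.0]),
            scales=np.array([1.0]),
            coef=np.array([1.5]),
            intercept=0.3,
        )
        scaled = TrainedClassifier(
            selected=[fm.descriptors[0]],
            means=np.array([0.0]),
            scales=np.array([1.0]),
            coef=np.array([1.5 * 7.0]),
            intercept=0.3 * 7.0,
        )
        _, pred_a = score_and_classify(base, fm)
        _, pred_b = score_and_classify(scaled, fm)
        np.testing.assert_array_equal(pred_a, pred_b)

    def test_single_class_training_rejected(self):
        fm = labeled_matrix(6, 0)
        split = SplitAssignment(
            subsets=np.array(["train"] * 6, dtype=object), strata=fm.labels
        )
        with pytest.raises(ValueError, match="both classes"):
            fit(fm, split, [fm.descriptors[0]])

    def test_test_rows_cannot_influence_fit(self):
        fm = labeled_matrix(12, 12, sep=3.0, seed=8)
        split = stratified_split(fm.labels, seed=0)
        model_a = fit(fm, split, [fm.descriptors[0]])
        sel_a = forward_select(fm, split)
        corrupted = make_matrix(fm.values.copy(), fm.labels)
        corrupted.values[split.indices("test")] += 1e3
        model_b = fit(corrupted, split, [fm.descriptors[0]])
        sel_b = forward_select(corrupted, split)
        np.testing.assert_array_equal(model_a.coef, model_b.coef)
        assert model_a.means == pytest.approx(model_b.means)
        assert [d.name for d in sel_a] == [d.name for d in sel_b]


class TestEvaluate:
    @pytest.mark.parametrize("n_pos,n_neg,expected", [(7, 4, 0.64), (7, 6, 0.54)])
    def test_random_ap_baseline_is_prevalence(self, n_pos, n_neg, expected):
        assert round(prevalence_baseline(n_pos, n_neg), 2) == expected

    def test_perfect_ranking_gives_unit_ap(self):
        fm = labeled_matrix(7, 4, n_features=1, sep=10.0)
        split = SplitAssignment(
            subsets=np.array(["train"] * 5 + ["test"] * 6, dtype=object),
            strata=fm.labels,
        )
        # train rows: 5 positives would be single-class; rebuild with mix
        fm = labeled_matrix(7, 4, n_features=1, sep=10.0)
        split = stratified_split(fm.labels, seed=0)
        model = fit(fm, split, [fm.descriptors[0]])
        report = evaluate(model, fm, split, "test")
        assert report.average_precision == 1.0
        assert report.accuracy == 1.0
        assert report.recall_positive == 1.0
        assert report.recall_negative == 1.0

    def test_subset_without_positives_rejected(self):
        fm = labeled_matrix(9, 3, n_features=1, sep=5.0)
        split = stratified_split(fm.labels, seed=0)
        bad = make_matrix(fm.values, ["negative"] * 12)
        model = fit(fm, split, [fm.descriptors[0]])
        with pytest.raises(ValueError, match="no positives"):
            evaluate(model, bad, split, "test")

    def test_random_scores_ap_converges_to_prevalence(self):
        """Monte-Carlo: the AP of random rankings averages to prevalence."""
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(0)
        y = np.array([True] * 350 + [False] * 200)
        aps = [
            average_precision_score(y, rng.standard_normal(y.size))
            for _ in range(300)
        ]
        assert np.mean(aps) == pytest.approx(prevalence_baseline(350, 200), abs=0.02)


class TestExposureSweep:
    @staticmethod
    def _builder(jump_at):
        """Feature separates classes only for durations >= jump_at."""
        labels = ["positive"] * 12 + ["negative"] * 12
        rng_pool = np.random.default_rng(99).standard_normal((24, 1))

        def build(duration_min):
            if duration_min < 5.0:
                raise ValueError("shorter than one window")
            if duration_min >= jump_at:
                X = np.array([[10.0 if l == "positive" else -10.0] for l in labels])
                X = X + 0.01 * rng_pool
            else:
                X = rng_pool
            return make_matrix(X, labels)

        return build, labels

    def test_constant_curve_plateaus_at_first_point(self):
        build, labels = self._builder(jump_at=0.0)
        split = stratified_split(labels, seed=0)
        sweep = exposure_sweep(build, split, grid=[15, 30, 45, 60], tolerance=0.0, seed=0)
        assert sweep.plateau_min == 15
        np.testing.assert_allclose(sweep.accuracies, 1.0)

    def test_saturating_effect_plateaus_near_jump(self):
        build, labels = self._builder(jump_at=45.0)
        split = stratified_split(labels, seed=0)
        sweep = exposure_sweep(build, split, grid=[15, 30, 45, 60], tolerance=0.0, seed=0)
        assert sweep.plateau_min == 45

    def test_increasing_curve_plateaus_at_last_point(self):
        labels = ["positive"] * 12 + ["negative"] * 12
        rng = np.random.default_rng(1)
        base = np.array([[1.0 if l == "positive" else -1.0] for l in labels])
        noise = rng.standard_normal((24, 1))

        def build(duration_min):
            snr = duration_min / 60.0
            return make_matrix(base * snr + noise * (1.2 - snr), labels)

        split = stratified_split(labels, seed=0)
        sweep = exposure_sweep(build, split, grid=[15, 30, 45, 60], tolerance=0.0, seed=0)
        if np.all(np.diff(sweep.accuracies) > 0):
            assert sweep.plateau_min == 60

    def test_generator_effect_saturation_plateaus_early(self):
        """With a strong, fast-onset band effect the cross-validated accuracy
        saturates within the first exposure durations, so the plateau lands
        at an early grid point."""
        from nanodst.features import FeatureGrammar, build_feature_matrix
        from nanodst.quantile_spectra import quantile_spectrogram
        from nanodst.signals import Phase
        from nanodst.synthetic import (
            EffectConfig,
            NoiseConfig,
            SimulationConfig,
            SpikeConfig,
            member_configs,
            simulate_recording,
        )

        template = SimulationConfig(
            sampling_rate=500.0, blank_min=0.5, medium_min=5.0, drug_min=30.0,
            noise=NoiseConfig(pink_amplitude=0.0),
            spikes=SpikeConfig(rate_hz=0.0),
            effect=EffectConfig(
                band_lo_hz=0.5, band_hi_hz=10.0, power_ratio=0.1, tau_min=2.0
            ),
        )
        specs, labels = [], []
        for cfg in member_configs(8, 8, template, seed=21):
            rec = simulate_recording(cfg)
            specs.append(
                quantile_spectrogram(rec, window_min=5.0, phases=[Phase.DRUG])
            )
            labels.append(cfg.label.value)

        def build(duration_min):
            grammar = FeatureGrammar(
                kinds=("band_power",),
                bands_hz=((0.5, 10.0), (10.0, 100.0)),
                levels=(0.5,),
                intervals_min=((5.0, 5.0 + duration_min - 4.9),),
                summary_pcts=(50.0,),
            )
            return build_feature_matrix(specs, grammar, labels=labels)

        split = stratified_split(labels, seed=0)
        sweep = exposure_sweep(build, split, grid=[10, 20, 30], tolerance=0.0, seed=0)
        assert sweep.plateau_min <= 20
        assert sweep.accuracies[-1] >= 0.9

    def test_too_short_durations_skipped(self):
        build, labels = self._builder(jump_at=0.0)
        split = stratified_split(labels, seed=0)
        sweep = exposure_sweep(build, split, grid=[1, 15, 30], tolerance=0.0, seed=0)
        np.testing.assert_array_equal(sweep.exposure_min, [15, 30])
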