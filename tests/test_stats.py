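import numpy as np
import pytest

from rattlekit.containers import AnnotationTrack, Condition, Interval, Tier, ValidationError
from rattlekit.stats import (
    build_longitudinal_table,
    cohens_kappa,
    fit_repeated_effects,
)

TP = ["T1", "T2", "T3", "T4"]


def _table(values, metric="rattling_frequency_hz", condition="ALL"):
    """values: dict subject -> list of 4 per-timepoint values (None = missing)."""
    rows = []
    for subj, vals in values.items():
        for tp, v in zip(TP, vals):
            if v is None:
                continue
            rows.append(
                {"subject_id": subj, "timepoint": tp, "condition": condition,
                 "metric": metric, "value": v}
            )
    return build_longitudinal_table(rows)


def _simulated_table(rng, effect=0.0, n_subjects=20, noise=0.3):
    values = {}
    for i in range(n_subjects):
        base = rng.normal(1.0, 0.2)
        values[f"s{i:02d}"] = [
            base + effect * k + rng.normal(0, noise) for k in range(4)
        ]
    return _table(values)


class TestTable:
    def test_duplicate_cell_rejected(self):
        rows = [
            {"subject_id": "a", "timepoint": "T1", "condition": "ALL",
             "metric": "m", "value": 1.0}
        ] * 2
        with pytest.raises(ValidationError, match="duplicate"):
            build_longitudinal_table(rows)

    def test_unknown_timepoint_rejected(self):
        rows = [{"subject_id": "a", "timepoint": "T9", "condition": "ALL",
                 "metric": "m", "value": 1.0}]
        with pytest.raises(ValidationError, match="timepoint"):
            build_longitudinal_table(rows)

    def test_timepoints_ordered_categorical(self):
        t = _table({"a": [1, 2, 3, 4]})
        assert list(t["timepoint"].cat.categories) == TP


class TestRepeatedEffects:
    def test_planted_age_effect_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            table = _simulated_table(rng, effect=0.25)
            rep = fit_repeated_effects(table, "rattling_frequency_hz")
            if rep.effects["timepoint"]["p"] < 0.05:
                hits += 1
        assert hits >= 18

    def test_near_constant_metric_not_significant(self):
        rng = np.random.default_rng(1)
        table = _simulated_table(rng, effect=0.0, noise=0.3)
        rep = fit_repeated_effects(table, "rattling_frequency_hz")
        assert rep.effects["timepoint"]["p"] > 0.05

    def test_type_one_error_controlled(self):
        # checked in the asymptotic regime (80 clusters): the robust GEE
        # Wald test is mildly anti-conservative at small cluster counts
        # (~7% at 40 clusters), which is a property of the sandwich
        # covariance, not of this implementation
        rng = np.random.default_rng(2)
        false_pos = 0
        n_rep = 200
        for _ in range(n_rep):
            table = _simulated_table(rng, effect=0.0, n_subjects=80)
            rep = fit_repeated_effects(table, "rattling_frequency_hz")
            if rep.effects["timepoint"]["p"] < 0.05:
                false_pos += 1
        assert false_pos / n_rep <= 0.075

    def test_bonferroni_adjustment_and_pair_count(self):
        rng = np.random.default_rng(3)
        rep = fit_repeated_effects(
            _simulated_table(rng, effect=0.3), "rattling_frequency_hz"
        )
        assert len(rep.pairwise) == 6  # C(4,2) timepoint pairs
        for pw in rep.pairwise:
            assert pw.p_adj == pytest.approx(min(1.0, pw.p_raw * 6))

    def test_direction_consistent_with_paired_t(self):
        rng = np.random.default_rng(4)
        values = {f"s{i}": [1.0 + rng.normal(0, 0.1),
                            2.0 + rng.normal(0, 0.1), None, None]
                  for i in range(12)}
        table = _table(values)
        rep = fit_repeated_effects(table, "rattling_frequency_hz")
        pw = rep.pairwise[0]
        assert (pw.level_a, pw.level_b) == ("T1", "T2")
        assert pw.estimate > 0  # T2 above T1
        assert pw.p_adj < 0.05

    def test_level_without_data_rejected(self):
        values = {"a": [1.0, None, None, None], "b": [2.0, None, None, None]}
        with pytest.raises(ValidationError, match="fewer than 2"):
            fit_repeated_effects(_table(values), "rattling_frequency_hz")

    def test_poisson_family_for_counts(self):
        rng = np.random.default_rng(5)
        values = {f"s{i}": list(rng.poisson([10, 15, 25, 40]))
                  for i in range(15)}
        table = _table(values, metric="n_rattling_movements")
        rep = fit_repeated_effects(table, "n_rattling_movements")
        assert rep.effects["timepoint"]["p"] < 0.05


def _rand_track(rng, extent=100.0, coverage=0.3):
    ivs = []
    t = 0.0
    while t < extent - 2.0:
        gap = rng.exponential(1.0 * (1 - coverage) / coverage)
        dur = rng.exponential(1.0)
        on = t + gap
        off = min(on + max(dur, 0.05), extent)
        if off <= on or on >= extent:
            break
        ivs.append(Interval(Tier.RATTLING, on, off, Condition.MOTHER_NOT_PROVIDING))
        t = off
    return AnnotationTrack(ivs)


class TestKappa:
    def test_identical_tracks_kappa_one(self, rng):
        track = _rand_track(rng)
        assert cohens_kappa(track, track, extent_s=100.0) == pytest.approx(1.0)

    def test_complementary_tracks_nonpositive(self):
        a = AnnotationTrack([Interval(Tier.RATTLING, 0.0, 50.0)])
        b = AnnotationTrack([Interval(Tier.RATTLING, 50.0, 100.0)])
        assert cohens_kappa(a, b, extent_s=100.0) <= 0.0

    def test_independent_tracks_near_zero(self):
        kappas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = _rand_track(rng, extent=400.0)
            b = _rand_track(rng, extent=400.0)
            kappas.append(cohens_kappa(a, b, extent_s=400.0))
        assert np.max(np.abs(kappas)) < 0.15
        assert abs(np.mean(kappas)) < 0.05

    def test_symmetry_and_label_swap_invariance(self, rng):
        a = _rand_track(rng, extent=200.0)
        b = _rand_track(rng, extent=200.0)
        k_ab = cohens_kappa(a, b, extent_s=200.0)
        k_ba = cohens_kappa(b, a, extent_s=200.0)
        assert k_ab == pytest.approx(k_ba)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import cohen_kappa_score

        from rattlekit.sync import binarize_annotations

        a = _rand_track(rng, extent=150.0)
        b = _rand_track(rng, extent=150.0)
        ours = cohens_kappa(a, b, fs=25.0, extent_s=150.0)
        fa = binarize_annotations(a, Tier.RATTLING, 25.0, 150.0)
        fb = binarize_annotations(b, Tier.RATTLING, 25.0, 150.0)
        assert ours == pytest.approx(cohen_kappa_score(fa, fb), abs=1e-12)

    def test_both_constant_same_label_undefined(self):
        a = AnnotationTrack([Interval(Tier.RATTLING, 0.0, 10.0)])
        with pytest.warns(UserWarning, match="undefined"):
            k = cohens_kappa(a, a, extent_s=10.0)
        assert np.isnan(k)
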