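"""Pretext datasets, loss, metrics, training loop, CV and weight transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arrowtime.core_data import Cohort, LabeledSequence, SubjectTimeSeries
from arrowtime.model import ModelConfig, init_model
from arrowtime.training import (
    TrainConfig,
    accuracy,
    auc,
    balanced_accuracy,
    bce_loss,
    build_ocp_pairs,
    build_pcl_pairs,
    build_tr_dataset,
    cross_validate,
    pretrain,
    reverse_time,
    train,
    transfer_weights,
)


def _random_cohort(rng, n, T=8, N=3, labels=None):
    subjects = [
        SubjectTimeSeries(f"s{i}", rng.normal(size=(T, N)),
                          None if labels is None else labels[i])
        for i in range(n)
    ]
    return Cohort("c", subjects)


class TestReverseTime:
    def test_definition(self):
        X = np.array([[1, 10], [2, 20], [3, 30]])
        np.testing.assert_array_equal(reverse_time(X), [[3, 30], [2, 20], [1, 10]])

    def test_single_row_unchanged(self):
        X = np.array([[1.0, 2.0]])
        np.testing.assert_array_equal(reverse_time(X), X)

    @settings(max_examples=30, deadline=None)
    @given(T=st.integers(1, 30), N=st.integers(1, 5), seed=st.integers(0, 10**6))
    def test_involution(self, T, N, seed):
        X = np.random.default_rng(seed).normal(size=(T, N))
        np.testing.assert_array_equal(reverse_time(reverse_time(X)), X)


class TestTRDataset:
    def test_balanced_construction(self, rng):
        cohort = _random_cohort(rng, 10)
        data = build_tr_dataset(cohort)
        assert len(data) == 20
        assert sum(d.y for d in data) == 10
        # each reversed example is the reversal of its forward sibling
        by_id = {}
        for d in data:
            by_id.setdefault(d.origin_id, {})[d.y] = d.values
        for sid, pair in by_id.items():
            np.testing.assert_array_equal(pair[1], reverse_time(pair[0]))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_tr_dataset(Cohort("empty", []))


class TestBCE:
    def test_half_probability_gives_log2(self):
        assert bce_loss(np.array([0, 1, 1]), np.full(3, 0.5)) == pytest.approx(np.log(2))

    def test_perfect_prediction_near_zero(self):
        assert bce_loss(np.array([0.0, 1.0]), np.array([0.0, 1.0])) < 1e-6

    def test_hand_computed_value(self):
        # -(log 0.9 + log 0.9)/2
        val = bce_loss(np.array([0, 1]), np.array([0.1, 0.9]))
        assert val == pytest.approx(-np.log(0.9), rel=1e-12)


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([1, 0, 1, 0], [0.4] * 4) == 0.5

    def test_antisymmetry_under_score_negation(self, rng):
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        s = rng.normal(size=30)
        assert auc(y, s) == pytest.approx(1.0 - auc(y, -s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.5, 0.6])

    def test_matches_pairwise_oracle(self, rng):
        """Rank formula equals the brute-force P(score_pos > score_neg) + ties/2."""
        for trial in range(30):
            n = int(rng.integers(4, 15))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc(y, s) == pytest.approx(wins / (len(pos) * len(neg)))


class TestBalancedAccuracy:
    def test_mean_of_class_recalls(self):
        y = [0, 0, 0, 1]
        s = [0.1, 0.9, 0.9, 0.9]  # recall 1/3 for class 0, 1 for class 1
        assert balanced_accuracy(y, s) == pytest.approx((1 / 3 + 1) / 2)


class TestPairBuilders:
    def test_ocp_half_split_and_order(self, rng):
        cohort = _random_cohort(rng, 3, T=20)
        pairs = build_ocp_pairs(cohort, segment_len=4, pairs_per_subject=4, seed=0)
        assert len(pairs) == 12
        for sid in ("s0", "s1", "s2"):
            ys = [p.y for p in pairs if p.origin_id == sid]
            assert sorted(ys) == [0, 0, 1, 1]

    def test_ocp_segments_never_overlap(self, rng):
        cohort = _random_cohort(rng, 2, T=20)
        pairs = build_ocp_pairs(cohort, segment_len=5, pairs_per_subject=20, seed=1)
        subj = {s.subject_id: s.values for s in cohort}
        for p in pairs:
            X = subj[p.origin_id]
            # locate segments by matching values (unique with continuous noise)
            a0 = next(t for t in range(16) if np.array_equal(X[t : t + 5], p.segment_a))
            b0 = next(t for t in range(16) if np.array_equal(X[t : t + 5], p.segment_b))
            assert abs(a0 - b0) >= 5
            if p.y == 1:
                assert a0 < b0  # positives keep temporal order
            else:
                assert a0 > b0  # negatives are presented misordered

    def test_pcl_positive_adjacency_and_determinism(self, rng):
        cohort = _random_cohort(rng, 2, T=24)
        pairs = build_pcl_pairs(cohort, window_len=6, pairs_per_subject=6, seed=3)
        again = build_pcl_pairs(cohort, window_len=6, pairs_per_subject=6, seed=3)
        subj = {s.subject_id: s.values for s in cohort}
        for p, q in zip(pairs, again):
            np.testing.assert_array_equal(p.segment_a, q.segment_a)
            assert p.y == q.y
            if p.y == 1:
                X = subj[p.origin_id]
                a0 = next(t for t in range(19) if np.array_equal(X[t : t + 6], p.segment_a))
                np.testing.assert_array_equal(X[a0 + 6 : a0 + 12], p.segment_b)

    def test_too_long_segments_rejected(self, rng):
        cohort = _random_cohort(rng, 2, T=8)
        with pytest.raises(ValueError):
            build_ocp_pairs(cohort, segment_len=5, pairs_per_subject=2, seed=0)
        with pytest.raises(ValueError):
            build_pcl_pairs(cohort, window_len=5, pairs_per_subject=2, seed=0)


def _separable_data(rng, n=24, T=10, N=3):
    """Class 1 sequences trend upward over time; class 0 downward."""
    data = []
    trend = np.linspace(-1, 1, T)[:, None]
    for i in range(n):
        y = i % 2
        sign = 1 if y else -1
        X = sign * trend + 0.1 * rng.normal(size=(T, N))
        data.append(LabeledSequence(X, y, f"d{i}"))
    return data


class TestTrainLoop:
    def test_deterministic_history(self, rng):
        data = _separable_data(rng)
        cfg = TrainConfig(seed=11, max_epochs=5, batch_size=8)
        mcfg = ModelConfig(input_size=3, lstm_hidden=8, attention_hidden=8,
                           decoder_hidden=4, seed=11)
        _, h1 = train(init_model(mcfg), data, cfg)
        _, h2 = train(init_model(mcfg), data, cfg)
        assert h1["train_curve"] == h2["train_curve"]
        assert h1["val_curve"] == h2["val_curve"]

    def test_learns_separable_task(self, rng):
        data = _separable_data(rng, n=32)
        cfg = TrainConfig(seed=0, max_epochs=120, batch_size=8, early_stop_patience=30)
        mcfg = ModelConfig(input_size=3, lstm_hidden=8, attention_hidden=8,
                           decoder_hidden=4, dropout_rate=0.0, seed=0)
        fitted, hist = train(init_model(mcfg), data, cfg)
        X = np.stack([d.values for d in data])
        y = np.array([d.y for d in data], dtype=float)
        assert accuracy(y, fitted.predict_proba(X)) >= 0.9

    def test_zero_patience_stops_at_first_stall(self, rng):
        data = _separable_data(rng)
        cfg = TrainConfig(seed=1, max_epochs=200, early_stop_patience=0, batch_size=8)
        mcfg = ModelConfig(input_size=3, lstm_hidden=4, attention_hidden=4,
                           decoder_hidden=3, seed=1)
        _, hist = train(init_model(mcfg), data, cfg)
        val = hist["val_curve"]
        # with zero patience every epoch before the last must improve on the
        # running best; a final non-improving epoch ends training immediately
        best = np.inf
        for v in val[:-1]:
            assert v < best - 1e-6
            best = min(best, v)
        if len(val) < cfg.max_epochs:
            assert val[-1] >= best - 1e-6

    def test_single_class_data_rejected(self, rng):
        data = [LabeledSequence(rng.normal(size=(6, 3)), 1, f"x{i}") for i in range(8)]
        mcfg = ModelConfig(input_size=3, lstm_hidden=4, attention_hidden=4,
                           decoder_hidden=3, seed=0)
        with pytest.raises(ValueError, match="single class"):
            train(init_model(mcfg), data, TrainConfig(seed=0))


class TestTransfer:
    def _configs(self):
        donor_cfg = ModelConfig(input_size=3, lstm_hidden=6, attention_hidden=4,
                                decoder_hidden=3, seed=0)
        target_cfg = ModelConfig(input_size=3, lstm_hidden=6, attention_hidden=4,
                                 decoder_hidden=3, seed=99)
        return donor_cfg, target_cfg

    def test_full_copy(self):
        donor_cfg, target_cfg = self._configs()
        donor = init_model(donor_cfg)
        out = transfer_weights(donor, target_cfg, reinit_head=False)
        for k in donor.parameters:
            np.testing.assert_array_equal(out.parameters[k], donor.parameters[k])
        assert out.provenance.startswith("pretrained:")

    def test_reinit_head_redraws_decoder_only(self):
        donor_cfg, target_cfg = self._configs()
        donor = init_model(donor_cfg)
        out = transfer_weights(donor, target_cfg, reinit_head=True)
        for k in donor.parameters:
            if k.startswith("dec.W"):
                assert not np.array_equal(out.parameters[k], donor.parameters[k]), k
            elif not k.startswith("dec."):
                np.testing.assert_array_equal(out.parameters[k], donor.parameters[k])

    def test_structural_mismatch_rejected(self):
        donor_cfg, _ = self._configs()
        donor = init_model(donor_cfg)
        bad = ModelConfig(input_size=3, lstm_hidden=8, attention_hidden=4,
                          decoder_hidden=3, seed=0)
        with pytest.raises(ValueError, match="lstm_hidden"):
            transfer_weights(donor, bad)


class TestCrossValidate:
    def _labeled_cohort(self, rng, n=20, T=10, N=3):
        subjects = []
        trend = np.linspace(-1, 1, T)[:, None]
        for i in range(n):
            y = i % 2
            sign = 1 if y else -1
            X = sign * trend + 0.1 * rng.normal(size=(T, N))
            subjects.append(SubjectTimeSeries(f"s{i}", X, label=y))
        return Cohort("cv", subjects)

    def test_folds_partition_subjects(self, rng):
        cohort = self._labeled_cohort(rng, n=20)
        mcfg = ModelConfig(input_size=3, lstm_hidden=4, attention_hidden=4,
                           decoder_hidden=3, seed=0)
        tcfg = TrainConfig(seed=0, max_epochs=2, n_folds=10, batch_size=8)
        folds = cross_validate(cohort, mcfg, tcfg)
        assert len(folds) == 10
        for f in folds:
            assert 0 <= f.auc <= 1
            assert 0 <= f.balanced_accuracy <= 1

    def test_too_many_folds_rejected(self, rng):
        cohort = self._labeled_cohort(rng, n=8)
        mcfg = ModelConfig(input_size=3, lstm_hidden=4, attention_hidden=4,
                           decoder_hidden=3, seed=0)
        with pytest.raises(ValueError, match="n_folds"):
            cross_validate(cohort, mcfg, TrainConfig(seed=0, n_folds=10))

    def test_separable_cohort_reaches_high_auc(self, rng):
        cohort = self._labeled_cohort(rng, n=24)
        mcfg = ModelConfig(input_size=3, lstm_hidden=8, attention_hidden=8,
                           decoder_hidden=4, dropout_rate=0.0, seed=0)
        tcfg = TrainConfig(seed=0, max_epochs=100, early_stop_patience=25,
                           n_folds=4, batch_size=8, val_fraction=0.25)
        folds = cross_validate(cohort, mcfg, tcfg)
        assert np.median([f.auc for f in folds]) >= 0.9


class TestPretrain:
    def test_unknown_method_rejected(self, rng):
        cohort = _random_cohort(rng, 4)
        mcfg = ModelConfig(input_size=3, lstm_hidden=4, attention_hidden=4,
                           decoder_hidden=3, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            pretrain("simclr", cohort, mcfg, TrainConfig(seed=0))

    def test_tr_pretraining_learns_chirp_arrow(self, small_chirp_cohort):
        mcfg = ModelConfig(input_size=6, lstm_hidden=32, attention_hidden=32,
                           decoder_hidden=8, dropout_rate=0.2, seed=7)
        tcfg = TrainConfig(seed=7, max_epochs=150, early_stop_patience=20)
        _, acc = pretrain("tr", small_chirp_cohort, mcfg, tcfg)
        assert acc >= 0.9

    def test_ocp_pretraining_beats_chance_on_chirps(self):
        # frequencies kept below Nyquist at this length so that short
        # segments still carry readable frequency ordering
        from arrowtime.synthetic import ChirpParams, generate_chirp_cohort

        cohort = generate_chirp_cohort(
            32,
            ChirpParams(n_components=6, n_timepoints=96, f0_range=(1, 4),
                        f1_range=(10, 20), noise_sd=0.1, seed=7),
        )
        mcfg = ModelConfig(input_size=6, lstm_hidden=32, attention_hidden=32,
                           decoder_hidden=8, dropout_rate=0.2, seed=7)
        tcfg = TrainConfig(seed=7, max_epochs=250, early_stop_patience=40)
        _, acc = pretrain("ocp", cohort, mcfg, tcfg,
                          segment_len=24, pairs_per_subject=8)
        assert acc > 0.5
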