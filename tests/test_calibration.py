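"""Reliable-sample selection, clipping, calibration cycles, scheduling."""

import numpy as np
import pytest

from mvep_adapt.calibration import (STANDARD, TARGET, CalibrationConfig,
                                    TimedSample, TrainingSet,
                                    calibrate_cycle, clip_training_set,
                                    run_adaptive_from_averaged,
                                    run_adaptive_session, select_reliable)
from mvep_adapt.classifiers import predict_posterior
from mvep_adapt.csp import csp_features
from mvep_adapt.evaluate import decode_block
from mvep_adapt.preprocess import PreprocessConfig


def ts(label=TARGET, p_svm=None, p_fcm=None, t=0, feat=(0.0, 0.0)):
    return TimedSample(features=np.asarray(feat, dtype=float),
                       assigned_label=label, timestamp=t,
                       p_svm=p_svm, p_fcm=p_fcm)


class TestSelection:
    def test_fusion_requires_agreement_and_both_confidences(self):
        agree = np.array([1]), np.array([1])
        disagree = np.array([1]), np.array([0])
        sel = select_reliable([ts(p_svm=0.8, p_fcm=0.8)], 0.75, "fusion",
                              svm_labels=agree[0], fcm_labels=agree[1])
        assert len(sel) == 1
        # strict inequality on either probability fails the candidate
        sel = select_reliable([ts(p_svm=0.8, p_fcm=0.75)], 0.75, "fusion",
                              svm_labels=agree[0], fcm_labels=agree[1])
        assert sel == []
        sel = select_reliable([ts(p_svm=0.99, p_fcm=0.99)], 0.75, "fusion",
                              svm_labels=disagree[0], fcm_labels=disagree[1])
        assert sel == []

    def test_single_labeler_strategies_use_one_confidence(self):
        c = [ts(p_svm=0.9, p_fcm=0.5), ts(p_svm=0.5, p_fcm=0.9)]
        assert select_reliable(c, 0.75, "svm_only") == [c[0]]
        assert select_reliable(c, 0.75, "fcm_only") == [c[1]]

    def test_selection_monotone_in_delta_and_fusion_subset(self):
        rng = np.random.default_rng(0)
        cands = [ts(p_svm=rng.uniform(0.5, 1), p_fcm=rng.uniform(0.5, 1))
                 for _ in range(100)]
        sv = rng.integers(0, 2, 100)
        fc = np.where(rng.random(100) < 0.8, sv, 1 - sv)
        prev = None
        for delta in (0.6, 0.7, 0.8, 0.9):
            sel = {id(s) for s in select_reliable(cands, delta, "fusion",
                                                  svm_labels=sv, fcm_labels=fc)}
            if prev is not None:
                assert sel <= prev
            prev = sel
        fus = {id(s) for s in select_reliable(cands, 0.75, "fusion",
                                              svm_labels=sv, fcm_labels=fc)}
        svm = {id(s) for s in select_reliable(cands, 0.75, "svm_only")}
        fcm = {id(s) for s in select_reliable(cands, 0.75, "fcm_only")}
        assert fus <= svm and fus <= fcm

    def test_selection_preserves_order(self):
        c = [ts(p_svm=0.9, p_fcm=0.9, feat=(i, i)) for i in range(5)]
        sel = select_reliable(c, 0.6, "svm_only")
        assert [s.features[0] for s in sel] == [0, 1, 2, 3, 4]


class TestClip:
    def _filled(self, n, capacity, labels=None):
        t = TrainingSet(capacity=capacity)
        labels = labels or [TARGET if i % 2 else STANDARD for i in range(n)]
        t.samples = [ts(label=l, t=i + 1) for i, l in enumerate(labels)]
        return t

    def test_clip_removes_oldest_beyond_capacity(self):
        t = self._filled(260, 250)
        removed = clip_training_set(t)
        assert removed == 10 and len(t) == 250
        assert sorted(t.timestamps()) == list(range(1, 251))

    def test_below_capacity_unchanged(self):
        t = self._filled(100, 250)
        assert clip_training_set(t) == 0 and len(t) == 100

    def test_class_floor_keeps_newest_of_endangered_class(self):
        # newest 4 all standard; older targets exist; floor of 2 per class
        t = TrainingSet(capacity=4)
        t.samples = [ts(label=l, t=i + 1)
                     for i, l in enumerate([STANDARD] * 4 + [TARGET] * 4)]
        clip_training_set(t, min_per_class=2)
        assert len(t) == 4
        kept = sorted((s.timestamp, s.assigned_label) for s in t.samples)
        counts = {TARGET: 0, STANDARD: 0}
        for _, l in kept:
            counts[l] += 1
        assert counts == {TARGET: 2, STANDARD: 2}
        assert sorted(t.timestamps()) == [1, 2, 3, 4]

    def test_timestamps_always_a_permutation(self):
        rng = np.random.default_rng(1)
        t = self._filled(37, 20)
        clip_training_set(t)
        assert sorted(t.timestamps()) == list(range(1, len(t) + 1))

    def test_add_batch_ages_existing_and_stamps_newest_first(self):
        t = self._filled(3, 100)
        t.add_batch([ts(label=TARGET), ts(label=STANDARD)])
        # the last added sample carries timestamp 1
        assert t.samples[-1].timestamp == 1
        assert t.samples[-2].timestamp == 2
        assert min(s.timestamp for s in t.samples[:3]) == 3


class TestCycle:
    def _setup(self, small_subject):
        from mvep_adapt.calibration import _initial_models
        cfg = CalibrationConfig(seed=1)
        tset, csp_model, svm_model = _initial_models(
            small_subject["averaged_train"], cfg)
        segment = [s for b in range(4) for s in small_subject["averaged_test"][b]]
        return cfg, tset, csp_model, svm_model, segment

    def test_delta_one_is_a_no_op(self, small_subject):
        from dataclasses import replace
        cfg, tset, csp_model, svm_model, segment = self._setup(small_subject)
        cfg = replace(cfg, delta=1.0)
        size = len(tset)
        probe = np.random.default_rng(0).normal(2.0, 1.0, size=(20, 2))
        before = svm_model.posterior(probe)
        tset2, csp2, svm2, audit = calibrate_cycle(tset, csp_model, svm_model,
                                                   segment, cfg)
        assert audit["n_selected"] == 0
        assert len(tset2) == size
        assert np.array_equal(svm2.posterior(probe), before)

    def test_additions_match_brute_force_recount(self, small_subject):
        """The audit's A/B counts equal an independent recount of the
        fusion rule applied to the labelers' raw outputs."""
        from mvep_adapt.classifiers import (compute_class_centers, fcm_label,
                                            fit_fcm, match_clusters)
        cfg, tset, csp_model, svm_model, segment = self._setup(small_subject)
        # recount BEFORE the cycle mutates the training set
        feats = np.vstack([csp_features(csp_model, s) for s in segment])
        svm_labels, p_svm = predict_posterior(svm_model, feats)
        centers = compute_class_centers(tset.features, tset.labels,
                                        positive_label=TARGET)
        fcm = fit_fcm(feats, m=cfg.fcm_m, init_centers=centers,
                      tol=cfg.fcm_tol, max_iter=cfg.fcm_max_iter)
        mapping = match_clusters(fcm, centers, labels=(TARGET, STANDARD))
        fcm_labels, p_fcm = fcm_label(fcm, mapping)
        truth = np.array([int(s.is_target) for s in segment])
        picked = [(int(ls), int(t)) for ls, lf, ps, pf, t in
                  zip(svm_labels, fcm_labels, p_svm, p_fcm, truth)
                  if ls == lf and ps > cfg.delta and pf > cfg.delta]
        expected_b = len(picked)
        expected_a = sum(1 for lab, t in picked if lab == t)

        _, _, _, audit = calibrate_cycle(tset, csp_model, svm_model, segment,
                                         cfg)
        assert audit["n_candidates"] == len(segment)
        assert audit["n_selected"] == expected_b
        assert audit["n_correct"] == expected_a

    def test_audit_conservation_and_capacity(self, small_subject):
        from dataclasses import replace
        cfg, tset, csp_model, svm_model, segment = self._setup(small_subject)
        cfg = replace(cfg, capacity=26, delta=0.6)
        tset.capacity = 26
        clip_training_set(tset)
        size_before = len(tset)
        tset2, _, _, audit = calibrate_cycle(tset, csp_model, svm_model,
                                             segment, cfg)
        assert len(tset2) <= 26
        assert (audit["n_selected"] - audit["n_removed"]
                == audit["size_after"] - audit["size_before"])
        assert sorted(tset2.timestamps()) == list(range(1, len(tset2) + 1))


class TestNoiseFreeCycle:
    def test_separable_segment_harvest_is_perfectly_labeled(self):
        """On noise-free separable features every fusion addition carries
        the correct label (audit ratio C = 1)."""
        rng = np.random.default_rng(5)
        n = 40
        Xt = rng.normal([3.0, 0.0], 0.1, size=(n, 2))
        Xs = rng.normal([0.0, 3.0], 0.1, size=(n, 2))
        from mvep_adapt.classifiers import train_svm
        svm = train_svm(np.vstack([Xt, Xs]),
                        np.array([TARGET] * n + [STANDARD] * n), seed=0)
        tset = TrainingSet(capacity=250)
        tset.add_batch([ts(label=TARGET, feat=f) for f in Xt]
                       + [ts(label=STANDARD, feat=f) for f in Xs])

        class IdentityCSP:
            filters = np.eye(2)

        from mvep_adapt.preprocess import AveragedSample
        seg = []
        truth = []
        for i in range(24):
            is_tgt = i % 6 == 0
            f = rng.normal([3.0, 0.0] if is_tgt else [0.0, 3.0], 0.1)
            seg.append((f, int(is_tgt)))
            truth.append(int(is_tgt))

        candidates = [TimedSample(features=np.asarray(f), assigned_label=-1,
                                  timestamp=0, true_label=t)
                      for (f, _), t in zip(seg, truth)]
        feats = np.vstack([c.features for c in candidates])
        labels, p_svm = predict_posterior(svm, feats)
        from mvep_adapt.classifiers import (compute_class_centers, fcm_label,
                                            fit_fcm, match_clusters)
        centers = compute_class_centers(tset.features, tset.labels,
                                        positive_label=TARGET)
        fcm = fit_fcm(feats, init_centers=centers)
        mapping = match_clusters(fcm, centers, labels=(TARGET, STANDARD))
        fcm_labels, p_fcm = fcm_label(fcm, mapping)
        for c, ls, ps, pf in zip(candidates, labels, p_svm, p_fcm):
            c.assigned_label = int(ls)
            c.p_svm, c.p_fcm = float(ps), float(pf)
        sel = select_reliable(candidates, 0.75, "fusion",
                              svm_labels=labels, fcm_labels=fcm_labels)
        agreeing_confident = [
            c for c, ls, lf in zip(candidates, labels, fcm_labels)
            if ls == lf and c.p_svm > 0.75 and c.p_fcm > 0.75]
        assert len(sel) == len(agreeing_confident) > 0
        assert all(s.assigned_label == s.true_label for s in sel)


class TestScheduling:
    def test_strategy_none_matches_traditional_pipeline(self, small_subject):
        from mvep_adapt.calibration import _initial_models
        cfg = CalibrationConfig(strategy="none", seed=2)
        res = run_adaptive_from_averaged(small_subject["averaged_train"],
                                         small_subject["averaged_test"],
                                         small_subject["targets"], cfg)
        # traditional pipeline: fixed models decode every block
        tset, csp_model, svm_model = _initial_models(
            small_subject["averaged_train"], cfg)
        fixed = [decode_block(svm_model, csp_model, blk).predicted_button
                 for blk in small_subject["averaged_test"]]
        assert res.predicted_buttons == fixed
        assert res.audit_trail == []

    def test_interval_spanning_whole_test_equals_none(self, small_subject):
        from dataclasses import replace
        base = CalibrationConfig(strategy="fusion", seed=2)
        cfg = replace(base, interval_blocks=len(small_subject["averaged_test"]))
        adaptive = run_adaptive_from_averaged(small_subject["averaged_train"],
                                              small_subject["averaged_test"],
                                              small_subject["targets"], cfg)
        none_cfg = replace(base, strategy="none")
        fixed = run_adaptive_from_averaged(small_subject["averaged_train"],
                                           small_subject["averaged_test"],
                                           small_subject["targets"], none_cfg)
        assert adaptive.predicted_buttons == fixed.predicted_buttons

    def test_end_to_end_session_runner(self, small_subject):
        res = run_adaptive_session(small_subject["train"],
                                   small_subject["test"],
                                   CalibrationConfig(seed=3),
                                   PreprocessConfig())
        assert len(res.predicted_buttons) == 12
        assert len(res.audit_trail) == 2  # segments of 4, last not calibrated
        for rec in res.audit_trail:
            assert rec["n_candidates"] == 24

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CalibrationConfig(delta=1.5)
        with pytest.raises(ValueError):
            CalibrationConfig(interval_blocks=0)
        with pytest.raises(ValueError):
            CalibrationConfig(strategy="bogus")
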