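"""Synthetic cohort generator: determinism, geometric invariants,
composition presets, reader-call simulation calibration."""

import numpy as np
import pytest
from scipy import stats

import cadekit as ck
from cadekit.metrics import grade_to_binary


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        spec = ck.CohortSpec(
            groups=(("G1", "benign", 3), ("G5", "Sig", 3)), image_size=(48, 48), seed=5
        )
        a, b = ck.generate_cohort(spec), ck.generate_cohort(spec)
        for rec_a, rec_b in zip(a.records, b.records):
            np.testing.assert_array_equal(rec_a.tissue_mask.values, rec_b.tissue_mask.values)
        for sid in a.maps:
            np.testing.assert_array_equal(a.maps[sid].values, b.maps[sid].values)
            assert a.detections[sid].boxes == b.detections[sid].boxes

    def test_different_seed_differs(self):
        g = lambda seed: ck.generate_cohort(
            ck.CohortSpec(groups=(("G1", "benign", 2),), image_size=(48, 48), seed=seed)
        )
        assert not np.array_equal(g(1).maps["s0000"].values, g(2).maps["s0000"].values)


class TestGeometricInvariants:
    def test_probabilities_lesions_and_fractions(self, small_cohort):
        lo, hi = small_cohort.spec.lesion_area_fraction_range
        for rec in small_cohort.records:
            pmap = small_cohort.maps[rec.sample_id]
            assert pmap.values.min() >= 0.0 and pmap.values.max() <= 1.0
            if rec.gt_mask is not None:
                # lesions never leave the tissue
                assert not (rec.gt_mask.values & ~rec.tissue_mask.values).any()
                frac = rec.gt_mask.count() / rec.tissue_mask.count()
                assert lo <= frac <= hi

    def test_detectability_split_matches_generator_record_exactly(self, small_cohort):
        truth = small_cohort.truth.set_index("sample_id")
        n_overlooked = 0
        for rec in small_cohort.records:
            if grade_to_binary(rec.grade) != "malignant":
                continue
            label = ck.detectability(rec)
            recorded = truth.loc[rec.sample_id, "lesion_area_fraction"]
            assert label.malignant_area_fraction == recorded
            assert (label.category == "likely_overlooked") == (recorded < 0.30)
            n_overlooked += label.category == "likely_overlooked"
        n_malignant = int((truth["label"] == "malignant").sum())
        # the two categories partition the malignant set
        assert n_overlooked + sum(
            ck.detectability(r).category == "easily_detectable"
            for r in small_cohort.records
            if grade_to_binary(r.grade) == "malignant"
        ) == n_malignant

    def test_sig_samples_receive_high_scoring_detections(self, small_cohort):
        truth = small_cohort.truth
        sig = truth[truth.subtype == "Sig"]
        assert (sig["det_score"] > 0.8).mean() > 0.5
        benign = truth[truth.label == "benign"]
        assert (benign["det_score"] <= 0.8).all()


class TestPresets:
    def test_roc_cohort_composition(self):
        spec = ck.get_preset("roc_cohort")
        g5 = {st: n for g, st, n in spec.groups if g == "G5"}
        assert g5 == {
            "Tub_well": 40, "Tub_mod": 85, "Pap": 17, "Por_solid": 13,
            "Por_nonsolid": 124, "Sig": 15, "Muc": 3, "MALT": 9,
        }
        assert sum(g5.values()) == 306
        assert spec.n_benign == 211 and spec.n_malignant == 324

    def test_eval_and_reader_cohorts(self):
        ev = ck.get_preset("eval_cohort")
        assert ev.n_total == 190
        assert sum(n for g, _, n in ev.groups if g == "G5") == 98
        rd = ck.get_preset("reader_cohort")
        assert rd.n_total == 199
        assert rd.n_benign == 99 and rd.n_malignant == 100

    def test_training_cohort_totals(self):
        tr = ck.get_preset("training_cohort")
        assert tr.n_benign == 1105 and tr.n_malignant == 820
        assert tr.n_total == 1925

    def test_subtype_counts_sum_to_malignant_total(self):
        for name in ("roc_cohort", "eval_cohort", "reader_cohort", "training_cohort"):
            spec = ck.get_preset(name)
            assert sum(spec.subtype_counts.values()) == spec.n_malignant

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="preset"):
            ck.get_preset("mystery_cohort")


class TestScoreSeparation:
    def test_zero_signal_null_is_indistinguishable(self):
        spec = ck.CohortSpec(
            groups=(("G1", "benign", 40), ("G5", "Tub_mod", 40)),
            image_size=(48, 48), seed=21, signal=0.0,
        )
        cohort = ck.generate_cohort(spec)
        t = cohort.truth
        ben = t[t.label == "benign"]["seg_score"]
        mal = t[t.label == "malignant"]["seg_score"]
        p = stats.mannwhitneyu(ben, mal, alternative="two-sided").pvalue
        assert p > 0.01  # null construction: no detectable separation

    def test_end_to_end_threshold_recovery(self):
        """With strong signal, the Youden cut-off learned on one cohort
        gives >= 95% sensitivity and specificity on a fresh cohort."""
        kwargs = dict(
            groups=(("G1", "benign", 50), ("G5", "Tub_mod", 50)),
            image_size=(64, 64), signal=0.45, noise_sd=0.05,
        )
        train = ck.generate_cohort(ck.CohortSpec(seed=31, **kwargs))
        r = ck.roc_curve(train.sample_scores(), which="seg")
        test = ck.generate_cohort(ck.CohortSpec(seed=32, **kwargs))
        calls, labels = {}, {}
        for rec in test.records:
            roi = ck.binarize(test.maps[rec.sample_id], r.cutoff)
            calls[rec.sample_id] = ck.ovl_sample_call(roi)
            labels[rec.sample_id] = grade_to_binary(rec.grade)
        m = ck.evaluate(calls, labels)
        assert m.sensitivity >= 0.95
        assert m.specificity >= 0.95


class TestReaderSimulation:
    @staticmethod
    def _records(n, grade="G5", subtype="Tub_mod"):
        spec = ck.CohortSpec(groups=((grade, subtype, n),), image_size=(32, 32), seed=1)
        return ck.generate_cohort(spec).records

    def test_perfect_sensitivity_gives_malignant_grades(self):
        recs = self._records(10)
        rs = ck.ReaderSpec(sens_without=1.0, sens_with=1.0)
        calls = ck.simulate_reader_calls(recs, rs, n_readers=3, seed=4)
        assert all(c.grade in ("G4", "G5") for c in calls)

    def test_phase_difference_matches_binomial_expectation(self):
        recs = self._records(100)
        rs = ck.ReaderSpec(sens_without=0.92, sens_with=0.93)
        diffs = []
        for rep in range(150):
            calls = ck.simulate_reader_calls(recs, rs, n_readers=5, seed=3000 + rep)
            correct = {"first": 0, "second": 0}
            for c in calls:
                correct[c.phase] += c.grade in ("G4", "G5")
            diffs.append((correct["second"] - correct["first"]) / 500 * 100)
        # 150 replicates of 500 paired calls: MC error ~ 0.15 pp
        assert np.mean(diffs) == pytest.approx(1.0, abs=0.45)

    def test_zero_rho_gives_uncorrelated_readers(self):
        recs = self._records(150)
        rs = ck.ReaderSpec(sens_without=0.7, sens_with=0.7, cluster_rho=0.0)
        cors = []
        for rep in range(20):
            calls = ck.simulate_reader_calls(recs, rs, n_readers=2, seed=500 + rep)
            y = {}
            for c in calls:
                if c.phase == "first":
                    y.setdefault(c.reader_id, {})[c.sample_id] = c.grade in ("G4", "G5")
            sids = sorted(y["r1"])
            a = np.array([y["r1"][s] for s in sids], float)
            b = np.array([y["r2"][s] for s in sids], float)
            cors.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(cors)) < 0.05

    def test_positive_rho_induces_cluster_correlation(self):
        recs = self._records(150)
        rs = ck.ReaderSpec(sens_without=0.7, sens_with=0.7, cluster_rho=0.4)
        cors = []
        for rep in range(20):
            calls = ck.simulate_reader_calls(recs, rs, n_readers=2, seed=900 + rep)
            y = {}
            for c in calls:
                if c.phase == "first":
                    y.setdefault(c.reader_id, {})[c.sample_id] = c.grade in ("G4", "G5")
            sids = sorted(y["r1"])
            a = np.array([y["r1"][s] for s in sids], float)
            b = np.array([y["r2"][s] for s in sids], float)
            cors.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(cors) == pytest.approx(0.4, abs=0.1)
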