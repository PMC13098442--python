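"""Second-reader workflow: per-reader/pooled metrics, GEE phase comparison."""

import numpy as np
import pytest

import cadekit as ck
from cadekit.gee import fit_gee, wald_test


def build_calls(per_reader_correct, truth, phase_flip=None):
    """Construct a complete two-phase design from correctness tables.

    per_reader_correct: {reader: {sample: bool}} applied to both phases;
    phase_flip: {(reader, sample): phase} entries whose correctness flips
    in the named phase.
    """
    calls = []
    for r, table in per_reader_correct.items():
        for s, correct in table.items():
            for phase in ("first", "second"):
                c = correct
                if phase_flip and phase_flip.get((r, s)) == phase:
                    c = not c
                malignant = truth[s] == "malignant"
                if malignant:
                    grade = "G5" if c else "G1"
                else:
                    grade = "G1" if c else "G5"
                calls.append(ck.ReaderCall(r, s, phase, grade))
    return calls


def two_phase_counts(n_samples, correct_first, correct_second, reader, label, prefix):
    """Calls for one reader over n samples with exact per-phase correct counts."""
    calls = []
    for i in range(n_samples):
        sid = f"{prefix}{i}"
        for phase, n_correct in (("first", correct_first), ("second", correct_second)):
            c = i < n_correct
            if label == "malignant":
                grade = "G5" if c else "G1"
            else:
                grade = "G1" if c else "G5"
            calls.append(ck.ReaderCall(reader, sid, phase, grade))
    return calls


class TestReaderCallValidation:
    def test_bad_phase_and_grade(self):
        with pytest.raises(ValueError):
            ck.ReaderCall("r1", "s1", "third", "G1")
        with pytest.raises(ValueError):
            ck.ReaderCall("r1", "s1", "first", "G6")

    def test_duplicate_call_rejected(self):
        calls = [ck.ReaderCall("r1", "s1", "first", "G1")] * 2
        with pytest.raises(ValueError, match="duplicate"):
            ck.reader_metrics(calls, {"s1": "benign"})

    def test_incomplete_design_reported_per_reader(self):
        calls = [
            ck.ReaderCall("r1", "s1", "first", "G1"),
            ck.ReaderCall("r1", "s1", "second", "G1"),
            ck.ReaderCall("r2", "s1", "first", "G1"),
        ]
        with pytest.raises(ValueError, match="reader r2"):
            ck.reader_metrics(calls, {"s1": "benign"})


class TestReaderMetrics:
    def test_single_reader_all_correct_flagged_degenerate(self):
        truth = {"s0": "malignant", "s1": "benign"}
        calls = build_calls({"r1": {"s0": True, "s1": True}}, truth)
        m = ck.reader_metrics(calls, truth)
        assert m.pooled["first"].sensitivity == 1.0
        assert m.pooled["second"].specificity == 1.0
        assert any("single reader" in f for f in m.flags)
        assert m.across_readers["ci_low"].isna().all()

    def test_pooled_sensitivity_is_decision_weighted(self):
        # 5 readers, each 92 of 100 malignant correct in both phases
        truth = {f"s{i}": "malignant" for i in range(100)}
        calls = []
        for r in range(5):
            calls += two_phase_counts(100, 92, 92, f"r{r}", "malignant", "s")
        m = ck.reader_metrics(calls, truth)
        assert m.pooled["first"].tp == 460
        assert m.pooled["first"].sensitivity == pytest.approx(0.92)

    def test_across_reader_t_interval(self):
        truth = {f"s{i}": "malignant" for i in range(10)}
        calls = []
        sens = [10, 9, 8, 9, 10]
        for r, k in enumerate(sens):
            calls += two_phase_counts(10, k, k, f"r{r}", "malignant", "s")
        m = ck.reader_metrics(calls, truth)
        row = m.across_readers.query("phase == 'first' and metric == 'sensitivity'").iloc[0]
        vals = np.array(sens) / 10
        from scipy import stats

        half = stats.t.ppf(0.975, 4) * vals.std(ddof=1) / np.sqrt(5)
        assert row["mean"] == pytest.approx(vals.mean())
        assert row["ci_low"] == pytest.approx(vals.mean() - half)


class TestGEEEngine:
    def test_single_obs_clusters_reproduce_two_proportion_closed_form(self, rng):
        n = 150
        y1 = (rng.random(n) < 0.8).astype(float)
        y2 = (rng.random(n) < 0.9).astype(float)
        y = np.concatenate([y1, y2])
        X = np.column_stack([np.ones(2 * n), np.r_[np.zeros(n), np.ones(n)]])
        fit = fit_gee(y, X, np.arange(2 * n), rho=0.0)
        p1, p2 = y1.mean(), y2.mean()
        assert fit.beta[1] == pytest.approx(p2 - p1, abs=1e-10)
        se = np.sqrt(p1 * (1 - p1) / n + p2 * (1 - p2) / n)
        assert np.sqrt(fit.robust_cov[1, 1]) == pytest.approx(se, abs=1e-10)

    def test_agrees_with_statsmodels_exchangeable_gee(self, rng):
        import warnings

        import statsmodels.api as sm

        n_cl, n_per = 120, 6
        gamma = np.sqrt(0.3)
        y = np.empty((n_cl, n_per))
        z1 = rng.random(n_cl) < 0.75
        z2 = rng.random(n_cl) < 0.85
        for j in range(n_per):
            second = j >= n_per // 2
            z, p = (z2, 0.85) if second else (z1, 0.75)
            copy = rng.random(n_cl) < gamma
            y[:, j] = np.where(copy, z, rng.random(n_cl) < p)
        yf = y.ravel()
        phase = np.tile(np.r_[np.zeros(n_per // 2), np.ones(n_per // 2)], n_cl)
        X = np.column_stack([np.ones(n_cl * n_per), phase])
        clusters = np.repeat(np.arange(n_cl), n_per)

        mine = fit_gee(yf, X, clusters)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # identity link outside Binomial domain
            ref = sm.GEE(
                yf, X, groups=clusters,
                family=sm.families.Binomial(link=sm.families.links.Identity()),
                cov_struct=sm.cov_struct.Exchangeable(),
            ).fit()
        assert mine.beta[1] == pytest.approx(ref.params[1], abs=1e-8)
        assert np.sqrt(mine.robust_cov[1, 1]) == pytest.approx(ref.bse[1], abs=1e-8)
        assert mine.rho == pytest.approx(float(ref.cov_struct.dep_params), abs=1e-6)

    def test_wald_degenerate_conventions(self):
        assert wald_test(0.0, 0.0) == 1.0
        assert wald_test(1.0, 0.0) == 0.0
        assert wald_test(0.0, 1.0) == 1.0


class TestGEEDifference:
    def test_identical_phases_degenerate(self):
        truth = {f"s{i}": "malignant" for i in range(20)}
        table = {f"r{r}": {s: (i % 4 != 0) for i, s in enumerate(truth)} for r in range(3)}
        calls = build_calls(table, truth)
        res = ck.gee_difference(calls, truth, "malignant")
        assert res.estimate == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_separation_flagged(self):
        truth = {f"s{i}": "malignant" for i in range(10)}
        calls = build_calls({"r1": {s: True for s in truth}}, truth)
        res = ck.gee_difference(calls, truth, "malignant")
        assert res.robust_se == 0.0
        assert any("degenerate" in f or "separation" in f for f in res.flags)

    def test_invariant_to_cluster_order_and_reader_labels(self, rng):
        truth = {f"s{i}": "malignant" for i in range(40)}
        table = {
            f"r{r}": {s: bool(rng.random() < 0.8) for s in truth} for r in range(4)
        }
        flips = {
            (f"r{r}", s): "second" for r in range(4) for s in truth if rng.random() < 0.15
        }
        calls = build_calls(table, truth, phase_flip=flips)
        res1 = ck.gee_difference(calls, truth, "malignant")
        shuffled = list(calls)
        rng.shuffle(shuffled)
        relabeled = [
            ck.ReaderCall("reader_" + c.reader_id[::-1], c.sample_id, c.phase, c.grade)
            for c in shuffled
        ]
        res2 = ck.gee_difference(relabeled, truth, "malignant")
        assert res2.estimate == pytest.approx(res1.estimate, abs=1e-9)
        assert res2.robust_se == pytest.approx(res1.robust_se, abs=1e-9)

    def test_benign_stratum_scores_correct_exclusion(self):
        truth = {"s0": "benign", "s1": "benign"}
        calls = build_calls(
            {"r1": {"s0": True, "s1": False}}, truth, phase_flip={("r1", "s1"): "second"}
        )
        res = ck.gee_difference(calls, truth, "benign")
        # specificity goes 1/2 -> 2/2: +50 percentage points
        assert res.estimate == pytest.approx(50.0, abs=1e-6)
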