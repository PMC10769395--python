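import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from regulon_forge.cohort import (
    QpcrMeasurement,
    bh_fdr,
    correlation_screen,
    ddct_fold_change,
    km_logrank,
    quartile_concordance,
    range_screen,
    welch_t,
)
from regulon_forge.genomic_io import ExpressionMatrix, SurvivalRecord
from regulon_forge.simulate import SimulationConfig, simulate_cohort, simulate_survival


def matrix_from(rows: dict, prefix: str = "s") -> ExpressionMatrix:
    frame = pd.DataFrame(rows).T
    frame.columns = [f"{prefix}{i}" for i in range(frame.shape[1])]
    return ExpressionMatrix(frame)


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_swap_negates_statistic(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 9.0]
        fwd, rev = welch_t(a, b), welch_t(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p == pytest.approx(rev.p)
        assert fwd.direction == -rev.direction

    def test_constant_groups_equal_means(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (res.statistic, res.p) == (0.0, 1.0)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 20)
        res = welch_t(a, b)
        va, vb = a.var(ddof=1) / 30, b.var(ddof=1) / 20
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 29 + vb**2 / 19)
        assert res.statistic == pytest.approx(t)
        assert res.df == pytest.approx(df)

    def test_power_at_unit_effect(self):
        # N(0,1) n=42 vs N(1,1) n=79 is detected at p<0.01 essentially always
        rng = np.random.default_rng(77)
        hits = sum(
            welch_t(rng.normal(1, 1, 79), rng.normal(0, 1, 42)).p < 0.01
            for _ in range(100)
        )
        assert hits >= 99


class TestRangeScreen:
    def test_identical_matrices_pass_nothing(self):
        rng = np.random.default_rng(1)
        rows = {f"g{i}": rng.uniform(1, 10, 12) for i in range(20)}
        tumors = matrix_from(rows, "t")
        cells = matrix_from(rows, "c")
        passed, skipped = range_screen(tumors, cells, rows.keys())
        assert passed == set() and skipped == []

    def test_missing_genes_skipped_and_reported(self):
        rng = np.random.default_rng(2)
        tumors = matrix_from({"a": rng.uniform(0, 1, 6)})
        cells = matrix_from({"b": rng.uniform(0, 1, 6)})
        passed, skipped = range_screen(tumors, cells, ["a", "b"])
        assert skipped == ["a", "b"]

    def test_planted_shift_recovered(self):
        cfg = SimulationConfig(seed=3, n_null_genes=50, n_shifted_genes=8,
                               shift_delta=3.0)
        cohort = simulate_cohort(cfg)
        shifted = set(cohort.truth.loc[cohort.truth.role == "shifted", "gene_id"])
        passed, _ = range_screen(cohort.tumors, cohort.celllines,
                                 cohort.tumors.gene_ids, p_cut=0.01)
        assert shifted <= passed
        nulls = set(cohort.truth.loc[cohort.truth.role == "null", "gene_id"])
        assert len(passed & nulls) <= 3  # ~0.5% expected false positives


class TestBhFdr:
    def test_hand_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37]) == [0.37]

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 200))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_fdr(p), expected)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        q = np.asarray(bh_fdr(p))
        q_perm = np.asarray(bh_fdr(p[perm]))
        assert np.allclose(q[perm], q_perm)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        q = np.asarray(bh_fdr(p))
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCorrelationScreen:
    def _matrix(self, n=30, seed=5):
        rng = np.random.default_rng(seed)
        reg = rng.uniform(1, 100, n)
        rows = {
            "REG": reg,
            "SAME": reg.copy(),
            "NOISE": rng.uniform(1, 100, n),
            "CONST": np.full(n, 7.0),
        }
        return matrix_from(rows)

    def test_self_correlation_is_one(self):
        results = {r.gene_id: r for r in correlation_screen(
            self._matrix(), "REG", ["SAME", "NOISE", "CONST"], q_cut=0.05)}
        assert results["SAME"].r == pytest.approx(1.0)
        assert results["SAME"].passed

    def test_constant_candidate_flagged(self):
        results = {r.gene_id: r for r in correlation_screen(
            self._matrix(), "REG", ["CONST"], q_cut=0.05)}
        assert not results["CONST"].defined
        assert not results["CONST"].passed

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(11)
        reg = rng.uniform(1, 50, 40)
        cand = reg + rng.normal(0, 5, 40)
        cand = cand - cand.min() + 0.1
        m1 = matrix_from({"R": reg, "C": cand})
        m2 = matrix_from({"R": reg, "C": np.expm1(cand / 10)})  # monotone
        r1 = correlation_screen(m1, "R", ["C"], method="spearman", q_cut=0.05)[0]
        r2 = correlation_screen(m2, "R", ["C"], method="spearman", q_cut=0.05)[0]
        assert r1.r == pytest.approx(r2.r)
        assert r1.p == pytest.approx(r2.p)

    def test_planted_pair_detected(self):
        cfg = SimulationConfig(seed=13, n_null_genes=40, planted_rho=0.9)
        cohort = simulate_cohort(cfg)
        results = {r.gene_id: r for r in correlation_screen(
            cohort.tumors, "reg_0000",
            [g for g in cohort.tumors.gene_ids if g != "reg_0000"], q_cut=0.01)}
        assert results["tgt_0000"].passed
        assert results["tgt_0000"].r > 0.7

    def test_missing_regulator_errors(self):
        with pytest.raises(KeyError):
            correlation_screen(self._matrix(), "NOPE", ["SAME"], q_cut=0.05)


class TestQuartileConcordance:
    def test_n_is_20_of_79(self):
        rng = np.random.default_rng(4)
        m = matrix_from({"R": rng.uniform(0, 9, 79), "T": rng.uniform(0, 9, 79)})
        _, n = quartile_concordance(m, "R", "T")
        assert n == 20

    def test_perfect_rank_correlation(self):
        vals = np.arange(1.0, 41.0)
        m = matrix_from({"R": vals, "T": vals * 2})
        k, n = quartile_concordance(m, "R", "T")
        assert k == n == 10

    def test_invariant_to_increasing_transform_of_target(self):
        rng = np.random.default_rng(14)
        reg = rng.uniform(0, 10, 79)
        tgt = rng.uniform(0, 10, 79)
        m1 = matrix_from({"R": reg, "T": tgt})
        m2 = matrix_from({"R": reg, "T": np.exp(tgt / 3)})
        assert quartile_concordance(m1, "R", "T") == quartile_concordance(m2, "R", "T")

    def test_null_concordance_near_half(self):
        rng = np.random.default_rng(15)
        ks = []
        for _ in range(400):
            m = matrix_from({"R": rng.uniform(0, 9, 79), "T": rng.uniform(0, 9, 79)})
            k, n = quartile_concordance(m, "R", "T")
            ks.append(k / n)
        # null mean slightly above 0.5: ">= median" is inclusive and the
        # median of 79 values is itself a sample value
        assert abs(np.mean(ks) - 0.5) < 0.05


class TestKmLogrank:
    def _records(self, times, events, exprs):
        return [
            SurvivalRecord(f"s{i}", float(t), int(e), float(x))
            for i, (t, e, x) in enumerate(zip(times, events, exprs))
        ]

    def test_no_events_flat_curves(self):
        recs = self._records([1, 2, 3, 4], [0, 0, 0, 0], [1, 2, 8, 9])
        high, low, chi2, p = km_logrank(recs)
        assert set(high.survival) == {1.0} and set(low.survival) == {1.0}
        assert (chi2, p) == (0.0, 1.0)

    def test_identical_groups_chi2_zero(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        exprs = [10, 10, 10, 1, 1, 1]
        _, _, chi2, _ = km_logrank(self._records(times, events, exprs), split=5)
        assert chi2 == 0.0

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(17)
        times = rng.exponential(10, 40)
        exprs = np.r_[np.ones(20) * 9, np.ones(20)]
        recs = self._records(times, np.ones(40), exprs)
        high, low, _, _ = km_logrank(recs, split=5)
        group_times = np.sort(times[:20])
        for t, s in zip(high.times, high.survival):
            assert s == pytest.approx(np.mean(group_times > t))

    def test_empty_group_errors(self):
        recs = self._records([1, 2, 3, 4], [1, 1, 1, 1], [5, 5, 5, 5])
        with pytest.raises(ValueError):
            km_logrank(recs, split="median")  # all expressions tie -> empty high

    def test_planted_hazard_detected(self):
        cfg = SimulationConfig(seed=19, surv_n=85, surv_hazard_ratio=3.0)
        sim = simulate_survival(cfg)
        _, _, chi2, p = km_logrank(sim.records, split="median")
        assert p < 0.05


class TestDdct:
    def test_worked_example(self):
        treated = QpcrMeasurement(25.0, 20.0, "treated")
        control = QpcrMeasurement(27.0, 20.0, "control")
        assert ddct_fold_change(treated, control) == pytest.approx(4.0)

    def test_identity(self):
        m = QpcrMeasurement(24.0, 18.0)
        assert ddct_fold_change(m, m) == 1.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            ct = rng.uniform(10, 35, 4)
            treated = QpcrMeasurement(ct[0], ct[1])
            control = QpcrMeasurement(ct[2], ct[3])
            expected = 2.0 ** -((ct[0] - ct[1]) - (ct[2] - ct[3]))
            assert ddct_fold_change(treated, control) == pytest.approx(expected)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            QpcrMeasurement(0.0, 20.0)
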