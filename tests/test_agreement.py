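"""Bland–Altman, ICC(A,1), Pearson, pairing and table assembly.

The ICC implementation is checked against both a from-scratch two-way
ANOVA oracle and pingouin's independent implementation; the RPC/CV
identity is checked on the published stride-length summary values.
"""

import numpy as np
import pandas as pd
import pytest

from gaitrig import (PairedMeasurements, agreement_stats, agreement_table,
                     bland_altman, classify_icc, icc_a1, pair_steps, pearson)
from gaitrig.agreement import bland_altman_plot_data, render_table


def pairs_of(a, b, parameter="step_length", level="single"):
    return PairedMeasurements(parameter, "cm", level, np.asarray(a, float),
                              np.asarray(b, float))


def icc_a1_anova_oracle(a, b):
    """Independent mean-squares computation straight from the ANOVA sums."""
    y = np.column_stack([a, b]).astype(float)
    n, k = y.shape
    grand = y.mean()
    ms_rows = k * np.sum((y.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((y.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum((y - y.mean(axis=1, keepdims=True)
                  - y.mean(axis=0, keepdims=True) + grand) ** 2)
    ms_err = sse / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err))


class TestBlandAltman:
    def test_identical_pairs(self):
        p = pairs_of([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        ba = bland_altman(p)
        assert ba["bias"] == 0.0 and ba["rpc"] == 0.0
        assert ba["cv_percent"] == 0.0

    def test_constant_offset(self):
        b = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(pairs_of(b + 0.5, b))
        assert ba["bias"] == pytest.approx(0.5)
        assert ba["rpc"] == pytest.approx(0.0, abs=1e-12)

    def test_bias_equals_difference_of_means(self, rng):
        a, b = rng.normal(120, 10, 50), rng.normal(118, 9, 50)
        ba = bland_altman(pairs_of(a, b))
        assert ba["bias"] == pytest.approx(a.mean() - b.mean(), abs=1e-12)

    def test_published_stride_length_row_internal_consistency(self):
        """The published one-sided left-stride summary (means 145.95 and
        145.36 cm, RPC 13.43, CV 4.71 %) satisfies CV = (RPC/1.96)/grand
        mean — and our implementation reproduces that identity on data
        constructed with exactly those moments."""
        rng = np.random.default_rng(42)
        n = 267
        mean_a, mean_b, rpc_pub, cv_pub = 145.95, 145.36, 13.43, 4.71
        sd_d = rpc_pub / 1.96
        d = rng.normal(0, 1, n)
        d = (d - d.mean()) / d.std(ddof=1) * sd_d + (mean_a - mean_b)
        base = rng.normal(0, 8.0, n)
        b = base - base.mean() + mean_b
        a = b + d
        a = a - a.mean() + mean_a        # pin both means exactly
        d = a - b
        assert np.std(d, ddof=1) == pytest.approx(sd_d, rel=1e-6)
        ba = bland_altman(pairs_of(a, b, "stride_length"))
        assert ba["rpc"] == pytest.approx(rpc_pub, abs=0.01)
        # the CV our formula produces matches the published cell to its
        # printed precision
        grand = np.mean((a + b) / 2)
        assert ba["cv_percent"] == pytest.approx(ba["sd_diff"] / grand * 100,
                                                 abs=1e-12)
        assert ba["cv_percent"] == pytest.approx(cv_pub, abs=0.02)

    def test_zero_grand_mean_flagged(self):
        p = pairs_of([1.0, -1.0], [-1.0, 1.0])
        assert np.isnan(bland_altman(p)["cv_percent"])

    def test_plot_data_limits(self, rng):
        a, b = rng.normal(100, 5, 30), rng.normal(100, 5, 30)
        df = bland_altman_plot_data(pairs_of(a, b))
        ba = bland_altman(pairs_of(a, b))
        assert np.allclose(df["difference"], a - b)
        assert np.allclose(df["upper_limit"], ba["bias"] + ba["rpc"])


class TestIcc:
    def test_identical_pairs_give_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert icc_a1(pairs_of(a, a)) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000)
        assert abs(icc_a1(pairs_of(a, b))) < 0.05

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        subj = rng.normal(0, rng.uniform(0.5, 3.0), n)
        a = subj + rng.normal(0, 1, n)
        b = subj + rng.normal(rng.uniform(-1, 1), 1, n)
        ours = icc_a1(pairs_of(a, b))
        assert ours == pytest.approx(icc_a1_anova_oracle(a, b), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin(self, seed):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(100 + seed)
        n = 25
        subj = rng.normal(0, 2, n)
        a = subj + rng.normal(0, 1, n)
        b = subj + rng.normal(0.5, 1, n)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(n), 2),
            "raters": ["A", "B"] * n,
            "ratings": np.column_stack([a, b]).ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="ratings")
        ref_val = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]),
                          "ICC"].iloc[0]
        assert icc_a1(pairs_of(a, b)) == pytest.approx(float(ref_val),
                                                       abs=1e-8)

    def test_shift_invariance_and_absolute_agreement(self, rng):
        """A common shift of both systems leaves ICC(A,1) unchanged; a shift
        of one system alone lowers it."""
        subj = rng.normal(0, 2, 40)
        a = subj + rng.normal(0, 0.5, 40)
        b = subj + rng.normal(0, 0.5, 40)
        base = icc_a1(pairs_of(a, b))
        assert icc_a1(pairs_of(a + 7.0, b + 7.0)) == pytest.approx(base,
                                                                   abs=1e-12)
        assert icc_a1(pairs_of(a + 2.0, b)) < base

    def test_permutation_invariance(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        perm = rng.permutation(30)
        assert icc_a1(pairs_of(a[perm], b[perm])) == pytest.approx(
            icc_a1(pairs_of(a, b)), abs=1e-12)

    def test_zero_variance_undefined(self):
        assert np.isnan(icc_a1(pairs_of([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])))


class TestClassifyIcc:
    @pytest.mark.parametrize("value,label", [
        (0.910, "excellent"), (0.452, "fair"), (0.297, "poor"),
        (0.0, "poor"), (0.4, "fair"), (0.6, "good"), (0.75, "excellent"),
        (1.0, "excellent"), (0.599, "fair"), (0.749, "good"),
    ])
    def test_published_and_boundary_values(self, value, label):
        assert classify_icc(value) == label

    def test_negative_flagged_as_poor(self):
        assert classify_icc(-0.2).startswith("poor")

    def test_monotone(self):
        order = ["poor", "fair", "good", "excellent"]
        grid = np.linspace(0, 1, 201)
        ranks = [order.index(classify_icc(v)) for v in grid]
        assert all(r2 >= r1 for r1, r2 in zip(ranks[:-1], ranks[1:]))

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(1.2)


class TestPearson:
    def test_proportional_pairs(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(pairs_of(a, 2 * a))["r"] == pytest.approx(1.0)
        assert pearson(pairs_of(a, -2 * a))["r"] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        a, b = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
        b = 0.5 * a + b
        r = pearson(pairs_of(a, b))["r"]
        oracle = (np.mean(a * b) - a.mean() * b.mean()) / (
            a.std(ddof=0) * b.std(ddof=0))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(pairs_of([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


def params_table(rec, foot_values, parameter="step_length", t0=0.0):
    rows = []
    for i, (foot, value) in enumerate(foot_values):
        rows.append((rec, "sys", "both", foot, parameter, value,
                     t0 + 0.6 * i))
    return pd.DataFrame(rows, columns=["recording_id", "system", "sides_used",
                                       "foot", "parameter", "value", "time"])


class TestPairSteps:
    def test_equal_counts_pair_by_rank(self):
        a = params_table("r1", [("L", 70.0), ("R", 72.0), ("L", 71.0)])
        b = params_table("r1", [("L", 69.5), ("R", 72.5), ("L", 70.5)])
        p = pair_steps(a, b, "step_length")
        assert p.n == 3 and p.n_dropped == 0
        assert np.allclose(p.values_a - p.values_b, [0.5, -0.5, 0.5])

    def test_missing_middle_step_matched_by_time(self):
        """System B misses one middle step: greedy time matching equals the
        brute-force optimal assignment on this small instance."""
        import itertools
        a = params_table("r1", [("L", 70.0), ("R", 72.0), ("L", 71.0),
                                ("R", 73.0)])
        b = params_table("r1", [("L", 69.0), ("L", 71.5), ("R", 72.5)])
        # drop B's middle: B has steps at t=0, 1.2, 1.8 vs A at 0,0.6,1.2,1.8
        b["time"] = [0.0, 1.2, 1.8]
        p = pair_steps(a, b, "step_length")
        assert p.n == 3 and p.n_dropped == 1
        ta = a["time"].to_numpy()
        tb = b["time"].to_numpy()
        best, best_cost = None, np.inf
        for assign in itertools.permutations(range(len(ta)), len(tb)):
            cost = sum(abs(tb[j] - ta[i]) for j, i in enumerate(assign))
            if all(abs(tb[j] - ta[i]) <= 0.2 for j, i in enumerate(assign)) \
                    and cost < best_cost:
                best, best_cost = assign, cost
        matched_a = sorted(a["value"].to_numpy()[list(best)])
        assert sorted(p.values_a) == pytest.approx(matched_a)

    def test_disjoint_recordings_rejected(self):
        a = params_table("r1", [("L", 70.0)])
        b = params_table("r2", [("L", 70.0)])
        with pytest.raises(ValueError, match="share"):
            pair_steps(a, b, "step_length")


class TestAgreementTable:
    def _two_system_tables(self, rng, bias=0.0, noise=0.0):
        frames_a, frames_b = [], []
        for subj in range(6):
            cadence_steps = [("L", 70 + subj), ("R", 72 + subj)] * 4
            rec = f"S{subj:02d}/T01"
            for parameter in ("step_length", "stride_length", "step_width",
                              "step_time"):
                vals = [(f, v + (10 if parameter == "step_width" else 0))
                        for f, v in cadence_steps]
                a = params_table(rec, [(f, v + bias + rng.normal(0, noise))
                                       for f, v in vals], parameter)
                bt = params_table(rec, vals, parameter)
                frames_a.append(a)
                frames_b.append(bt)
            for df, system in ((frames_a, "a"), (frames_b, "b")):
                df.append(pd.DataFrame(
                    [(rec, system, "both", "both", "walking_speed",
                      120.0 + subj + (bias if system == "a" else 0), np.nan)],
                    columns=["recording_id", "system", "sides_used", "foot",
                             "parameter", "value", "time"]))
        return (pd.concat(frames_a, ignore_index=True),
                pd.concat(frames_b, ignore_index=True))

    def test_identical_systems_are_perfect(self, rng):
        a, b = self._two_system_tables(rng)
        table = agreement_table(a, b)
        assert (table["bias"].abs() < 1e-9).all()
        assert (table["rpc"].abs() < 1e-9).all()
        single = table[table["level"] == "single"]
        assert (single["icc_a1"] > 0.999).all()

    def test_n_column_counts_included_steps(self, rng):
        a, b = self._two_system_tables(rng)
        table = agreement_table(a, b)
        row = table[table["row"].str.startswith("step length L")].iloc[0]
        assert row["n"] == 6 * 4     # 4 left steps per subject
        avg = table[table["row"].str.startswith("AV step length L")].iloc[0]
        assert avg["n"] == 6

    def test_render_matches_published_column_order(self, rng):
        a, b = self._two_system_tables(rng, bias=0.5, noise=0.2)
        text = render_table(agreement_table(a, b))
        header = text.splitlines()[0]
        for col in ("R", "P", "N", "Bias", "RPC", "CV(%)", "ICC(A,1)"):
            assert col in header
        assert "AV Walking Speed (cm/s)" in text


def test_agreement_stats_flags_propagate(rng):
    p = pairs_of([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    st = agreement_stats(p)
    assert st.icc_category == "undefined"
    assert any("icc undefined" in f for f in st.flags)
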