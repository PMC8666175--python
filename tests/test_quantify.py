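"""Interference flagging, ratio computation, normalization, rollup."""

import numpy as np
import pandas as pd
import pytest

from srmquant.quantify import (
    NormalizationResult,
    compute_ratios,
    flag_interference,
    normalize,
    rollup,
)
from srmquant.srm_data import TRANSITION_COLUMNS, ValidationError


def transition_rows(run, pep, light, heavy, protein="P1"):
    """Build paired light/heavy transition rows from area dicts."""
    rows = []
    for frag, a in light.items():
        rows.append((run, protein, pep, 2, frag, "light", 10.0, a))
    for frag, a in heavy.items():
        rows.append((run, protein, pep, 2, frag, "heavy", 10.0, a))
    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


class TestFlagInterference:
    def test_deviant_transition_excluded(self):
        t = transition_rows("r1", "AAAAAAAK",
                            light={"y5": 100, "y6": 105, "y7": 400},
                            heavy={"y5": 100, "y6": 100, "y7": 100})
        excluded, warn = flag_interference(t, fold_tolerance=2.0)
        assert list(excluded["fragment"]) == ["y7"]
        assert excluded.iloc[0]["reason"] == "interference"
        assert not warn

    def test_consistent_ratios_unflagged(self):
        t = transition_rows("r1", "AAAAAAAK",
                            light={"y5": 100, "y6": 200, "y7": 300},
                            heavy={"y5": 50, "y6": 100, "y7": 150})
        excluded, _ = flag_interference(t)
        assert excluded.empty

    def test_single_transition_warns_not_flags(self):
        t = transition_rows("r1", "AAAAAAAK", light={"y5": 100},
                            heavy={"y5": 50})
        excluded, warn = flag_interference(t)
        assert excluded.empty
        assert len(warn) == 1

    def test_never_excludes_all_transitions(self):
        # two transitions > 2-fold apart: at most one can be excluded
        t = transition_rows("r1", "AAAAAAAK",
                            light={"y5": 100, "y6": 1000},
                            heavy={"y5": 100, "y6": 100})
        excluded, _ = flag_interference(t)
        assert len(excluded) <= 1

    def test_injected_contamination_detected(self):
        """8x interference injected into 5% of transitions: >= 95% of
        contaminated transitions flagged, <= 1% clean ones false-flagged."""
        rng_master = np.random.default_rng(2024)
        seeds = rng_master.integers(0, 2**31, size=50)
        tp = fp = pos = neg = 0
        for seed in seeds:
            rng = np.random.default_rng(seed)
            frames, labels = [], {}
            for r in range(4):
                for p in range(10):
                    pep = f"{'ACDEFGHILN'[p]}AAAAAAK"
                    heavy = {f"y{i}": 1000.0 * rng.lognormal(0, 0.05)
                             for i in range(4, 9)}
                    light = {f: a * 0.5 * rng.lognormal(0, 0.05)
                             for f, a in heavy.items()}
                    for f in light:
                        contaminated = rng.random() < 0.05
                        labels[(f"r{r}", pep, f)] = contaminated
                        if contaminated:
                            light[f] *= 8.0
                    frames.append(transition_rows(f"r{r}", pep, light, heavy))
            table = pd.concat(frames, ignore_index=True)
            excluded, _ = flag_interference(table, fold_tolerance=2.0)
            flagged = set(zip(excluded["run_id"], excluded["peptide"],
                              excluded["fragment"]))
            for key, is_bad in labels.items():
                if is_bad:
                    pos += 1
                    tp += key in flagged
                else:
                    neg += 1
                    fp += key in flagged
        assert tp / pos >= 0.95
        assert fp / neg <= 0.01


class TestComputeRatios:
    def test_summed_transition_ratio(self):
        t = transition_rows("r1", "AAAAAAAK", light={"y5": 100, "y6": 200},
                            heavy={"y5": 50, "y6": 100})
        out = compute_ratios(t)
        assert out.loc[0, "ratio"] == pytest.approx(2.0)
        assert out.loc[0, "transitions_used"] == 2

    def test_orientation_flip(self):
        t = transition_rows("r1", "AAAAAAAK", light={"y5": 100},
                            heavy={"y5": 50})
        out = compute_ratios(t, orientation="heavy_over_light")
        assert out.loc[0, "ratio"] == pytest.approx(0.5)

    def test_missing_light_gives_reason_code(self):
        t = transition_rows("r1", "AAAAAAAK", light={"y5": np.nan},
                            heavy={"y5": 50})
        out = compute_ratios(t)
        assert np.isnan(out.loc[0, "ratio"])
        assert out.loc[0, "reason"] == "no_light_signal"

    def test_zero_heavy_sum_missing_with_reason(self):
        t = transition_rows("r1", "AAAAAAAK", light={"y5": 100},
                            heavy={"y5": 0.0})
        out = compute_ratios(t)
        assert np.isnan(out.loc[0, "ratio"])
        assert out.loc[0, "reason"] == "zero_heavy_sum"

    def test_used_plus_excluded_covers_measured(self):
        t = transition_rows("r1", "AAAAAAAK",
                            light={"y5": 100, "y6": 200, "y7": np.nan},
                            heavy={"y5": 50, "y6": 100, "y7": 10})
        excluded = pd.DataFrame([dict(run_id="r1", peptide="AAAAAAAK",
                                      fragment="y6", reason="interference")])
        out = compute_ratios(t, excluded=excluded)
        assert out.loc[0, "transitions_used"] + out.loc[0, "n_excluded"] == 3
        assert out.loc[0, "ratio"] == pytest.approx(2.0)  # y5 only


def ratio_table(log2_heavy, log2_ratio):
    """runs x peptides log2 matrices -> tidy ratio table."""
    rows = []
    for run in log2_heavy.index:
        for pep in log2_heavy.columns:
            rows.append(dict(run_id=run, protein="P1", peptide=pep,
                             light_sum=np.nan,
                             heavy_sum=2.0 ** log2_heavy.loc[run, pep],
                             ratio=2.0 ** log2_ratio.loc[run, pep],
                             log2_ratio=log2_ratio.loc[run, pep],
                             transitions_used=3, n_excluded=0, reason=""))
    return pd.DataFrame(rows)


class TestNormalize:
    def _base(self, n_runs=6, n_peps=8, seed=0):
        rng = np.random.default_rng(seed)
        runs = [f"r{i}" for i in range(n_runs)]
        peps = [f"{c}AAAAAAK" for c in "ACDEFGHI"[:n_peps]]
        heavy = pd.DataFrame(rng.normal(15, 0.1, (n_runs, n_peps)),
                             index=runs, columns=peps)
        ratios = pd.DataFrame(rng.normal(0, 0.1, (n_runs, n_peps)),
                              index=runs, columns=peps)
        return heavy, ratios

    def test_identical_runs_identity(self):
        heavy = pd.DataFrame(15.0, index=["r0", "r1"],
                             columns=["AAAAAAAK", "CAAAAAAK", "DAAAAAAK"])
        ratios = pd.DataFrame([[0.1, 0.2, 0.3], [0.1, 0.2, 0.3]],
                              index=heavy.index, columns=heavy.columns)
        res = normalize(ratio_table(heavy, ratios))
        assert (res.run_factors == 0).all()
        np.testing.assert_allclose(res.values.values, ratios.values)

    def test_injected_offset_removed(self):
        heavy, ratios = self._base()
        heavy.loc["r2"] += 1.0   # +1 log2 loading offset hits heavy areas
        ratios.loc["r2"] += 1.0  # ... and the measured ratios
        res = normalize(ratio_table(heavy, ratios))
        run_means = res.values.mean(axis=1)
        others = run_means.drop("r2").mean()
        assert abs(run_means["r2"] - others) < 0.05

    def test_median_factor_matches_least_squares_on_symmetric_data(self):
        # with symmetric (outlier-free) residuals the median and the
        # two-way least-squares run effect coincide
        heavy = pd.DataFrame(
            [[15.0, 16.0, 17.0], [15.5, 16.5, 17.5]],
            index=["r0", "r1"],
            columns=["AAAAAAAK", "CAAAAAAK", "DAAAAAAK"])
        ratios = pd.DataFrame(0.0, index=heavy.index, columns=heavy.columns)
        t = ratio_table(heavy, ratios)
        med = normalize(t, method="median").run_factors
        ls = normalize(t, method="linear_model").run_factors
        np.testing.assert_allclose(med.values, ls.values, atol=1e-6)
        np.testing.assert_allclose(med.values, [-0.25, 0.25], atol=1e-6)

    def test_sparse_run_flagged_factor_zero(self):
        heavy, ratios = self._base(n_peps=3)
        heavy.loc["r0", ["CAAAAAAK", "DAAAAAAK"]] = np.nan
        t = ratio_table(heavy, ratios)
        t.loc[(t["run_id"] == "r0") & t["peptide"].isin(
            ["CAAAAAAK", "DAAAAAAK"]), "heavy_sum"] = np.nan
        res = normalize(t)
        assert res.run_factors["r0"] == 0.0
        assert any("r0" in w for w in res.warnings)

    def test_contrast_unbiased_without_technical_effects(self):
        """Normalization leaves between-group contrasts unbiased when no
        run effects exist (mean shift < 3 SE over 200 simulations)."""
        shifts = []
        for s in range(200):
            rng = np.random.default_rng(s)
            heavy, ratios = self._base(n_runs=10, seed=s)
            ratios.iloc[5:] += 1.0  # true group contrast
            res = normalize(ratio_table(heavy, ratios))
            raw = ratios.iloc[5:].mean().mean() - ratios.iloc[:5].mean().mean()
            norm = (res.values.iloc[5:].mean().mean()
                    - res.values.iloc[:5].mean().mean())
            shifts.append(norm - raw)
        se = np.std(shifts, ddof=1) / np.sqrt(len(shifts))
        assert abs(np.mean(shifts)) < 3 * se + 1e-12


class TestRollup:
    def test_equal_weights_mean(self):
        vals = pd.DataFrame({"A": [2.0], "C": [4.0]}, index=["s1"])
        m = rollup(vals, {"A": "P1", "C": "P1"}, scheme="equal")
        assert m.values.loc["s1", "P1"] == pytest.approx(3.0)

    def test_single_peptide_identity(self):
        vals = pd.DataFrame({"A": [2.0, 5.0]}, index=["s1", "s2"])
        m = rollup(vals, {"A": "P1"})
        np.testing.assert_allclose(m.values["P1"], [2.0, 5.0])

    def test_inverse_variance_matches_closed_form(self):
        rng = np.random.default_rng(8)
        n = 4000
        vals = pd.DataFrame({
            "A": 10.0 + rng.normal(0, 0.1, n),   # error var 0.01
            "C": 10.0 + rng.normal(0, 0.2, n),   # error var 0.04
        }, index=[f"s{i}" for i in range(n)])
        m = rollup(vals, {"A": "P1", "C": "P1"}, scheme="inverse_variance")
        w = m.provenance["P1"]
        # closed-form minimum-variance weights 1/sigma^2: {0.8, 0.2}
        assert w["A"] == pytest.approx(0.8, abs=0.02)
        assert w["C"] == pytest.approx(0.2, abs=0.02)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(9)
        vals = pd.DataFrame(rng.normal(10, 1, (20, 4)),
                            columns=list("ACDE"),
                            index=[f"s{i}" for i in range(20)])
        m = rollup(vals, {p: "P1" for p in "ACDE"})
        assert sum(m.provenance["P1"].values()) == pytest.approx(1.0)

    def test_shift_consistency(self):
        rng = np.random.default_rng(10)
        vals = pd.DataFrame(rng.normal(10, 1, (10, 3)), columns=list("ACD"),
                            index=[f"s{i}" for i in range(10)])
        mapping = {p: "P1" for p in "ACD"}
        before = rollup(vals, mapping).values
        after = rollup(vals + 2.5, mapping).values
        np.testing.assert_allclose(after.values, before.values + 2.5,
                                   atol=1e-12)

    def test_missing_cells_propagate_not_fabricate(self):
        vals = pd.DataFrame({"A": [2.0, np.nan], "C": [np.nan, np.nan]},
                            index=["s1", "s2"])
        m = rollup(vals, {"A": "P1", "C": "P1"}, scheme="equal")
        assert m.values.loc["s1", "P1"] == pytest.approx(2.0)
        assert np.isnan(m.values.loc["s2", "P1"])

    def test_unmapped_peptide_rejected(self):
        vals = pd.DataFrame({"A": [1.0]}, index=["s1"])
        with pytest.raises(ValidationError):
            rollup(vals, {})
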