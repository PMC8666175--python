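"""Differential model, BH correction, PCA, and Ward clustering."""

import numpy as np
import pandas as pd
import pytest

from srmquant import synthetic
from srmquant.cohort_stats import (
    benjamini_hochberg,
    cluster_proteins,
    fit_condition_model,
    impute_half_min,
    run_pca,
)
from srmquant.quantify import rollup
from srmquant.srm_data import ValidationError


def cohort_matrix(effects=None, noise_sd=0.3, n=(28, 15, 19), seed=0,
                  proteins=("P1", "P2", "P3")):
    """Direct samples x proteins matrix with per-protein condition effects
    (protein -> {cirrhosis: d, HCC: d})."""
    rng = np.random.default_rng(seed)
    labels = (["control"] * n[0] + ["cirrhosis"] * n[1] + ["HCC"] * n[2])
    samples = [f"s{i}" for i in range(len(labels))]
    data = {}
    for prot in proteins:
        eff = (effects or {}).get(prot, {})
        mu = np.array([eff.get(c, 0.0) for c in labels])
        data[prot] = 10.0 + mu + rng.normal(0, noise_sd, len(labels))
    values = pd.DataFrame(data, index=samples)
    values.index.name = "sample_id"
    meta = pd.DataFrame({"run_id": samples, "sample_id": samples,
                         "condition": labels})
    return values, meta


def brute_force_bh(p):
    """Step-up definition applied literally."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestBenjaminiHochberg:
    def test_closed_form_triplet(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_is_its_own_q(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 40)))
            np.testing.assert_array_equal(benjamini_hochberg(p),
                                          brute_force_bh(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, 25)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(benjamini_hochberg(p), q_sm, rtol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1, 20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(benjamini_hochberg(p)[perm],
                                   benjamini_hochberg(p[perm]))

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(1e-6, 1, 30)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= 0)

    def test_invalid_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.1], [np.nan, 0.5]):
            with pytest.raises(ValidationError):
                benjamini_hochberg(bad)


class TestFitConditionModel:
    def test_effect_estimate_recovered(self):
        values, meta = cohort_matrix(
            effects={"P1": {"HCC": 1.0}}, noise_sd=0.3, seed=5)
        res = fit_condition_model(values, meta)
        row = res[(res["protein"] == "P1") & (res["contrast"] == "HCC-control")]
        assert row["effect"].iloc[0] == pytest.approx(1.0, abs=0.25)
        assert row["q_value"].iloc[0] < 0.05

    def test_constant_matrix_p_one_with_flag(self):
        values, meta = cohort_matrix(noise_sd=0.0)
        res = fit_condition_model(values, meta)
        overall = res[res["contrast"] == "overall"]
        assert (overall["p_value"] == 1.0).all()
        assert overall["zero_variance"].all()

    def test_condition_with_too_few_values_untestable(self):
        values, meta = cohort_matrix(n=(5, 4, 4))
        values.iloc[5:8, 0] = np.nan  # leaves 1 cirrhosis value for P1
        res = fit_condition_model(values, meta)
        assert res[res["protein"] == "P1"]["untestable"].all()
        assert not res[res["protein"] == "P2"]["untestable"].any()

    def test_q_values_assigned_per_contrast_family(self):
        values, meta = cohort_matrix()
        res = fit_condition_model(values, meta)
        for label, grp in res.groupby("contrast"):
            order = np.argsort(grp["p_value"].values)
            assert np.all(np.diff(grp["q_value"].values[order]) >= -1e-12)

    def test_subject_blocking_path(self):
        values, meta = cohort_matrix(effects={"P1": {"HCC": 2.0}},
                                     noise_sd=0.2, n=(6, 6, 6))
        meta = meta.copy()
        meta["subject"] = [f"subj{i % 9}" for i in range(len(meta))]
        res = fit_condition_model(values, meta, subject_col="subject")
        row = res[(res["protein"] == "P1") & (res["contrast"] == "overall")]
        assert row["p_value"].iloc[0] < 0.01


class TestPCA:
    def test_rank_one_structure_on_pc1(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 30)
        values = pd.DataFrame({"P1": 10 + a, "P2": 10 - a},
                              index=[f"s{i}" for i in range(30)])
        res = run_pca(values)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.normal(0, 1, (20, 6)),
                              index=[f"s{i}" for i in range(20)],
                              columns=[f"P{i}" for i in range(6)])
        res = run_pca(values)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_protein_order_up_to_sign(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(rng.normal(0, 1, (15, 5)),
                              index=[f"s{i}" for i in range(15)],
                              columns=list("ABCDE"))
        r1 = run_pca(values)
        r2 = run_pca(values[list("ECABD")])
        for pc in ("PC1", "PC2"):
            s1, s2 = r1.scores[pc].values, r2.scores[pc].values
            assert (np.allclose(s1, s2, atol=1e-8)
                    or np.allclose(s1, -s2, atol=1e-8))

    def test_zero_variance_protein_excluded_with_warning(self):
        rng = np.random.default_rng(9)
        values = pd.DataFrame({"P1": rng.normal(0, 1, 10),
                               "P2": np.full(10, 3.0)},
                              index=[f"s{i}" for i in range(10)])
        values["P3"] = rng.normal(0, 1, 10)
        res = run_pca(values)
        assert "P2" not in res.loadings.index
        assert any("P2" in w for w in res.warnings)

    def test_cirrhosis_centroid_intermediate_on_pc1(self):
        """With intermediate cirrhosis effects, the cirrhosis centroid sits
        between the control and HCC centroids along PC1."""
        truth = synthetic.default_ground_truth(hcc_effect=1.5,
                                               cirrhosis_fraction=0.5,
                                               cohort_noise_sd=0.3)
        table, meta = synthetic.generate_cohort(
            synthetic.default_cohort_design(), truth, seed=11)
        matrix = rollup(table, truth.peptide_to_protein)
        res = run_pca(matrix)
        cond = meta.set_index("sample_id")["condition"]
        cents = res.scores["PC1"].groupby(cond).mean()
        assert (cents["control"] < cents["cirrhosis"] < cents["HCC"]
                or cents["control"] > cents["cirrhosis"] > cents["HCC"])


def lance_williams_ward(X):
    """Brute-force Ward agglomeration (independent of scipy)."""
    n = X.shape[0]
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = np.sum((X[i] - X[j]) ** 2)
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        (a, b), best = min(
            ((k, v) for k, v in d2.items()
             if k[0] in active and k[1] in active),
            key=lambda kv: (kv[1], kv[0]))
        merges.append((a, b, np.sqrt(best), sizes[a] + sizes[b]))
        na, nb = sizes[a], sizes[b]
        for c in active - {a, b}:
            nc = sizes[c]
            dac = d2[tuple(sorted((a, c)))]
            dbc = d2[tuple(sorted((b, c)))]
            dab = best
            new = ((na + nc) * dac + (nb + nc) * dbc - nc * dab) / (na + nb + nc)
            d2[tuple(sorted((next_id, c)))] = new
        active -= {a, b}
        active.add(next_id)
        sizes[next_id] = na + nb
        next_id += 1
    return merges


class TestClusterProteins:
    def test_opposite_profiles_recovered(self):
        values, _ = cohort_matrix(
            effects={"P1": {"HCC": 1.5}, "P2": {"HCC": 1.5},
                     "P3": {"HCC": -1.5}, "P4": {"HCC": -1.5}},
            noise_sd=0.1, proteins=("P1", "P2", "P3", "P4"), seed=12)
        res = cluster_proteins(values, k=2)
        assert res.assignments["P1"] == res.assignments["P2"]
        assert res.assignments["P3"] == res.assignments["P4"]
        assert res.assignments["P1"] != res.assignments["P3"]

    def test_identical_profiles_merge_at_zero_height(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0, 1, 12)
        values = pd.DataFrame({"P1": a, "P2": a, "P3": b},
                              index=[f"s{i}" for i in range(12)])
        res = cluster_proteins(values, k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-10)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(14)
        values = pd.DataFrame(rng.normal(0, 1, (20, 8)),
                              index=[f"s{i}" for i in range(20)],
                              columns=[f"P{i}" for i in range(8)])
        res = cluster_proteins(values, k=2)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)

    def test_heights_match_brute_force_ward(self):
        rng = np.random.default_rng(15)
        for trial in range(5):
            values = pd.DataFrame(
                rng.normal(0, 1, (20, 13)),
                index=[f"s{i}" for i in range(20)],
                columns=[f"P{i}" for i in range(13)])
            res = cluster_proteins(values, k=2)
            scaled = (values - values.mean()) / values.std(ddof=1)
            merges = lance_williams_ward(scaled.values.T)
            got = np.sort(res.linkage[:, 2])
            want = np.sort([m[2] for m in merges])
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_k_larger_than_protein_count_rejected(self):
        values, _ = cohort_matrix()
        with pytest.raises(ValidationError):
            cluster_proteins(values, k=10)

    def test_newick_contains_all_proteins(self):
        values, _ = cohort_matrix()
        res = cluster_proteins(values, k=2)
        for p in values.columns:
            assert p in res.newick
        assert res.newick.endswith(";")


class TestImputation:
    def test_half_minimum_fill(self):
        values = pd.DataFrame({"P1": [4.0, np.nan, 8.0]},
                              index=["s1", "s2", "s3"])
        out = impute_half_min(values)
        assert out.loc["s2", "P1"] == pytest.approx(2.0)
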