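"""Gene-set test behaviour: ES oracles, calibration, rotation nulls."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

import hmpenrich as he
from hmpenrich.de import DesignSpec
from hmpenrich.enrichment import (
    fit_linear_model,
    posterior_var,
    squeeze_var,
    t_to_z,
    trigamma_inverse,
)
from hmpenrich.gene_sets import GeneSetCollection
from conftest import make_metadata


def ranked_from(values, prefix="g"):
    return he.RankedList(stats=pd.Series(
        values, index=[f"{prefix}{i:03d}" for i in range(len(values))]
    ))


def oracle_es(stats_sorted, hit_mask, weight=1.0):
    """Exhaustive O(N) running-sum enrichment score."""
    N = len(stats_sorted)
    m = int(hit_mask.sum())
    w = np.abs(stats_sorted) ** weight
    tot = w[hit_mask].sum() or 1.0
    running = 0.0
    best = 0.0
    for i in range(N):
        if hit_mask[i]:
            running += w[i] / tot
        else:
            running -= 1.0 / (N - m)
        if abs(running) > abs(best):
            best = running
    return best


class TestRanking:
    def test_signed_neglog10(self, two_pass):
        de = two_pass["de"]
        r = he.rank_genes(de, "trans_het")
        tab = de.contrast("trans_het")
        g = tab.index[0]
        expected = np.sign(tab.loc[g, "logFC"]) * -np.log10(tab.loc[g, "p"])
        assert r.stats[g] == pytest.approx(expected)

    def test_examples(self):
        tab = pd.DataFrame({
            "gene": ["a", "b"], "contrast": "c",
            "logFC": [-1.0, 2.0], "logCPM": 5.0, "dispersion": 0.1,
            "p": [0.01, 1.0], "fdr": [0.02, 1.0], "de": False, "converged": True,
        })
        de = he.DEResult(table=tab, joint=pd.DataFrame(), design=None)
        r = he.rank_genes(de, "c")
        assert r.stats["a"] == pytest.approx(-2.0)
        assert r.stats["b"] == pytest.approx(0.0)

    def test_order_invariant_to_monotone_p_rescaling(self, rng):
        p = rng.uniform(0.001, 1.0, 50)
        lfc = rng.standard_normal(50)
        def build(pvals):
            tab = pd.DataFrame({
                "gene": [f"g{i}" for i in range(50)], "contrast": "c",
                "logFC": lfc, "logCPM": 5.0, "dispersion": 0.1,
                "p": pvals, "fdr": pvals, "de": False, "converged": True,
            })
            return he.rank_genes(
                he.DEResult(table=tab, joint=pd.DataFrame(), design=None), "c"
            )
        assert build(p).genes == build(p**1.7).genes


class TestGSEA:
    def test_single_top_gene_scores_one(self):
        r = ranked_from(np.linspace(3, -3, 30))
        res = he.gsea_preranked(r, GeneSetCollection(sets={"T": [r.genes[0]]}),
                                n_perm=50, rng=0)
        assert res["es"].iloc[0] == pytest.approx(1.0)

    def test_mirrored_list_negates_es_and_keeps_p(self, rng):
        stats = pd.Series(rng.standard_normal(150),
                          index=[f"g{i:03d}" for i in range(150)])
        sets = GeneSetCollection(sets={
            "A": list(stats.index[:2:20]) or list(stats.index[:20]),
            "B": list(stats.index[40:70]),
        })
        a = he.gsea_preranked(he.RankedList(stats=stats), sets, n_perm=500, rng=9)
        b = he.gsea_preranked(he.RankedList(stats=-stats), sets, n_perm=500, rng=9)
        a, b = a.set_index("set"), b.set_index("set")
        assert np.allclose(a["es"], -b["es"])
        assert np.allclose(a["p"], b["p"])

    def test_es_matches_exhaustive_running_sum(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            stats = np.sort(r.standard_normal(40))[::-1]
            ranked = ranked_from(stats)
            members = list(np.array(ranked.genes)[r.choice(40, 8, replace=False)])
            res = he.gsea_preranked(ranked, GeneSetCollection(sets={"S": members}),
                                    n_perm=10, rng=0)
            hit = np.isin(np.array(ranked.genes), members)
            assert res["es"].iloc[0] == pytest.approx(
                oracle_es(ranked.stats.to_numpy(), hit), abs=1e-12
            )

    def test_p_value_within_binomial_error_of_enumeration(self):
        """20-gene list, 5-gene set: enumerate all C(20,5) same-size sets."""
        rng = np.random.default_rng(4)
        stats = np.sort(rng.standard_normal(20))[::-1]
        ranked = ranked_from(stats)
        members = [ranked.genes[i] for i in (0, 2, 5, 11, 15)]
        hit_obs = np.isin(np.array(ranked.genes), members)
        es_obs = oracle_es(stats, hit_obs)
        null = []
        for combo in combinations(range(20), 5):
            mask = np.zeros(20, dtype=bool)
            mask[list(combo)] = True
            null.append(oracle_es(stats, mask))
        null = np.array(null)
        exact = ((null >= es_obs) & (null >= 0)).sum() / (null >= 0).sum() \
            if es_obs >= 0 else ((null <= es_obs) & (null <= 0)).sum() / (null <= 0).sum()
        res = he.gsea_preranked(ranked, GeneSetCollection(sets={"S": members}),
                                n_perm=20_000, rng=1)
        p_mc = res["p"].iloc[0]
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(p_mc - exact) < 4 * se + 2e-4

    def test_weight_zero_invariant_under_monotone_transform(self, rng):
        stats = np.sort(rng.standard_normal(60))[::-1]
        ranked = ranked_from(stats)
        members = [ranked.genes[i] for i in rng.choice(60, 10, replace=False)]
        sets = GeneSetCollection(sets={"S": members})
        a = he.gsea_preranked(ranked, sets, n_perm=10, gsea_weight=0.0, rng=0)
        transformed = ranked_from(np.tanh(stats) * 3.0)
        b = he.gsea_preranked(transformed, sets, n_perm=10, gsea_weight=0.0, rng=0)
        assert a["es"].iloc[0] == pytest.approx(b["es"].iloc[0])

    def test_leading_edge_contains_extremum_prefix(self, rng):
        stats = np.linspace(4, -4, 50)
        ranked = ranked_from(stats)
        members = [ranked.genes[i] for i in (0, 1, 2, 40)]
        res = he.gsea_preranked(ranked, GeneSetCollection(sets={"S": members}),
                                n_perm=50, rng=0)
        lead = res["leading_edge"].iloc[0].split(",")
        assert set(lead) == {ranked.genes[0], ranked.genes[1], ranked.genes[2]}


class TestModeratedT:
    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for y in (0.001, 0.5, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-6)

    def test_squeeze_var_recovers_prior_scale(self, rng):
        df, d0_true, s0_true = 10, 20.0, 2.0
        s2 = s0_true * d0_true / st.chi2.rvs(d0_true, size=4000,
                                             random_state=1) \
            * st.chi2.rvs(df, size=4000, random_state=2) / df
        d0, s0 = squeeze_var(s2, df)
        assert 0.7 * s0_true < s0 < 1.3 * s0_true
        assert 10 < d0 < 40

    def test_posterior_var_interpolates(self):
        assert posterior_var(np.array([4.0]), 10, np.inf, 1.0)[0] == 1.0
        v = posterior_var(np.array([4.0]), 10, 10.0, 1.0)[0]
        assert 1.0 < v < 4.0


class TestCompetitive:
    def test_size_one_set_uses_unit_vif(self, enrichment_state):
        sets = GeneSetCollection(
            sets={"solo": [enrichment_state.logcpm.index[0]]}
        )
        res = he.competitive_test(
            enrichment_state.logcpm, enrichment_state.design, "trans_het", sets
        )
        assert res["vif"].iloc[0] == 1.0

    def test_zero_correlation_reduces_to_plain_z_test(self, rng):
        meta = make_metadata()
        design = DesignSpec.from_metadata(meta)
        Y = pd.DataFrame(rng.standard_normal((400, 24)),
                         index=[f"g{i}" for i in range(400)],
                         columns=meta.index)
        members = [f"g{i}" for i in range(30)]
        res = he.competitive_test(Y, design, "trans_het",
                                  GeneSetCollection(sets={"S": members}))
        fit = fit_linear_model(Y, design)
        z = t_to_z(fit.moderated_t("genotype_trans_het").to_numpy(),
                   fit.df_total)
        vif = res["vif"].iloc[0]
        sd = z.std(ddof=1)
        manual = (z[:30].mean() - z[30:].mean()) / (
            sd * np.sqrt(vif / 30 + 1 / 370)
        )
        assert res["stat"].iloc[0] == pytest.approx(manual)
        assert abs(res["rho_bar"].iloc[0]) < 0.05

    def test_vif_restores_calibration_under_correlation(self, rng):
        """The defining property: with within-set correlation 0.1 the plain
        two-sample test is anti-conservative, the VIF-adjusted one is not."""
        meta = make_metadata()
        design = DesignSpec.from_metadata(meta)
        rho, m, nsets = 0.1, 30, 500
        blocks, names = [], []
        for k in range(nsets):
            f = rng.standard_normal(24)
            e = rng.standard_normal((m, 24))
            blocks.append(np.sqrt(rho) * f + np.sqrt(1 - rho) * e)
            names += [f"s{k:03d}_{j}" for j in range(m)]
        Y = pd.DataFrame(np.vstack(blocks), index=names, columns=meta.index)
        sets = GeneSetCollection(sets={
            f"S{k}": [f"s{k:03d}_{j}" for j in range(m)] for k in range(nsets)
        })
        res = he.competitive_test(Y, design, "trans_het", sets)
        adjusted = (res["p"] < 0.05).mean()
        fit = fit_linear_model(Y, design)
        z = t_to_z(fit.moderated_t("genotype_trans_het").to_numpy(),
                   fit.df_total)
        sd, N = z.std(ddof=1), len(z)
        naive = []
        for k in range(nsets):
            zk = z[k * m:(k + 1) * m]
            rest_mean = (z.sum() - zk.sum()) / (N - m)
            stat = (zk.mean() - rest_mean) / (sd * np.sqrt(1 / m + 1 / (N - m)))
            naive.append(2 * st.norm.sf(abs(stat)))
        unadjusted = (np.array(naive) < 0.05).mean()
        assert unadjusted > 0.10
        assert 0.03 <= adjusted <= 0.07


class TestRotation:
    def toy(self, rng, G=80, n=6):
        meta = pd.DataFrame({
            "genotype": ["wildtype"] * 3 + ["trans_het"] * 3,
            "sex": ["female", "male"] * 3,
        }, index=[f"s{j}" for j in range(n)])
        meta["genotype"] = pd.Categorical(
            meta["genotype"], categories=["wildtype", "trans_het"]
        )
        design = DesignSpec.from_metadata(meta)
        Y = pd.DataFrame(rng.standard_normal((G, n)),
                         index=[f"g{i:03d}" for i in range(G)],
                         columns=meta.index)
        sets = GeneSetCollection(sets={
            "A": [f"g{i:03d}" for i in range(10)],
            "B": [f"g{i:03d}" for i in range(20, 45)],
        })
        return Y, design, sets

    def test_extreme_statistic_hits_p_floor(self, rng):
        Y, design, sets = self.toy(rng)
        Y.iloc[:10, 3:] += 50.0  # set A massively shifted in trans_het
        res = he.rotation_test(Y, design, "trans_het", sets, n_rot=199, rng=0)
        assert res.set_index("set").loc["A", "p"] == pytest.approx(1 / 200)

    def test_identical_samples_give_p_one(self, rng):
        Y, design, sets = self.toy(rng)
        Y.loc[:, :] = np.tile(Y.iloc[:, [0]].to_numpy(), (1, 6))
        res = he.rotation_test(Y, design, "trans_het", sets, n_rot=99, rng=0)
        assert (res["p"] == 1.0).all()

    def test_matches_explicit_rotation_matrix_oracle(self, rng):
        """Independent re-implementation: full random orthogonal rotations of
        the (effect + residual) coordinates, explicit per-rotation variance."""
        Y, design, sets = self.toy(rng)
        res = he.rotation_test(Y, design, "trans_het", sets, n_rot=5000, rng=2)

        X = design.matrix[
            [c for c in design.matrix.columns if c != "genotype_trans_het"]
            + ["genotype_trans_het"]
        ].to_numpy()
        n, p = X.shape
        q, r = np.linalg.qr(X, mode="complete")
        if r[p - 1, p - 1] < 0:
            q[:, p - 1] = -q[:, p - 1]
        z = Y.to_numpy() @ q[:, p - 1:]
        d = z.shape[1]
        s2 = (z[:, 1:] ** 2).sum(axis=1) / (d - 1)
        d0, s0 = squeeze_var(s2, d - 1)
        t_obs = z[:, 0] / np.sqrt(posterior_var(s2, d - 1, d0, s0))
        oracle_rng = np.random.default_rng(123)
        n_rot = 5000
        exceed = {name: 0 for name in sets.sets}
        for _ in range(n_rot):
            R = np.linalg.qr(oracle_rng.standard_normal((d, d)))[0]
            zr = z @ R.T
            s2r = (zr[:, 1:] ** 2).sum(axis=1) / (d - 1)
            tr = zr[:, 0] / np.sqrt(posterior_var(s2r, d - 1, d0, s0))
            for name, members in sets.sets.items():
                idx = [int(g[1:]) for g in members]
                if abs(tr[idx].mean()) >= abs(t_obs[idx].mean()):
                    exceed[name] += 1
        for name in sets.sets:
            p_oracle = (exceed[name] + 1) / (n_rot + 1)
            p_ours = res.set_index("set").loc[name, "p"]
            se = np.sqrt(p_oracle * (1 - p_oracle) / n_rot)
            assert abs(p_ours - p_oracle) < 4 * se + 1e-3, name


class TestUniformity:
    def test_null_p_values_approximately_uniform(self, rng):
        """Fully null data: each method's p over 1000 sets passes a KS check."""
        meta = make_metadata()
        design = DesignSpec.from_metadata(meta)
        G = 3000
        genes = [f"g{i:04d}" for i in range(G)]
        Y = pd.DataFrame(rng.standard_normal((G, 24)), index=genes,
                         columns=meta.index)
        sets = GeneSetCollection(sets={
            f"S{k}": list(rng.choice(genes, size=rng.integers(15, 61),
                                     replace=False))
            for k in range(1000)
        })
        rot = he.rotation_test(Y, design, "trans_het", sets, n_rot=999, rng=1)
        comp = he.competitive_test(Y, design, "trans_het", sets)
        stats_null = pd.Series(rng.standard_normal(G), index=genes)
        gs = he.gsea_preranked(he.RankedList(stats=stats_null), sets,
                               n_perm=999, rng=2)
        for name, tab in (("rotation", rot), ("competitive", comp),
                          ("gsea", gs)):
            ks = st.kstest(tab["p"], "uniform")
            assert ks.pvalue > 0.01, (name, ks)
            assert (tab["p"] > 0).all() and (tab["p"] <= 1).all()
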