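"""Aggregation, detection filter, TMM and CPM behaviour."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import hmpenrich as he
from hmpenrich.counts import (
    AggregationError,
    CountMatrix,
    FilterRule,
    TranscriptAbundanceTable,
    cpm,
)


def tiny_table():
    est = pd.DataFrame(
        {
            "s1": [10.0, 5.0, 3.0, 7.0],
            "s2": [20.0, 10.0, 6.0, 14.0],
        },
        index=["gA.t1", "gA.t2", "gA.unspliced", "gB.t1"],
    )
    t2g = pd.Series(["gA", "gA", "gA", "gB"], index=est.index)
    unspliced = pd.Series([False, False, True, False], index=est.index)
    return TranscriptAbundanceTable(est_counts=est, tx2gene=t2g,
                                    unspliced=unspliced)


class TestAggregation:
    def test_mature_transcripts_summed_unspliced_omitted(self):
        m = he.aggregate_to_genes(tiny_table())
        assert m.counts.loc["gA", "s1"] == 15.0  # 10 + 5, not the 3 unspliced
        assert m.counts.loc["gB", "s2"] == 14.0

    def test_gene_with_only_unspliced_rows_keeps_zero_row(self):
        est = pd.DataFrame({"s1": [4.0, 1.0]}, index=["gA.t1", "gC.unspliced"])
        tab = TranscriptAbundanceTable(
            est_counts=est,
            tx2gene=pd.Series(["gA", "gC"], index=est.index),
            unspliced=pd.Series([False, True], index=est.index),
        )
        m = he.aggregate_to_genes(tab)
        assert m.counts.loc["gC", "s1"] == 0.0

    def test_unmapped_transcript_raises_with_ids(self):
        tab = tiny_table()
        tab.tx2gene = tab.tx2gene.drop("gB.t1")
        with pytest.raises(AggregationError, match="gB.t1"):
            he.aggregate_to_genes(tab)

    def test_mass_conservation_and_truth_totals(self, planted_sim):
        from hmpenrich.counts import from_simulation

        tab = from_simulation(planted_sim["tables"])
        m = he.aggregate_to_genes(tab)
        mature_total = tab.est_counts.loc[~tab.unspliced].to_numpy().sum()
        assert m.counts.to_numpy().sum() == pytest.approx(mature_total)
        assert list(m.counts.index) == sorted(m.counts.index)


class TestFilter:
    def build(self, n_low):
        """One gene below threshold in exactly ``n_low`` of 24 samples."""
        counts = np.full((2, 24), 2000.0)
        # on a 1e6 library, CPM 0.66 corresponds to a count of 0.66
        counts[1, :n_low] = 0.5
        counts[1, n_low:] = 2000.0
        frame = pd.DataFrame(counts, index=["keep", "border"],
                             columns=[f"s{j}" for j in range(24)])
        filler = pd.DataFrame(
            np.full((3, 24), (1e6 - frame.sum(axis=0).to_numpy()) / 3),
            index=["f1", "f2", "f3"], columns=frame.columns,
        )
        return CountMatrix(counts=pd.concat([frame, filler]))

    def test_undetected_in_exactly_half_is_removed(self):
        out = he.filter_undetected(self.build(12))
        assert "border" not in out.counts.index

    def test_detected_in_13_of_24_is_retained(self):
        out = he.filter_undetected(self.build(11))
        assert "border" in out.counts.index

    def test_all_zero_gene_always_removed(self):
        m = self.build(0)
        m.counts.loc["zero"] = 0.0
        out = he.filter_undetected(CountMatrix(counts=m.counts))
        assert "zero" not in out.counts.index

    def test_filtering_is_idempotent(self, processed):
        again = he.filter_undetected(CountMatrix(counts=processed.counts))
        assert list(again.counts.index) == list(processed.counts.index)

    def test_library_sizes_recomputed_after_filter(self):
        out = he.filter_undetected(self.build(12))
        assert np.allclose(out.lib_sizes, out.counts.sum(axis=0))


class TestCPM:
    def test_basic_scaling(self):
        m = CountMatrix(counts=pd.DataFrame({"s1": [1.0, 1.0]}, index=["a", "b"]))
        assert np.allclose(cpm(m)["s1"], [500000.0, 500000.0])

    def test_columns_sum_to_one_million(self, processed):
        raw = cpm(processed, use_norm_factors=False)
        assert np.allclose(raw.sum(axis=0), 1e6)

    def test_monotone_within_sample(self, processed):
        col = processed.counts.iloc[:, 0]
        vals = cpm(processed).iloc[:, 0]
        a, b = col.idxmax(), col.idxmin()
        assert vals[a] > vals[b]

    def test_log_variant_finite_at_zero(self):
        m = CountMatrix(counts=pd.DataFrame({"s1": [0.0, 10.0]}, index=["a", "b"]))
        vals = cpm(m, log=True)
        assert np.isfinite(vals).all().all()
        assert vals.loc["b", "s1"] > vals.loc["a", "s1"]


def brute_force_tmm(counts, logratio_trim=0.3, sum_trim=0.05):
    """Straightforward double-loop transcription of the published TMM rule."""
    counts = np.asarray(counts, dtype=float)
    G, n = counts.shape
    libs = counts.sum(axis=0)
    uq = [np.quantile(counts[:, j] / libs[j], 0.75) for j in range(n)]
    ref = min(range(n), key=lambda j: abs(uq[j] - np.mean(uq)))
    log_factors = []
    for j in range(n):
        M, A, W = [], [], []
        for g in range(G):
            if counts[g, j] > 0 and counts[g, ref] > 0:
                pj = counts[g, j] / libs[j]
                pr = counts[g, ref] / libs[ref]
                M.append(np.log2(pj / pr))
                A.append(0.5 * np.log2(pj * pr))
                W.append(
                    (libs[j] - counts[g, j]) / (libs[j] * counts[g, j])
                    + (libs[ref] - counts[g, ref]) / (libs[ref] * counts[g, ref])
                )
        M, A, W = np.array(M), np.array(A), np.array(W)
        if M.size == 0 or np.allclose(M, 0, atol=1e-10):
            log_factors.append(0.0)
            continue
        from scipy.stats import rankdata

        nn = M.size
        rank_m = rankdata(M)
        rank_a = rankdata(A)
        lo_m, hi_m = np.floor(nn * logratio_trim) + 1, nn - np.floor(nn * logratio_trim)
        lo_a, hi_a = np.floor(nn * sum_trim) + 1, nn - np.floor(nn * sum_trim)
        keep = [(lo_m <= rank_m[i] <= hi_m) and (lo_a <= rank_a[i] <= hi_a)
                for i in range(nn)]
        keep = np.array(keep)
        if not keep.any():
            log_factors.append(0.0)
            continue
        log_factors.append(np.sum(M[keep] / W[keep]) / np.sum(1.0 / W[keep]))
    f = 2.0 ** np.array(log_factors)
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[100.0], [50.0], [10.0]], (1, 4)),
                              index=["a", "b", "c"],
                              columns=[f"s{j}" for j in range(4)])
        out = he.tmm_normalize(CountMatrix(counts=counts))
        assert np.allclose(out.norm_factors, 1.0)

    def test_doubled_sample_absorbed_by_library_size(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(100, size=50).astype(float) + 1
        counts = pd.DataFrame({"s1": base, "s2": 2 * base, "s3": base})
        out = he.tmm_normalize(CountMatrix(counts=counts))
        assert np.allclose(out.norm_factors, 1.0, atol=1e-10)

    def test_matches_bruteforce_oracle(self, rng):
        mu = rng.lognormal(3, 1, size=200)
        counts = rng.negative_binomial(5, 5 / (5 + mu[:, None]), size=(200, 4))
        counts = pd.DataFrame(counts.astype(float) + 0.0)
        counts = counts.loc[counts.sum(axis=1) > 0]
        ours = he.tmm_normalize(CountMatrix(counts=counts)).norm_factors
        oracle = brute_force_tmm(counts.to_numpy())
        assert np.max(np.abs(ours.to_numpy() - oracle)) < 1e-10

    def test_invariant_to_global_rescaling(self, rng):
        counts = pd.DataFrame(
            rng.poisson(60, size=(100, 5)).astype(float) + 1.0
        )
        a = he.tmm_normalize(CountMatrix(counts=counts)).norm_factors
        b = he.tmm_normalize(CountMatrix(counts=counts * 7.0)).norm_factors
        assert np.allclose(a, b)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]})
        with pytest.raises(ValueError, match="all-zero"):
            he.tmm_normalize(CountMatrix(counts=counts))

    def test_agrees_with_edger_reference(self, tmp_path, rng):
        """Independent cross-check against the Bioconductor implementation."""
        mu = rng.lognormal(4, 1, size=300)
        counts = rng.negative_binomial(8, 8 / (8 + mu[:, None]), size=(300, 6))
        counts = pd.DataFrame(counts.astype(float),
                              columns=[f"s{j}" for j in range(6)])
        counts = counts.loc[counts.sum(axis=1) > 0]
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("{path}"))
            f <- calcNormFactors(x, method="TMM")
            cat(sprintf("%.12f", f), sep="\\n")
        """)
        rscript = tmp_path / "tmm.R"
        rscript.write_text(script)
        proc = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                              text=True, timeout=300)
        if proc.returncode != 0:
            pytest.skip(f"Rscript/edgeR unavailable: {proc.stderr[:200]}")
        ref = np.array([float(v) for v in proc.stdout.split()])
        ours = he.tmm_normalize(CountMatrix(counts=counts)).norm_factors
        assert np.allclose(ours.to_numpy(), ref, atol=1e-6)
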