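"""Downstream expression statistics: TPM normalization, replicate QC, gene
selection, binomial enrichment and hierarchical clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fluxscape.expression import (
    binomial_enrichment,
    counts_to_logtpm,
    hierarchical_cluster,
    replicate_qc,
    select_phenotype_genes,
)
from fluxscape.model import InputError


def _matrix(counts, lengths, samples=None):
    genes = [f"g{i}" for i in range(len(lengths))]
    df = pd.DataFrame(
        np.asarray(counts, dtype=float),
        index=genes,
        columns=samples or [f"s{j}" for j in range(np.shape(counts)[1])],
    )
    return df, pd.Series(lengths, index=genes, dtype=float)


class TestLogTPM:
    def test_single_expressed_gene_takes_the_whole_million(self):
        counts, lengths = _matrix([[10], [0]], [100, 100])
        lt = counts_to_logtpm(counts, lengths)
        assert lt.iloc[0, 0] == pytest.approx(math.log2(1e6 + 1))
        assert lt.iloc[1, 0] == 0.0

    def test_tpm_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts, lengths = _matrix(
            rng.integers(0, 500, (50, 4)), rng.integers(200, 3000, 50)
        )
        lt = counts_to_logtpm(counts, lengths)
        tpm = np.power(2.0, lt) - 1.0
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_two_gene_hand_example(self):
        counts, lengths = _matrix([[10], [10]], [100, 200])
        lt = counts_to_logtpm(counts, lengths)
        tpm = np.power(2.0, lt.iloc[:, 0]) - 1.0
        assert tpm.iloc[0] == pytest.approx(666666.7, rel=1e-6)
        assert tpm.iloc[1] == pytest.approx(333333.3, rel=1e-6)

    def test_all_zero_sample_rejected_by_name(self):
        counts, lengths = _matrix([[1, 0], [2, 0]], [100, 100], ["ok", "empty"])
        with pytest.raises(InputError, match="empty"):
            counts_to_logtpm(counts, lengths)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance_of_one_sample(self, scale):
        counts, lengths = _matrix([[10, 10], [25, 25], [3, 3]], [100, 250, 900])
        scaled = counts.copy()
        scaled.iloc[:, 1] *= scale
        a = counts_to_logtpm(counts, lengths)
        b = counts_to_logtpm(scaled, lengths)
        assert np.allclose(a.iloc[:, 1], b.iloc[:, 1], atol=1e-9)


class TestReplicateQC:
    def test_identical_replicates_give_unit_r2(self):
        rng = np.random.default_rng(0)
        x = rng.random(100)
        lt = pd.DataFrame({"a_r1": x, "a_r2": x})
        assert replicate_qc(lt, [("a_r1", "a_r2")]).iloc[0] == pytest.approx(1.0)

    def test_synthetic_fixture_replicates_highly_correlated(
        self, expression_fixture
    ):
        matrix, truth = expression_fixture
        lt = counts_to_logtpm(matrix.counts, matrix.lengths)
        qc = replicate_qc(lt, truth["replicate_pairs"])
        assert (qc > 0.97).all()

    def test_independent_profiles_uncorrelated(self):
        rng = np.random.default_rng(1)
        lt = pd.DataFrame({"a": rng.normal(size=4000), "b": rng.normal(size=4000)})
        assert replicate_qc(lt, [("a", "b")]).iloc[0] < 0.01

    def test_constant_profile_rejected(self):
        lt = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        with pytest.raises(InputError):
            replicate_qc(lt, [("a", "b")])


class TestGeneSelection:
    def _design(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        q_ac = rng.uniform(1, 8, n)
        Y = 0.6 - 0.04 * q_ac + rng.normal(0, 0.002, n)
        mu = rng.uniform(0.4, 0.9, n)
        ann = pd.DataFrame(
            {"mu": mu, "Y": Y, "q_ac": q_ac,
             "q_glc": mu / (Y * 0.18), "q_o2": rng.uniform(5, 15, n)},
            index=[f"s{j}" for j in range(n)],
        )
        return ann, rng

    def test_constructed_signal_gene_selected(self):
        ann, rng = self._design()
        signal = 2.0 * ann["q_ac"] + rng.normal(0, 0.1, len(ann))
        # orthogonalize against growth rate so the mu test stays null
        signal = signal - np.polyval(np.polyfit(ann["mu"], signal, 1), ann["mu"])
        noise = rng.normal(size=len(ann))
        lt = pd.DataFrame({"sig": signal, "noise": noise}, index=ann.index).T
        selected, report = select_phenotype_genes(lt, ann)
        assert "sig" in selected
        assert report.loc["sig", "p_q_ac"] < 0.01

    def test_growth_rate_tracking_gene_excluded(self):
        ann, rng = self._design(seed=1)
        mu_gene = 3.0 * ann["mu"] + rng.normal(0, 0.05, len(ann))
        lt = pd.DataFrame({"mu_gene": mu_gene}, index=ann.index).T
        selected, _ = select_phenotype_genes(lt, ann)
        assert "mu_gene" not in selected

    def test_planted_genes_recovered_from_fixture(self, expression_fixture):
        matrix, truth = expression_fixture
        lt = counts_to_logtpm(matrix.counts, matrix.lengths)
        selected, _ = select_phenotype_genes(lt, matrix.annotations)
        planted = truth["gene_sets"]["oxphos"]
        assert len(selected & planted) >= 45

    def test_selection_enriched_in_planted_set(self, expression_fixture):
        matrix, truth = expression_fixture
        lt = counts_to_logtpm(matrix.counts, matrix.lengths)
        selected, _ = select_phenotype_genes(lt, matrix.annotations)
        planted = truth["gene_sets"]["oxphos"]
        p = binomial_enrichment(
            len(selected & planted), len(planted), len(selected), lt.shape[0]
        )
        assert p < 0.05

    def test_too_few_samples_rejected(self):
        ann, _ = self._design(n=3)
        lt = pd.DataFrame(np.ones((2, 3)), columns=ann.index)
        with pytest.raises(InputError):
            select_phenotype_genes(lt, ann)


class TestBinomialEnrichment:
    def test_oxphos_worked_example(self):
        assert binomial_enrichment(17, 94, 391, 4314) == pytest.approx(
            0.004, abs=5e-4
        )

    def test_tca_worked_example(self):
        assert binomial_enrichment(7, 27, 391, 4314) == pytest.approx(
            0.009, abs=5e-4
        )

    def test_zero_hits_give_probability_one(self):
        assert binomial_enrichment(0, 94, 391, 4314) == 1.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.integers(min_value=1, max_value=100),
        st.integers(min_value=1, max_value=500),
        st.integers(min_value=501, max_value=5000),
    )
    def test_matches_brute_force_point_mass_sum(self, n, K, N):
        k = min(n, max(0, n // 3))
        p = K / N
        brute = sum(
            math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
        )
        assert binomial_enrichment(k, n, K, N) == pytest.approx(brute, abs=1e-12)

    def test_bound_violations_rejected(self):
        with pytest.raises(InputError):
            binomial_enrichment(5, 4, 10, 100)
        with pytest.raises(InputError):
            binomial_enrichment(1, 4, 0, 100)


class TestHierarchicalCluster:
    def test_identical_samples_merge_at_height_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        lt = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=60)})
        Z, samples, _ = hierarchical_cluster(lt)
        first = Z[0]
        assert {samples[int(first[0])], samples[int(first[1])]} == {"a", "b"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_single_sample_is_singleton_tree(self):
        lt = pd.DataFrame({"a": np.arange(10.0)})
        Z, samples, labels = hierarchical_cluster(lt, n_clusters=1)
        assert Z.shape == (0, 4)
        assert samples == ["a"]
        assert list(labels) == [1]

    def test_two_group_fixture_recovered_exactly(self, expression_fixture):
        matrix, truth = expression_fixture
        lt = counts_to_logtpm(matrix.counts, matrix.lengths)
        genes = sorted(set().union(*truth["gene_sets"].values()))
        _, samples, labels = hierarchical_cluster(lt, genes=genes, n_clusters=2)
        by_label: dict[int, set[int]] = {}
        for s, l in zip(samples, labels):
            by_label.setdefault(int(l), set()).add(truth["groups"][s])
        assert all(len(v) == 1 for v in by_label.values())
        assert len(by_label) == 2

    def test_constant_profile_rejected(self):
        lt = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(InputError):
            hierarchical_cluster(lt)
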