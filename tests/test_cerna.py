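"""Hypergeometric overlap test, correlation screens, and pair scoring."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cernet import expression
from cernet.cerna import (
    HypergeomInput,
    InferenceParams,
    hypergeom_overlap_p,
    overrepresentation_test,
    pairs_to_frame,
    pearson_r,
    score_pairs,
    spearman_rho,
)


def enumerate_overlap_p(N, K, n, k):
    """Exhaustive oracle: fraction of size-n subsets of an N-universe sharing
    >= k elements with a fixed size-K subset."""
    if k == 0:
        return 1.0
    universe = range(N)
    k_set = set(range(K))
    hits = total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        hits += len(k_set & set(subset)) >= k
    return hits / total


class TestHypergeomOverlap:
    def test_upper_tail_at_zero_is_one(self):
        assert hypergeom_overlap_p(HypergeomInput(10, 4, 5, 0)) == 1.0

    def test_worked_values_against_enumeration(self):
        # N=10, K=4, n=5: all C(10,5)=252 subsets enumerated
        for k, expected in ((4, 6 / 252), (3, 66 / 252)):
            oracle = enumerate_overlap_p(10, 4, 5, k)
            assert oracle == pytest.approx(expected, rel=1e-12)
            assert hypergeom_overlap_p(HypergeomInput(10, 4, 5, k)) == pytest.approx(
                expected, rel=1e-10
            )

    def test_invalid_inputs_rejected(self):
        for N, K, n, k in ((10, 11, 5, 0), (10, 4, 5, 5), (10, 4, 11, 0), (-1, 0, 0, 0)):
            with pytest.raises(ValueError):
                HypergeomInput(N, K, n, k)

    def test_monotone_in_k(self):
        ps = [hypergeom_overlap_p(HypergeomInput(20, 8, 10, k)) for k in range(9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_symmetric_in_K_and_n(self):
        for K, n, k in ((3, 7, 2), (5, 5, 4), (2, 9, 1)):
            a = hypergeom_overlap_p(HypergeomInput(12, K, n, k))
            b = hypergeom_overlap_p(HypergeomInput(12, n, K, k))
            assert a == pytest.approx(b, rel=1e-12)


class TestCorrelations:
    def test_spearman_perfect_antimonotone(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_spearman_monotone_invariance(self):
        assert spearman_rho([1, 2, 3], [10, 100, 1000]) == pytest.approx(1.0)

    def test_spearman_ties_average_ranks(self):
        # hand ranks: x=[1, 2.5, 2.5, 4], y=[2.5, 2.5, 2.5... -> use distinct case
        x, y = [1, 2, 2, 4], [2, 3, 3, 1]
        rx, ry = [1, 2.5, 2.5, 4], [2, 3.5, 3.5, 1]
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_flagged_nan(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))
        assert math.isnan(pearson_r([2, 2, 2], [1, 2, 3]))

    def test_pearson_exact_linear(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_pearson_textbook_formula(self):
        x, y = [0.0, 1, 2, 3], [1.0, 1, 2, 4]
        n = 4
        num = n * np.dot(x, y) - sum(x) * sum(y)
        den = math.sqrt(n * np.dot(x, x) - sum(x) ** 2) * math.sqrt(
            n * np.dot(y, y) - sum(y) ** 2
        )
        assert pearson_r(x, y) == pytest.approx(num / den, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])


class TestInferenceParams:
    def test_strict_tighter_than_lenient(self):
        s, l = InferenceParams.strict(), InferenceParams.lenient()
        assert s.spearman_max <= l.spearman_max
        assert s.pearson_min >= l.pearson_min
        assert s.pair_p_max <= l.pair_p_max

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            InferenceParams(spearman_max=0.1)
        with pytest.raises(ValueError):
            InferenceParams(pearson_min=1.5)


def _run_score(ds, params=None, universe="all_de"):
    de = {}
    for name, m in (("mr", ds.mrna_counts), ("lnc", ds.lncrna_counts),
                    ("mi", ds.mirna_counts)):
        t = expression.filter_de(
            expression.de_test(expression.normalize(m)), m.class_label
        )
        de[name] = set(t.index[t["call"] != "not_de"].astype(str))
    from cernet.targets import predict_targets

    interactions = predict_targets(
        {k: v for k, v in ds.mirna_seqs.items() if k in de["mi"]},
        {
            k: v
            for k, v in {**ds.lncrna_seqs, **ds.mrna_seqs}.items()
            if k in de["lnc"] | de["mr"]
        },
    )
    return score_pairs(
        de["lnc"], de["mr"], de["mi"], interactions,
        expression.normalize(ds.lncrna_counts),
        expression.normalize(ds.mrna_counts),
        expression.normalize(ds.mirna_counts),
        params, universe=universe,
    )


class TestScorePairs:
    def test_planted_pairs_recovered(self, small_dataset):
        pairs = _run_score(small_dataset)
        passing = {(p.lncrna_id, p.mrna_id) for p in pairs if p.passed}
        truth = {(t.lncrna_id, t.mrna_id) for t in small_dataset.truth}
        assert len(truth & passing) / len(truth) >= 0.8

    def test_pairs_without_shared_mirna_never_scored(self, small_dataset):
        for p in _run_score(small_dataset):
            assert p.shared_mirnas

    def test_fdr_dominates_p(self, small_dataset):
        for p in _run_score(small_dataset):
            assert p.hypergeom_fdr >= p.hypergeom_p - 1e-15

    def test_strict_subset_of_lenient(self, small_dataset):
        lenient = {
            (p.lncrna_id, p.mrna_id)
            for p in _run_score(small_dataset, InferenceParams.lenient())
            if p.passed
        }
        strict = {
            (p.lncrna_id, p.mrna_id)
            for p in _run_score(small_dataset, InferenceParams.strict())
            if p.passed
        }
        assert strict <= lenient

    def test_missing_expression_named(self, small_dataset):
        ds = small_dataset
        lnc = expression.normalize(ds.lncrna_counts)
        dropped = lnc.values.drop(index=ds.truth[0].lncrna_id)
        import dataclasses

        lnc_broken = dataclasses.replace(lnc, values=dropped)
        with pytest.raises(KeyError, match=ds.truth[0].lncrna_id):
            de_lnc = {t.lncrna_id for t in ds.truth}
            de_mr = {t.mrna_id for t in ds.truth}
            de_mi = {t.mirna_id for t in ds.truth}
            from cernet.targets import predict_targets

            interactions = predict_targets(
                {k: ds.mirna_seqs[k] for k in de_mi},
                {k: {**ds.lncrna_seqs, **ds.mrna_seqs}[k] for k in de_lnc | de_mr},
            )
            score_pairs(
                de_lnc, de_mr, de_mi, interactions,
                lnc_broken,
                expression.normalize(ds.mrna_counts),
                expression.normalize(ds.mirna_counts),
            )

    def test_empty_interactions_warn_empty(self, small_dataset):
        ds = small_dataset
        with pytest.warns(UserWarning):
            out = score_pairs(
                {"LNC_00001"}, {"MR_00001"}, {"miR_00001"}, [],
                expression.normalize(ds.lncrna_counts),
                expression.normalize(ds.mrna_counts),
                expression.normalize(ds.mirna_counts),
            )
        assert out == []

    def test_frame_columns(self, small_dataset):
        df = pairs_to_frame(_run_score(small_dataset))
        assert {"lncrna_id", "mrna_id", "k", "K", "n", "N", "hypergeom_p",
                "pearson_r", "passed"} <= set(df.columns)
        assert (df["k"] <= df[["K", "n"]].min(axis=1)).all()


class TestOverrepresentation:
    def test_exact_term_recovery_vs_enumeration(self):
        universe = {f"g{i}" for i in range(20)}
        term_genes = {f"g{i}" for i in range(10)}
        gene_set = set(term_genes)
        out = overrepresentation_test(gene_set, {"T": term_genes}, universe)
        expected = enumerate_overlap_p(20, 10, 10, 10)
        assert out.loc["T", "p_value"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1 / math.comb(20, 10) * 1, rel=1e-12)

    def test_disjoint_term_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        out = overrepresentation_test(
            {"g0", "g1"}, {"T": {"g8", "g9"}, "U": {"g0"}}, universe
        )
        assert out.loc["T", "p_value"] == 1.0
        assert out.loc["U", "p_value"] < 1.0

    def test_gene_set_equal_universe_degenerate(self):
        universe = {f"g{i}" for i in range(6)}
        out = overrepresentation_test(universe, {"T": {"g0", "g1"}}, universe)
        assert out.loc["T", "p_value"] == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation_test(set(), {"T": set()}, set())
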