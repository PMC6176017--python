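"""Hypergeometric ORA, BH-FDR, PSI and the Y-scrambling null."""
import itertools
import math
import re
import warnings

import numpy as np
import pandas as pd
import pytest

import httimpute as h
from httimpute.enrichment import EnrichmentResult


def toy_ontology(category_sizes, background, parent_edges=None, offset=0):
    """Disjoint categories carved out of the background in order."""
    cats = {}
    genes = sorted(background)
    pos = offset
    for i, size in enumerate(category_sizes):
        cid = f"C{i}"
        cats[cid] = h.GeneSet(cid, f"category {i}", frozenset(genes[pos : pos + size]))
        pos += size
    return h.Ontology(cats, parent_edges)


class TestEnrich:
    def test_exact_full_hit_probability(self):
        background = [f"g{i}" for i in range(20)]
        ont = toy_ontology([5], background)
        query = sorted(ont.categories["C0"].members)
        res = h.enrich(query, ont, background, h.EnrichmentConfig())
        p = res.table.loc["C0", "p"]
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    @pytest.mark.parametrize("M,K,n", [(10, 4, 5), (12, 5, 6), (9, 3, 3)])
    def test_p_matches_brute_force_enumeration(self, M, K, n):
        # exact oracle: fraction of all C(M, n) queries with >= Q hits
        background = [f"g{i:02d}" for i in range(M)]
        category = set(background[:K])
        ont = toy_ontology([K], background)
        for Q in range(0, min(K, n) + 1):
            total = hits = 0
            for query in itertools.combinations(background, n):
                total += 1
                if len(category.intersection(query)) >= Q:
                    hits += 1
            # pick any query achieving exactly Q hits to score
            query = background[:Q] + background[K : K + (n - Q)]
            res = h.enrich(query, ont, background, h.EnrichmentConfig())
            assert res.table.loc["C0", "p"] == pytest.approx(hits / total, rel=1e-9)

    def test_min_query_elements_gate(self):
        # Q=4 with arbitrarily small q is still not significant
        background = [f"g{i}" for i in range(200)]
        ont = toy_ontology([4], background)
        query = sorted(ont.categories["C0"].members)
        res = h.enrich(query, ont, background, h.EnrichmentConfig(min_query_elements=5))
        row = res.table.loc["C0"]
        assert row["q"] < 0.005 and row["query_elements"] == 4
        assert not row["significant"]

    def test_bh_adjustment_properties(self):
        rng = np.random.default_rng(0)
        background = [f"g{i}" for i in range(300)]
        ont = toy_ontology([10] * 20, background)
        query = list(rng.choice(background, size=40, replace=False))
        res = h.enrich(query, ont, background)
        t = res.table.sort_values("p")
        assert (t["q"].to_numpy() >= t["p"].to_numpy() - 1e-12).all()
        assert (np.diff(t["q"].to_numpy()) >= -1e-12).all()

    def test_null_calibration(self):
        # under a uniform random query, ~5% of categories reach p < 0.05
        rng = np.random.default_rng(1)
        background = [f"g{i}" for i in range(1000)]
        ont = toy_ontology([20] * 50, background)
        fractions = []
        for _ in range(30):
            query = list(rng.choice(background, size=100, replace=False))
            res = h.enrich(query, ont, background)
            fractions.append(float((res.table["p"] < 0.05).mean()))
        mean_frac = float(np.mean(fractions))
        assert 0.01 <= mean_frac <= 0.09  # discrete p-values are conservative

    def test_empty_query_rejected(self):
        background = ["a", "b"]
        ont = toy_ontology([2], background)
        with pytest.raises(ValueError, match="query"):
            h.enrich([], ont, background)

    def test_query_outside_background_rejected(self):
        background = ["a", "b"]
        ont = toy_ontology([2], background)
        with pytest.raises(ValueError, match="outside"):
            h.enrich(["z"], ont, background)


def manual_result(sig_q, nonsig_q=(), key="K", background=frozenset({"x"})):
    """Hand-built enrichment result with given query-element counts."""
    rows = []
    for i, q in enumerate(sig_q):
        rows.append((f"S{i}", f"S{i}", q + 1, q, 1e-6, 1e-5, True))
    for i, q in enumerate(nonsig_q):
        rows.append((f"N{i}", f"N{i}", q + 1, q, 0.5, 0.8, False))
    table = pd.DataFrame(
        rows,
        columns=["category_id", "name", "category_size", "query_elements",
                 "p", "q", "significant"],
    ).set_index("category_id")
    return EnrichmentResult(table, 100, 20, key, background)


class TestComputePSI:
    def test_identical_results_give_one(self):
        res = manual_result([10, 5, 3])
        psi = h.compute_psi(res, res)
        assert psi.psi == 1.0
        assert psi.n_common == psi.n_actual == 3

    def test_no_common_pathways_zero(self):
        actual = manual_result([10, 5])
        predicted = manual_result([], nonsig_q=[10, 5])
        psi = h.compute_psi(actual, predicted)
        assert psi.psi == 0.0 and psi.n_common == 0 and psi.delta == 0.0

    def test_hand_worked_example(self):
        # actual significant Q = {10, 5, 3, 2}; the first two are common:
        # PSI = mean(2/4, (10+5)/(10+5+3+2)) = mean(0.5, 0.75) = 0.625
        actual = manual_result([10, 5, 3, 2])
        pred_table = actual.table.copy()
        pred_table.loc[["S2", "S3"], "significant"] = False
        predicted = EnrichmentResult(pred_table, 100, 20, "K", frozenset({"x"}))
        psi = h.compute_psi(actual, predicted)
        assert psi.psi == pytest.approx(0.625)
        assert psi.delta == pytest.approx(0.75)
        assert psi.common_pathway_ids == ["S0", "S1"]

    def test_zero_actual_significant_rejected(self):
        empty = manual_result([], nonsig_q=[3])
        with pytest.raises(ValueError, match="undefined"):
            h.compute_psi(empty, empty)

    def test_mismatched_ontology_rejected(self):
        a = manual_result([5], key="K1")
        b = manual_result([5], key="K2")
        with pytest.raises(ValueError, match="different ontologies"):
            h.compute_psi(a, b)

    def test_monotone_in_common_set(self):
        # promoting one more actual pathway into the common set never lowers PSI
        actual = manual_result([10, 5, 3, 2])
        previous = -1.0
        for n_common in range(0, 5):
            pred_table = actual.table.copy()
            pred_table["significant"] = [i < n_common for i in range(4)]
            predicted = EnrichmentResult(pred_table, 100, 20, "K", frozenset({"x"}))
            psi = h.compute_psi(actual, predicted)
            assert psi.psi >= previous
            previous = psi.psi

    def test_predicted_q_convention_flag(self):
        actual = manual_result([10, 5])
        pred_table = actual.table.copy()
        pred_table["query_elements"] = [20, 10]
        predicted = EnrichmentResult(pred_table, 100, 20, "K", frozenset({"x"}))
        bounded = h.compute_psi(actual, predicted, q_source="actual")
        unbounded = h.compute_psi(actual, predicted, q_source="predicted")
        assert bounded.psi == 1.0
        assert unbounded.delta == pytest.approx(2.0)


class TestPSIFromPredictions:
    def test_perfect_prediction_gives_one_everywhere(self, small_sim):
        matrix, ontology, truth, cfg = small_sim
        cat = h.categorize(matrix)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = h.psi_from_predictions(cat, cat, ontology)
        valid = summary.table["psi"].dropna()
        assert len(valid) > 0
        assert (valid == 1.0).all()

    def test_shuffled_prediction_scores_lower(self, small_sim):
        matrix, ontology, truth, cfg = small_sim
        cat = h.categorize(matrix)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cat.n_samples)
        shuffled = h.CategorizedMatrix(
            pd.DataFrame(
                cat.classes.to_numpy()[:, perm],
                index=cat.probe_ids,
                columns=cat.sample_ids,
            )
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            honest = h.psi_from_predictions(cat, cat, ontology).mean_psi
            scrambled = h.psi_from_predictions(cat, shuffled, ontology).mean_psi
        assert scrambled < honest

    def test_mismatched_samples_rejected(self, small_sim):
        matrix, ontology, _, _ = small_sim
        cat = h.categorize(matrix)
        other = cat.subset_samples(cat.sample_ids[:-1])
        with pytest.raises(ValueError, match="samples"):
            h.psi_from_predictions(cat, other, ontology)


@pytest.fixture(scope="module")
def fitted(small_sim):
    matrix, ontology, truth, cfg = small_sim
    cat = h.categorize(matrix)
    train = cat.subset_samples(cat.sample_ids[:60])
    test = cat.subset_samples(cat.sample_ids[60:])
    surro = h.ProbeSet(
        "per-pathway",
        frozenset(p for pw in truth.membership.values() for p in pw[:2]),
    )
    model = h.train_consensus(train, surro, h.ConsensusConfig(mode="multioutput", seed=0))
    return model, test, ontology


class TestYScramble:
    def test_identity_permutation_matches_unscrambled(self, fitted):
        model, test, ontology = fitted
        sub = test.subset_probes(model.surrogates + model.targets)
        identity = [np.arange(test.n_samples)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = h.y_scramble(sub, model, ontology, permutations=identity)
            pred = h.predict_consensus(model, sub.subset_probes(model.surrogates))
            full = h.assemble_full_profile(
                sub.subset_probes(model.surrogates), pred.classes
            )
            honest = h.psi_from_predictions(sub, full, ontology).mean_psi
        assert null.null_means[0] == pytest.approx(honest)

    def test_scrambled_mean_below_unscrambled(self, fitted):
        model, test, ontology = fitted
        sub = test.subset_probes(model.surrogates + model.targets)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = h.y_scramble(sub, model, ontology, n_permutations=4, seed=1)
            pred = h.predict_consensus(model, sub.subset_probes(model.surrogates))
            full = h.assemble_full_profile(
                sub.subset_probes(model.surrogates), pred.classes
            )
            honest = h.psi_from_predictions(sub, full, ontology).mean_psi
        assert null.null_mean < honest


class TestExportDAG:
    def make_result_and_ontology(self, significant):
        background = [f"g{i}" for i in range(30)]
        edges = (("C0", "C1"), ("C1", "C2"))
        ont = toy_ontology([5, 5, 5], background, parent_edges=edges)
        query = sorted(ont.categories["C0"].members) if significant else background[20:25]
        cfg = h.EnrichmentConfig(fdr_threshold=0.05, min_query_elements=3)
        res = h.enrich(query, ont, background, cfg)
        return res, ont

    def test_no_significant_categories_empty_graph(self):
        res, ont = self.make_result_and_ontology(significant=False)
        dot = h.export_dag(res, ont)
        assert "->" not in dot and "[" not in dot

    def test_leaf_with_ancestors_forms_path(self):
        res, ont = self.make_result_and_ontology(significant=True)
        dot = h.export_dag(res, ont)
        assert dot.count("->") == 2
        assert '"C0" -> "C1"' in dot and '"C1" -> "C2"' in dot

    def test_attributes_round_trip(self, tmp_path):
        res, ont = self.make_result_and_ontology(significant=True)
        path = tmp_path / "dag.dot"
        h.export_dag(res, ont, path)
        text = path.read_text()
        attrs = {}
        for m in re.finditer(r'"(C\d)" \[([^\]]*)\];', text):
            node, blob = m.groups()
            attrs[node] = dict(re.findall(r'(\w+)="([^"]*)"', blob))
        row = res.table.loc["C0"]
        assert float(attrs["C0"]["neglog10_q"]) == pytest.approx(
            -np.log10(row["q"]), rel=1e-5
        )
        assert int(attrs["C0"]["query_elements"]) == int(row["query_elements"])
        assert attrs["C0"]["significant"] == "true"

    def test_missing_parent_edges_rejected(self):
        background = [f"g{i}" for i in range(10)]
        ont = toy_ontology([5], background)
        res = h.enrich(background[:5], ont, background)
        with pytest.raises(ValueError, match="parent_edges"):
            h.export_dag(res, ont)
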