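import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import oracle_auroc, oracle_fisher_greater, oracle_mwu_exact
from phytoscreen.evaluation import (
    LiteratureIndex,
    accuracy,
    auroc,
    cooccurrence,
    fisher_exact,
    jaccard,
    literature_report,
    make_kfold,
    make_split,
    mann_whitney,
    ranked_sets,
    summarize,
)
from phytoscreen.pcnn_model import PredictionTable


class TestSplits:
    def test_ten_ids_split_622(self):
        plan = make_split([f"i{k}" for k in range(10)], (6, 2, 2), seed=0)
        assert (len(plan.train), len(plan.validation), len(plan.test)) == (6, 2, 2)

    def test_partition_covers_all_ids(self):
        ids = [f"i{k}" for k in range(37)]
        plan = make_split(ids, seed=1)
        assert sorted(plan.train + plan.validation + plan.test) == sorted(ids)

    def test_stratification_preserves_prevalence(self):
        ids = [f"i{k}" for k in range(100)]
        labels = [1] * 20 + [0] * 80
        plan = make_split(ids, seed=2, stratify_by=labels)
        lab = dict(zip(ids, labels))
        assert sum(lab[i] for i in plan.train) == 12
        assert sum(lab[i] for i in plan.validation) == 4
        assert sum(lab[i] for i in plan.test) == 4

    def test_kfold_sizes_and_disjointness(self):
        ids = [f"i{k}" for k in range(100)]
        plan = make_kfold(ids, k=10, seed=3)
        assert all(len(f) == 10 for f in plan.folds)
        assert sorted(i for f in plan.folds for i in f) == sorted(ids)

    def test_deterministic_under_seed(self):
        ids = [f"i{k}" for k in range(20)]
        assert make_split(ids, seed=5).train == make_split(ids, seed=5).train


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=4000)
        y = rng.integers(0, 2, size=4000)
        assert abs(auroc(s, y) - 0.5) < 0.03

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_pair_counting_oracle_with_ties(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(6, 30))
        s = rng.integers(0, 5, size=n).astype(float)  # heavy ties
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=max(1, n // 3), replace=False)] = 1
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        assert auroc(s, y) == pytest.approx(oracle_auroc(s, y))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=60)
        y = (rng.random(60) < 0.4).astype(int)
        assert auroc(s, y) == pytest.approx(auroc(np.exp(s), y))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])

    def test_agrees_with_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        s = rng.normal(size=200)
        y = (rng.random(200) < 0.3).astype(int)
        assert auroc(s, y) == pytest.approx(roc_auc_score(y, s))


class TestAccuracySummarize:
    def test_accuracy_extremes_and_oracle(self):
        assert accuracy([0.9, 0.1], [1, 0]) == 1.0
        assert accuracy([0.1, 0.9], [1, 0]) == 0.0
        rng = np.random.default_rng(1)
        s = rng.random(50)
        y = rng.integers(0, 2, size=50)
        manual = np.mean((s >= 0.5).astype(int) == y)
        assert accuracy(s, y) == pytest.approx(manual)

    def test_summarize_constant_list(self):
        assert summarize([0.5, 0.5, 0.5]) == (0.5, 0.0)

    def test_summarize_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=30)
        mean, sd = summarize(v)
        assert mean == pytest.approx(v.sum() / 30)
        assert sd == pytest.approx(np.sqrt(((v - v.mean()) ** 2).sum() / 29))


def _prediction_table(n_compounds=10, n_diseases=2, seed=0):
    rng = np.random.default_rng(seed)
    return PredictionTable(
        compound_ids=[f"c{i}" for i in range(n_compounds)],
        disease_ids=[f"d{j}" for j in range(n_diseases)],
        scores=rng.random((n_compounds, n_diseases)),
    )


class TestRankedSets:
    def test_sizes_and_disjointness(self):
        table = _prediction_table()
        high, low, rand = ranked_sets(table, fraction=0.1, seed=0)
        assert len(high) == len(low) == len(rand) == 2
        assert not set(high) & set(low)

    def test_ranking_property(self):
        table = _prediction_table(seed=3)
        high, low, _ = ranked_sets(table, fraction=0.2, seed=0)
        score = {(c, d): s for c, d, s in table.pairs()}
        assert min(score[p] for p in high) >= max(score[p] for p in low)


class TestLiteratureIndex:
    def docs(self):
        return {
            "d1": "Curcumin reduces inflammation in arthritis models",
            "d2": "Curcumin pharmacokinetics in healthy volunteers",
            "d3": "Arthritis prevalence and treatment",
            "d4": "Unrelated plant metabolite survey",
        }

    def test_cooccurrence_counts_documents(self):
        idx = LiteratureIndex(self.docs())
        assert cooccurrence(idx, ("curcumin", "arthritis")) == 1
        assert cooccurrence(idx, ("curcumin", "volcano")) == 0

    def test_multiword_terms_match_contiguously(self):
        idx = LiteratureIndex({"d1": "alpha tocopherol protects membranes",
                               "d2": "tocopherol alpha ordering differs"})
        assert len(idx.postings("alpha tocopherol")) == 1

    def test_empty_index(self):
        idx = LiteratureIndex({})
        assert cooccurrence(idx, ("a", "b")) == 0

    def test_jaccard_identical_and_disjoint(self):
        idx = LiteratureIndex(self.docs())
        assert jaccard(idx, ("curcumin", "curcumin")) == 1.0
        assert jaccard(idx, ("volunteers", "prevalence")) == 0.0

    def test_jaccard_matches_set_arithmetic(self):
        idx = LiteratureIndex(self.docs())
        a = idx.postings("curcumin")
        b = idx.postings("arthritis")
        assert jaccard(idx, ("curcumin", "arthritis")) == len(a & b) / len(a | b)


class TestFisher:
    def test_zero_cooccurrence_no_enrichment(self):
        idx = LiteratureIndex({"d1": "aaa", "d2": "bbb", "d3": "ccc"})
        assert fisher_exact(idx, ("aaa", "bbb")) >= 0.5

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_hypergeometric_tail_oracle(self, trial):
        rng = np.random.default_rng(trial)
        both, a_only, b_only, neither = (int(x) for x in rng.integers(0, 12, 4))
        if both + a_only + b_only + neither == 0:
            neither = 1
        docs = {}
        k = 0
        for _ in range(both):
            docs[f"d{k}"] = "terma termb"; k += 1
        for _ in range(a_only):
            docs[f"d{k}"] = "terma filler"; k += 1
        for _ in range(b_only):
            docs[f"d{k}"] = "termb filler"; k += 1
        for _ in range(neither):
            docs[f"d{k}"] = "nothing here"; k += 1
        idx = LiteratureIndex(docs)
        expected = oracle_fisher_greater(both, a_only, b_only, neither)
        assert fisher_exact(idx, ("terma", "termb")) == pytest.approx(
            expected, abs=1e-10
        )

    def test_more_background_strengthens_association(self):
        ps = []
        for neither in (5, 20, 80):
            docs = {f"b{k}": "x y" for k in range(4)}
            docs.update({f"a{k}": "x only" for k in range(3)})
            docs.update({f"c{k}": "y only" for k in range(3)})
            docs.update({f"n{k}": "zz" for k in range(neither)})
            ps.append(fisher_exact(LiteratureIndex(docs), ("x", "y")))
        assert ps[0] >= ps[1] >= ps[2]


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_complete_separation_exact(self):
        _, p = mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252)

    @pytest.mark.parametrize("trial", range(10))
    def test_exact_branch_matches_permutation_oracle(self, trial):
        rng = np.random.default_rng(trial)
        x = rng.integers(0, 6, size=int(rng.integers(2, 8))).astype(float)
        y = rng.integers(0, 6, size=int(rng.integers(2, 8))).astype(float)
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(oracle_mwu_exact(x, y))

    def test_u_statistic_mirror_identity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = rng.normal(size=30)
        u_x, _ = mann_whitney(x, y)
        u_y, _ = mann_whitney(y, x)
        assert u_x + u_y == pytest.approx(25 * 30)

    def test_large_sample_asymptotic_branch(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = rng.normal(loc=1.0, size=40)
        _, p = mann_whitney(x, y)
        assert p < 0.01


class TestLiteratureReport:
    def test_planted_high_set_has_more_evidence(self):
        rng = np.random.default_rng(0)
        compounds = [f"c{i}" for i in range(10)]
        diseases = [f"d{j}" for j in range(3)]
        scores = rng.random((10, 3))
        table = PredictionTable(compounds, diseases, scores)
        high, low, _ = ranked_sets(table, fraction=0.1, seed=0)
        docs = {}
        k = 0
        for c, d in high:  # plant strong co-reporting for the top pairs
            for _ in range(6):
                docs[f"h{k}"] = f"{c} studied in {d}"; k += 1
        for c in compounds:
            for _ in range(2):
                docs[f"f{k}"] = f"{c} metabolism survey"; k += 1
        for d in diseases:
            docs[f"g{k}"] = f"epidemiology of {d}"; k += 1
        report = literature_report(table, LiteratureIndex(docs), seed=0)
        assert report["high"]["cooccurrence_mean"] > report["random"]["cooccurrence_mean"]
        assert report["high"]["cooccurrence_mean"] > report["low"]["cooccurrence_mean"]
        assert report["high"]["jaccard_mean"] > report["low"]["jaccard_mean"]
        assert "high_vs_low" in report["mann_whitney"]

    def test_empty_corpus_warns_and_zeroes(self):
        table = _prediction_table()
        with pytest.warns(UserWarning, match="empty corpus"):
            report = literature_report(table, LiteratureIndex({}), seed=0)
        assert report["high"]["cooccurrence_mean"] == 0.0
        assert report["high"]["n_significant"] == 0
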