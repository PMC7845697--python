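"""Splitting, ranking metrics, and the literature-statistics validation suite.

The split helpers produce the 6:2:2 train/validation/test plan and k-fold
assignments (stratified by default).  Metrics are rank-based AUROC (midrank
ties) and thresholded accuracy.  The literature suite indexes a corpus of
abstracts and compares high-, low- and randomly-ranked prediction pairs by
term co-occurrence, Jaccard index, Fisher's exact enrichment and
Mann-Whitney U contrasts.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .knowledge_embedding import preprocess
from .pcnn_model import PredictionTable

__all__ = [
    "SplitPlan",
    "LiteratureIndex",
    "make_split",
    "make_kfold",
    "auroc",
    "accuracy",
    "summarize",
    "ranked_sets",
    "cooccurrence",
    "jaccard",
    "fisher_exact",
    "fisher_enrichment_p",
    "mann_whitney",
    "literature_report",
]


@dataclass
class SplitPlan:
    """Disjoint train/validation/test id lists (or k-fold assignments)."""

    train: list[str]
    validation: list[str]
    test: list[str]
    folds: list[list[str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [self.train, self.validation, self.test]
        flat = [i for p in parts for i in p]
        if len(flat) != len(set(flat)):
            raise ValueError("split parts are not disjoint")


def _allocate(n: int, ratios: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items into len(ratios) parts."""
    total = sum(ratios)
    exact = [n * r / total for r in ratios]
    sizes = [math.floor(e) for e in exact]
    remainder = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: exact[i] - sizes[i], reverse=True)
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def make_split(
    ids: Sequence[str],
    ratios: Sequence[float] = (6, 2, 2),
    seed: int = 0,
    stratify_by: Sequence | None = None,
) -> SplitPlan:
    """Random train/validation/test split in the given ratio (default 6:2:2).

    With ``stratify_by`` each stratum is apportioned separately, so label
    prevalence is preserved across the three parts.  Deterministic under seed.
    """
    if len(ratios) != 3:
        raise ValueError("need three ratio terms (train/validation/test)")
    rng = np.random.default_rng(seed)
    strata: dict = defaultdict(list)
    if stratify_by is None:
        strata[None] = list(ids)
    else:
        if len(stratify_by) != len(ids):
            raise ValueError("stratify_by must align with ids")
        for i, s in zip(ids, stratify_by):
            strata[s].append(i)
    parts: list[list[str]] = [[], [], []]
    for key in sorted(strata, key=str):
        members = list(strata[key])
        rng.shuffle(members)
        sizes = _allocate(len(members), ratios)
        start = 0
        for p, size in enumerate(sizes):
            parts[p].extend(members[start : start + size])
            start += size
    return SplitPlan(train=parts[0], validation=parts[1], test=parts[2], seed=seed)


def make_kfold(
    ids: Sequence[str],
    k: int = 10,
    seed: int = 0,
    stratify_by: Sequence | None = None,
) -> SplitPlan:
    """k disjoint folds covering all ids (stratified when labels are given)."""
    if k < 2 or k > len(ids):
        raise ValueError("k must be in [2, len(ids)]")
    rng = np.random.default_rng(seed)
    strata: dict = defaultdict(list)
    if stratify_by is None:
        strata[None] = list(ids)
    else:
        for i, s in zip(ids, stratify_by):
            strata[s].append(i)
    folds: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for key in sorted(strata, key=str):
        members = list(strata[key])
        rng.shuffle(members)
        for j, member in enumerate(members):
            folds[(offset + j) % k].append(member)
        offset += len(members)
    return SplitPlan(train=[], validation=[], test=[], folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# metrics


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUROC (Mann-Whitney formulation with midranks for ties)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)  # midranks
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def accuracy(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> float:
    """Fraction of correct hard calls at the threshold."""
    y = np.asarray(labels)
    calls = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return float((calls == y).mean())


def summarize(values: Sequence[float]) -> tuple[float, float]:
    """(mean, sample standard deviation), the 'mean ± SD' of report tables."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd


# ---------------------------------------------------------------------------
# ranked prediction sets


def ranked_sets(
    predictions: PredictionTable, fraction: float = 0.1, seed: int = 0
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[tuple[str, str]]]:
    """(high, low, random) prediction-pair sets over all score cells.

    Pairs are ranked by score (ties broken by compound then disease id); the
    top and bottom ⌈fraction·N⌉ pairs form the high and low sets, and a
    size-matched random set is drawn without replacement with the fixed seed.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    cells = sorted(predictions.pairs(), key=lambda t: (-t[2], t[0], t[1]))
    n = len(cells)
    size = math.ceil(fraction * n)
    high = [(c, d) for c, d, _ in cells[:size]]
    low = [(c, d) for c, d, _ in sorted(cells, key=lambda t: (t[2], t[0], t[1]))[:size]]
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=size, replace=False)
    random_set = [(cells[i][0], cells[i][1]) for i in sorted(idx)]
    return high, low, random_set


# ---------------------------------------------------------------------------
# literature index and statistics


class LiteratureIndex:
    """Token-sequence index over a corpus of documents.

    A term (possibly multi-word) matches a document when its preprocessed
    token sequence occurs contiguously in the document's token list.
    """

    def __init__(self, documents: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = documents.items() if isinstance(documents, Mapping) else documents
        self.doc_tokens: dict[str, list[str]] = {
            doc_id: preprocess(text) for doc_id, text in items
        }
        self._postings: dict[tuple[str, ...], set[str]] = {}

    def __len__(self) -> int:
        return len(self.doc_tokens)

    @staticmethod
    def _contains(tokens: list[str], needle: tuple[str, ...]) -> bool:
        k = len(needle)
        if k == 0:
            return False
        return any(tuple(tokens[i : i + k]) == needle for i in range(len(tokens) - k + 1))

    def postings(self, term: str) -> set[str]:
        """Ids of documents containing the term."""
        key = tuple(preprocess(term))
        if key not in self._postings:
            self._postings[key] = {
                doc_id
                for doc_id, tokens in self.doc_tokens.items()
                if self._contains(tokens, key)
            }
        return self._postings[key]


def cooccurrence(index: LiteratureIndex, pair: tuple[str, str]) -> int:
    """Number of documents containing both terms (n_c)."""
    a, b = pair
    return len(index.postings(a) & index.postings(b))


def jaccard(index: LiteratureIndex, pair: tuple[str, str]) -> float:
    """|A∩B| / |A∪B| over the two posting sets (0 when the union is empty)."""
    a, b = pair
    pa, pb = index.postings(a), index.postings(b)
    union = pa | pb
    return len(pa & pb) / len(union) if union else 0.0


def fisher_enrichment_p(both, a_only, b_only, neither):
    """One-sided (enrichment) Fisher's exact p-value from 2×2 table counts.

    p = P(X ≥ both) for X hypergeometric with the table's margins — the upper
    tail of the co-occurrence count.  Accepts scalars or aligned arrays.
    """
    both = np.asarray(both)
    n = both + a_only + b_only + neither
    if np.any(n <= 0):
        raise ValueError("table total must be positive")
    with_a = both + a_only
    with_b = both + b_only
    p = stats.hypergeom.sf(both - 1, n, with_a, with_b)
    return float(p) if p.ndim == 0 else p


def fisher_exact(index: LiteratureIndex, pair: tuple[str, str]) -> float:
    """One-sided (enrichment) Fisher's exact p-value for term co-reporting.

    The 2×2 table counts documents by containment of each term; the p-value
    is the upper hypergeometric tail of the co-occurrence count.
    """
    n = len(index)
    if n == 0:
        raise ValueError("empty literature index")
    a, b = pair
    pa, pb = index.postings(a), index.postings(b)
    both = len(pa & pb)
    a_only = len(pa) - both
    b_only = len(pb) - both
    neither = n - both - a_only - b_only
    return fisher_enrichment_p(both, a_only, b_only, neither)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: (U statistic, p-value).

    Small samples (both ≤ 8) use exact enumeration over all label
    assignments, which handles ties and gives p = 1 for identical samples;
    larger samples use the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_x = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    if nx <= 8 and ny <= 8:
        pooled = np.concatenate([x, y])
        pooled_ranks = stats.rankdata(pooled)
        centre = nx * ny / 2.0
        observed = abs(u_x - centre)
        count = 0
        total = 0
        for subset in combinations(range(nx + ny), nx):
            u = pooled_ranks[list(subset)].sum() - nx * (nx + 1) / 2.0
            total += 1
            if abs(u - centre) >= observed - 1e-12:
                count += 1
        return float(u_x), count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u_x), float(res.pvalue)


def literature_report(
    predictions: PredictionTable,
    index: LiteratureIndex,
    names: Mapping[str, str] | None = None,
    fraction: float = 0.1,
    seed: int = 0,
    fisher_threshold: float = 0.001,
) -> dict:
    """Literature-evidence comparison of high/low/random prediction sets.

    For each set: mean ± SD co-occurrence (n_c), mean Jaccard index, and the
    count of pairs with Fisher enrichment p below the threshold (n_f);
    pairwise Mann-Whitney p-values contrast the three sets on each per-pair
    statistic.  ``names`` maps compound/disease ids to the literature terms
    searched (defaults to the ids themselves).
    """
    names = dict(names or {})
    high, low, random_set = ranked_sets(predictions, fraction=fraction, seed=seed)
    sets = {"high": high, "low": low, "random": random_set}
    report: dict = {"set_size": len(high), "n_documents": len(index)}
    per_pair: dict[str, dict[str, list[float]]] = {}
    for label, pairs in sets.items():
        nc, ji, fisher_p = [], [], []
        for compound, disease in pairs:
            term_pair = (names.get(compound, compound), names.get(disease, disease))
            nc.append(cooccurrence(index, term_pair))
            ji.append(jaccard(index, term_pair))
            if len(index):
                fisher_p.append(fisher_exact(index, term_pair))
        if not len(index):
            warnings.warn("empty corpus: Fisher's exact test skipped")
        mean_nc, sd_nc = summarize(nc)
        report[label] = {
            "cooccurrence_mean": mean_nc,
            "cooccurrence_sd": sd_nc,
            "jaccard_mean": float(np.mean(ji)),
            "n_significant": int(sum(p < fisher_threshold for p in fisher_p)),
        }
        per_pair[label] = {"cooccurrence": nc, "jaccard": ji, "fisher_p": fisher_p}
    report["mann_whitney"] = {}
    for a, b in (("high", "low"), ("high", "random"), ("low", "random")):
        comp = {}
        for stat in ("cooccurrence", "jaccard", "fisher_p"):
            xa, xb = per_pair[a][stat], per_pair[b][stat]
            if xa and xb:
                comp[stat] = mann_whitney(xa, xb)[1]
        report["mann_whitney"][f"{a}_vs_{b}"] = comp
    return report
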