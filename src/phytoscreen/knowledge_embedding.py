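"""Latent-knowledge features: compound-name embeddings from a sub-word vector table.

A compound name is tokenized, each token looked up in a pre-built word-vector
table (word2vec text dialect); out-of-vocabulary tokens fall back to character
n-gram composition, the sub-word trick that lets rare chemical names such as
"alpha-isothiocyanatotoluene" borrow vectors from frequent fragments.  The
module also carries the ATC-group cosine-similarity evaluation of embedding
quality.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "VectorTable",
    "AtcCode",
    "GREEK_MAP",
    "preprocess",
    "char_ngrams",
    "compose_vector",
    "embed_names",
    "group_mean_cosine",
    "atc_similarity_profile",
    "read_vector_table",
    "write_vector_table",
]


def _build_greek_map() -> dict[str, str]:
    # alphabetic names for every Greek letter, lower and upper case, derived
    # from the Unicode character names (… SMALL/CAPITAL LETTER ALPHA → alpha)
    table = {}
    for cp in range(0x0391, 0x03CA):
        ch = chr(cp)
        try:
            name = unicodedata.name(ch)
        except ValueError:
            continue
        if "GREEK" in name and "LETTER" in name:
            table[ch] = name.split()[-1].lower()
    table["µ"] = "mu"  # micro sign
    return table


#: Greek letter → alphabetic name (α → alpha), applied before tokenization
GREEK_MAP = _build_greek_map()

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def preprocess(text: str) -> list[str]:
    """Lowercase, map Greek letters to names, split on punctuation.

    Intra-word hyphens are preserved so "alpha-tocopherol" stays one token.
    The function is idempotent over its own output.
    """
    text = text.lower()
    text = "".join(GREEK_MAP.get(ch, ch) for ch in text)
    return _TOKEN_RE.findall(text)


def char_ngrams(word: str, n_min: int = 3, n_max: int = 6) -> list[str]:
    """All character n-grams of the boundary-padded word ``<word>``.

    Returns a list (a multiset: repeated substrings appear repeatedly) of all
    substrings of lengths ``n_min..n_max`` of ``"<" + word + ">"``.
    """
    if not word:
        raise ValueError("empty word")
    if not 1 <= n_min <= n_max:
        raise ValueError("need 1 <= n_min <= n_max")
    padded = f"<{word}>"
    grams = []
    for n in range(n_min, n_max + 1):
        grams.extend(padded[i : i + n] for i in range(len(padded) - n + 1))
    return grams


@dataclass
class VectorTable:
    """Token → vector table with an optional n-gram fallback table."""

    dim: int
    entries: dict[str, np.ndarray] = field(default_factory=dict)
    ngram_entries: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for store in (self.entries, self.ngram_entries):
            for token, vec in store.items():
                vec = np.asarray(vec, dtype=float)
                if vec.shape != (self.dim,):
                    raise ValueError(
                        f"vector for {token!r} has length {vec.shape}, "
                        f"expected {self.dim}"
                    )
                store[token] = vec

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AtcCode:
    """A drug's 7-character ATC classification code.

    The five hierarchy levels are prefixes of lengths 1, 3, 4, 5 and 7
    (anatomical group → therapeutic → pharmacological → chemical subgroup →
    substance).
    """

    drug_id: str
    code: str

    _LEVEL_LEN = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}

    def prefix(self, level: int) -> str:
        if level not in self._LEVEL_LEN:
            raise ValueError("ATC level must be in 1..5")
        return self.code[: self._LEVEL_LEN[level]]


def _word_vector(word: str, table: VectorTable) -> np.ndarray | None:
    if word in table.entries:
        return table.entries[word]
    if table.ngram_entries:
        found = [
            table.ngram_entries[g]
            for g in char_ngrams(word)
            if g in table.ngram_entries
        ]
        if found:
            # mean, not sum: keeps the norm comparable to in-vocabulary tokens
            return np.mean(found, axis=0)
    return None


def compose_vector(name: str, table: VectorTable) -> np.ndarray:
    """Embed a free-text compound name.

    Each token resolves to its stored vector, or to the mean of its available
    character n-gram vectors when out of vocabulary; the name vector is the
    mean over resolvable tokens (so it is invariant to word order).  If
    nothing resolves, a zero vector is returned with a warning.
    """
    if not table.entries and not table.ngram_entries:
        raise ValueError("empty vector table")
    vectors = []
    for word in preprocess(name):
        vec = _word_vector(word, table)
        if vec is not None:
            vectors.append(vec)
    if not vectors:
        warnings.warn(f"no vector resolvable for name {name!r}; using zeros")
        return np.zeros(table.dim)
    return np.mean(vectors, axis=0)


def embed_names(
    names: Mapping[str, str], table: VectorTable
) -> tuple[list[str], np.ndarray]:
    """Embed a mapping id → name into a (ids, matrix) latent feature block."""
    ids = list(names)
    mat = np.vstack([compose_vector(names[i], table) for i in ids])
    return ids, mat


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


def group_mean_cosine(
    vectors: Mapping[str, np.ndarray], groups: Mapping[str, Iterable[str]]
) -> dict[str, float]:
    """Mean pairwise cosine similarity within each group.

    Zero vectors are excluded with a warning; groups left with fewer than two
    usable members are skipped with a warning.
    """
    out = {}
    for gname, members in groups.items():
        usable = []
        for m in members:
            v = vectors.get(m)
            if v is None:
                continue
            if np.linalg.norm(v) == 0:
                warnings.warn(f"zero vector for {m!r} excluded from group {gname!r}")
                continue
            usable.append(v)
        if len(usable) < 2:
            warnings.warn(f"group {gname!r} has <2 usable members; skipped")
            continue
        sims = [_cosine(u, v) for u, v in combinations(usable, 2)]
        out[gname] = float(np.mean(sims))
    return out


def atc_similarity_profile(
    vectors: Mapping[str, np.ndarray],
    atc_codes: Sequence[AtcCode],
    level: int,
    seed: int = 0,
) -> dict[str, float | int]:
    """Within-ATC-group vs size-matched random-group mean cosine at one level.

    Drugs sharing the ATC prefix of the given level form a group; the pooled
    mean over all within-group pairs is compared against groups of the same
    sizes drawn at random (fixed seed) from the same drug pool.
    """
    groups: dict[str, list[str]] = {}
    for code in atc_codes:
        if code.drug_id in vectors:
            groups.setdefault(code.prefix(level), []).append(code.drug_id)
    groups = {g: m for g, m in groups.items() if len(m) >= 2}
    if not groups:
        return {"level": level, "n_groups": 0}

    def pooled_mean(group_map: Mapping[str, Sequence[str]]) -> float:
        sims = []
        for members in group_map.values():
            for a, b in combinations(members, 2):
                sims.append(_cosine(vectors[a], vectors[b]))
        return float(np.mean(sims))

    rng = np.random.default_rng(seed)
    pool = sorted({c.drug_id for c in atc_codes if c.drug_id in vectors})
    random_groups = {}
    for gname, members in groups.items():
        random_groups[gname] = list(rng.choice(pool, size=len(members), replace=False))
    return {
        "level": level,
        "n_groups": len(groups),
        "same_group_mean": pooled_mean(groups),
        "random_group_mean": pooled_mean(random_groups),
    }


# ---------------------------------------------------------------------------
# word2vec text dialect I/O


def read_vector_table(path: str | Path) -> VectorTable:
    """Read a word2vec-text-format table; tokens prefixed ``NG:`` are n-grams."""
    entries: dict[str, np.ndarray] = {}
    ngrams: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("vector table header must be 'vocab_size dim'")
        n_vec, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"entry {parts[0]!r} has {len(parts) - 1} values, expected {dim}"
                )
            token = parts[0]
            vec = np.array(parts[1:], dtype=float)
            if token.startswith("NG:"):
                ngrams[token[3:]] = vec
            else:
                entries[token] = vec
    if len(entries) + len(ngrams) != n_vec:
        raise ValueError(
            f"header promises {n_vec} vectors, file has {len(entries) + len(ngrams)}"
        )
    return VectorTable(dim=dim, entries=entries, ngram_entries=ngrams)


def write_vector_table(table: VectorTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        total = len(table.entries) + len(table.ngram_entries)
        fh.write(f"{total} {table.dim}\n")
        for token in sorted(table.entries):
            vals = " ".join(repr(float(x)) for x in table.entries[token])
            fh.write(f"{token} {vals}\n")
        for token in sorted(table.ngram_entries):
            vals = " ".join(repr(float(x)) for x in table.ngram_entries[token])
            fh.write(f"NG:{token} {vals}\n")
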