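"""Word-overlap comprehension scoring.

A verbal-recall response is scored against its reference sentence with the
Ratcliff-Obershelp sequence-matching ratio on word tokens: recursively find
the longest common contiguous block, recurse on the flanks, and report
``2 * M / T`` where ``M`` is the total number of matched tokens and ``T`` the
total number of tokens in both sequences. The score is 1 for identical token
lists and 0 for disjoint vocabularies.
"""

from __future__ import annotations

import re

import pandas as pd

__all__ = ["tokenize", "sequence_similarity", "score_pairs"]

_WORD = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercased, punctuation-stripped, whitespace-split word tokens."""
    if not text:
        return []
    return _WORD.findall(text.lower())


def _longest_match(a, b, alo, ahi, blo, bhi):
    """Longest contiguous matching block of a[alo:ahi] vs b[blo:bhi].

    Ties are broken by earliest start in ``a``, then earliest start in ``b``
    (the first maximal block found while scanning ascending positions).
    """
    best_i, best_j, best_k = alo, blo, 0
    j2len: dict[int, int] = {}
    for i in range(alo, ahi):
        new: dict[int, int] = {}
        ai = a[i]
        for j in range(blo, bhi):
            if ai == b[j]:
                k = j2len.get(j - 1, 0) + 1
                new[j] = k
                if k > best_k:
                    best_i, best_j, best_k = i - k + 1, j - k + 1, k
        j2len = new
    return best_i, best_j, best_k


def _matched(a, b, alo, ahi, blo, bhi) -> int:
    i, j, k = _longest_match(a, b, alo, ahi, blo, bhi)
    if k == 0:
        return 0
    return (k
            + _matched(a, b, alo, i, blo, j)
            + _matched(a, b, i + k, ahi, j + k, bhi))


def sequence_similarity(ref: list, resp: list) -> float:
    """Ratcliff-Obershelp similarity ratio 2M/T between two token lists.

    No junk heuristics are applied; two empty sequences score 1.0.
    """
    total = len(ref) + len(resp)
    if total == 0:
        return 1.0
    m = _matched(ref, resp, 0, len(ref), 0, len(resp))
    return 2.0 * m / total


def score_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Score a table of (trial_id, reference, response) sentence pairs.

    Returns a copy with tokenized columns replaced by a ``score`` in [0, 1].
    """
    needed = {"trial_id", "reference", "response"}
    if not needed <= set(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(needed)}")
    scores = [
        sequence_similarity(tokenize(str(ref) if not pd.isna(ref) else ""),
                            tokenize(str(resp) if not pd.isna(resp) else ""))
        for ref, resp in zip(pairs["reference"], pairs["response"])
    ]
    out = pairs.copy()
    out["score"] = scores
    return out
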