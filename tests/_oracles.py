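"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and graph code:
the alignment oracle enumerates every monotone global alignment path and
scores it with the affine gap rule applied move by move; the closure oracle
is a naive fixed-point relaxation.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

GAP = "GAP"


@lru_cache(maxsize=None)
def alignment_paths(n1: int, n2: int) -> tuple[tuple[str, ...], ...]:
    """All monotone move strings from (0,0) to (n1,n2).

    Moves: 'D' consumes one element of each sequence, 'X' consumes only
    sequence 1 (gap in sequence 2), 'Y' consumes only sequence 2.
    """
    if n1 == 0 and n2 == 0:
        return ((),)
    out = []
    if n1 > 0 and n2 > 0:
        out += [p + ("D",) for p in alignment_paths(n1 - 1, n2 - 1)]
    if n1 > 0:
        out += [p + ("X",) for p in alignment_paths(n1 - 1, n2)]
    if n2 > 0:
        out += [p + ("Y",) for p in alignment_paths(n1, n2 - 1)]
    return tuple(out)


def column_score(a: str, b: str, weights: dict, params) -> float:
    """Substitution column score, restated independently: GAP columns take
    the fixed gap-element penalty; otherwise match/mismatch times both
    inverse-frequency weights."""
    if a == GAP or b == GAP:
        return params.gap_element_score
    base = params.match if a == b else params.mismatch
    return base * weights[a] * weights[b]


def score_path(path, e1, e2, weights, params) -> float:
    """Affine scoring of one alignment path: a gap run opens once and
    extends thereafter; switching gap direction opens a new run."""
    score = 0.0
    i = j = 0
    prev = None
    for mv in path:
        if mv == "D":
            score += column_score(e1[i], e2[j], weights, params)
            i += 1
            j += 1
        elif mv == "X":
            score += params.gap_extend if prev == "X" else params.gap_open
            i += 1
        else:
            score += params.gap_extend if prev == "Y" else params.gap_open
            j += 1
        prev = mv
    return score


def brute_force_align_score(e1, e2, weights, params) -> float:
    """Maximum score over an exhaustive enumeration of global alignments."""
    return max(
        score_path(p, e1, e2, weights, params)
        for p in alignment_paths(len(e1), len(e2))
    )


def brute_force_scores_batch(sub_matrices: np.ndarray, n1: int, n2: int,
                             gap_open: float, gap_extend: float) -> np.ndarray:
    """Brute-force optimal scores for many pairs of one shape at once.

    ``sub_matrices`` has shape (n_pairs, n1*n2): the flattened substitution
    matrix of each pair.  Returns the per-pair maximum over all global
    alignment paths.
    """
    paths = alignment_paths(n1, n2)
    D = np.zeros((len(paths), n1 * n2))
    gap_const = np.zeros(len(paths))
    for k, path in enumerate(paths):
        i = j = 0
        prev = None
        for mv in path:
            if mv == "D":
                D[k, i * n2 + j] = 1.0
                i += 1
                j += 1
            elif mv == "X":
                gap_const[k] += gap_extend if prev == "X" else gap_open
                i += 1
            else:
                gap_const[k] += gap_extend if prev == "Y" else gap_open
                j += 1
            prev = mv
    best = np.full(sub_matrices.shape[0], -np.inf)
    chunk = max(1, int(5_000_000 // max(len(paths), 1)))
    for lo in range(0, sub_matrices.shape[0], chunk):
        block = sub_matrices[lo:lo + chunk] @ D.T + gap_const
        best[lo:lo + chunk] = block.max(axis=1)
    return best


def transitive_closure(edges: set[tuple[str, str]]) -> set[tuple[str, str]]:
    """Naive fixed-point reachability over child->parent edges."""
    closure = set(edges)
    changed = True
    while changed:
        changed = False
        for a, b in list(closure):
            for c, d in edges:
                if b == c and (a, d) not in closure:
                    closure.add((a, d))
                    changed = True
    return closure
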