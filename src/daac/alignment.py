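"""Weighted global alignment of domain architectures.

Two DAs are aligned with a Needleman–Wunsch global alignment whose alphabet
is the set of InterPro domain accessions (plus the GAP pseudo-domain) rather
than amino acids.  Substitution values follow a fixed ratio scheme — equal
magnitudes of opposite sign for match and mismatch, gap opening at half the
mismatch, gap extension at half the opening — and are multiplied by the
inverse domain frequency weights of both domains in the column.  Columns
that involve a GAP pseudo-domain (GAP vs anything, including GAP vs GAP) are
scored with the gap-opening penalty, unweighted: nothing is known about what
those regions contain.

Because opening and extension penalties differ, the optimum is computed by
three-state (substitution / insertion / deletion) affine-gap dynamic
programming.  The raw score ``S`` is normalized to a similarity in [0, 1]
against two anchors: the self-alignment scores ``Sself`` of the two DAs
(upper) and the minimum score ``Smn`` of the all-gap alignment in which the
two proteins share nothing (lower):

    SIM = min_i  (S - Smn) / (Sself_i - Smn).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .architectures import GAP, DomainArchitecture, WeightTable

_NEG_INF = float("-inf")

AlignedPair = tuple[Optional[str], Optional[str]]


@dataclass(frozen=True)
class ScoringParams:
    """Match/mismatch/gap parameters for DA alignment.

    The defaults encode the prescribed ratios on a unit match score:
    mismatch = -match, gap_open = mismatch / 2, gap_extend = gap_open / 2.
    Overrides are accepted but a warning is issued when they break the
    ratios.  ``gap_element_score`` is the fixed, unweighted score of any
    column pairing a GAP pseudo-domain with anything; it defaults to the
    gap-opening penalty.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -0.5
    gap_extend: float = -0.25
    gap_element_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0 \
                or self.gap_extend >= 0:
            raise ValueError(
                "match must be positive; mismatch, gap_open and gap_extend "
                "must be negative"
            )
        if self.gap_element_score is None:
            object.__setattr__(self, "gap_element_score", self.gap_open)
        ratios_ok = (
            self.mismatch == -self.match
            and self.gap_open == self.mismatch / 2
            and self.gap_extend == self.gap_open / 2
        )
        if not ratios_ok:
            warnings.warn(
                "scoring parameters deviate from the canonical ratios "
                "(mismatch = -match, gap_open = mismatch/2, "
                "gap_extend = gap_open/2)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AlignmentResult:
    """Raw score, normalization anchors and [0,1] similarity for a DA pair."""

    score: float
    self_score_1: float
    self_score_2: float
    min_score: float
    similarity: float
    aligned_pairs: tuple[AlignedPair, ...] = field(default=())


def substitution_score(
    a: str,
    b: str,
    weights: WeightTable,
    params: ScoringParams = ScoringParams(),
    strict: bool = True,
) -> float:
    """Score of one alignment column pairing elements ``a`` and ``b``.

    GAP-involving columns get the fixed ``gap_element_score``; otherwise the
    match/mismatch value is multiplied by the weights of both domains.
    """
    if a == GAP or b == GAP:
        return params.gap_element_score
    base = params.match if a == b else params.mismatch
    return base * weights.weight(a, strict=strict) * weights.weight(b, strict=strict)


def min_score(
    da1: Union[DomainArchitecture, int],
    da2: Union[DomainArchitecture, int],
    params: ScoringParams = ScoringParams(),
) -> float:
    """Score of the all-gap alignment: the two DAs share nothing.

    Gaps covering all n2 elements of DA2 are placed in DA1, then gaps
    covering all n1 elements of DA1 in DA2 — two affine runs, each one
    opening plus extensions:  [Gop + (n2-1) Gext] + [Gop + (n1-1) Gext].
    GAP elements occupy alignment columns, so they count toward n1/n2.
    """
    n1 = da1 if isinstance(da1, int) else len(da1.elements)
    n2 = da2 if isinstance(da2, int) else len(da2.elements)
    if n1 < 1 or n2 < 1:
        raise ValueError("architectures must be non-empty")
    run = lambda n: params.gap_open + (n - 1) * params.gap_extend
    return run(n1) + run(n2)


def _score_matrix(
    e1: Sequence[str],
    e2: Sequence[str],
    weights: WeightTable,
    params: ScoringParams,
    strict: bool,
) -> np.ndarray:
    """On-the-fly substitution matrix over just the elements of this pair."""
    alphabet = sorted(set(e1) | set(e2))
    w = {
        acc: (0.0 if acc == GAP else weights.weight(acc, strict=strict))
        for acc in alphabet
    }
    sub = {}
    for a in alphabet:
        for b in alphabet:
            if a == GAP or b == GAP:
                sub[a, b] = params.gap_element_score
            else:
                base = params.match if a == b else params.mismatch
                sub[a, b] = base * w[a] * w[b]
    n, m = len(e1), len(e2)
    s = np.empty((n, m))
    for i, a in enumerate(e1):
        for j, b in enumerate(e2):
            s[i, j] = sub[a, b]
    return s


def _affine_dp(s: np.ndarray, gap_open: float, gap_extend: float
               ) -> tuple[float, list, list, list]:
    """Three-state affine-gap global DP over a substitution matrix.

    States: M (column consumes both elements), X (gap in sequence 2,
    consumes sequence 1), Y (gap in sequence 1, consumes sequence 2).
    Returns the optimal score and the three score tables for traceback.
    """
    n, m = s.shape
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        si = s[i - 1]
        for j in range(1, m + 1):
            diag = max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            if diag > _NEG_INF:
                Mi[j] = diag + si[j - 1]
            Xi[j] = max(
                Mp[j] + gap_open, Xp[j] + gap_extend, Yp[j] + gap_open
            )
            Yi[j] = max(
                Mi[j - 1] + gap_open, Xi[j - 1] + gap_open, Yi[j - 1] + gap_extend
            )
    best = max(M[n][m], X[n][m], Y[n][m])
    return best, M, X, Y


def _traceback(e1, e2, s, M, X, Y, gap_open, gap_extend) -> tuple[AlignedPair, ...]:
    """Recover one optimal alignment; among co-optimal moves prefer the
    substitution state, then gap-in-sequence-2, then gap-in-sequence-1."""
    n, m = len(e1), len(e2)
    i, j = n, m
    final = max(M[n][m], X[n][m], Y[n][m])
    for state in "MXY":  # preference order
        if {"M": M, "X": X, "Y": Y}[state][n][m] == final:
            break
    pairs: list[AlignedPair] = []
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((e1[i - 1], e2[j - 1]))
            i, j = i - 1, j - 1
            best = max(M[i][j], X[i][j], Y[i][j])
            for prev in "MXY":
                if {"M": M, "X": X, "Y": Y}[prev][i][j] == best:
                    state = prev
                    break
        elif state == "X":
            pairs.append((e1[i - 1], None))
            val = X[i][j]
            i -= 1
            if M[i][j] + gap_open == val:
                state = "M"
            elif X[i][j] + gap_extend == val:
                state = "X"
            else:
                state = "Y"
            if i == 0 and j == 0:
                break
        else:
            pairs.append((None, e2[j - 1]))
            val = Y[i][j]
            j -= 1
            if M[i][j] + gap_open == val:
                state = "M"
            elif X[i][j] + gap_open == val:
                state = "X"
            else:
                state = "Y"
            if i == 0 and j == 0:
                break
        if i == 0 and j == 0:
            break
    return tuple(reversed(pairs))


def align_score(
    da1: DomainArchitecture,
    da2: DomainArchitecture,
    weights: WeightTable,
    params: ScoringParams = ScoringParams(),
    strict: bool = True,
) -> float:
    """Optimal global alignment score only (no traceback, no normalization)."""
    e1, e2 = da1.elements, da2.elements
    if not e1 or not e2:
        raise ValueError("cannot align an empty architecture")
    s = _score_matrix(e1, e2, weights, params, strict)
    best, *_ = _affine_dp(s, params.gap_open, params.gap_extend)
    return best


def self_score(
    da: DomainArchitecture,
    weights: WeightTable,
    params: ScoringParams = ScoringParams(),
    strict: bool = True,
) -> float:
    """Alignment score of a DA against itself (upper normalization anchor)."""
    return align_score(da, da, weights, params, strict=strict)


def align(
    da1: DomainArchitecture,
    da2: DomainArchitecture,
    weights: WeightTable,
    params: ScoringParams = ScoringParams(),
    strict: bool = True,
    traceback: bool = True,
) -> AlignmentResult:
    """Full weighted global alignment of two DAs with normalization.

    Populates the raw score, both self-alignment scores, the all-gap
    minimum score, the [0,1] similarity and (optionally) the aligned column
    descriptors of one optimal alignment.
    """
    e1, e2 = da1.elements, da2.elements
    if not e1 or not e2:
        raise ValueError("cannot align an empty architecture")
    s = _score_matrix(e1, e2, weights, params, strict)
    score, M, X, Y = _affine_dp(s, params.gap_open, params.gap_extend)
    pairs: tuple[AlignedPair, ...] = ()
    if traceback:
        pairs = _traceback(e1, e2, s, M, X, Y, params.gap_open, params.gap_extend)
    ss1 = self_score(da1, weights, params, strict=strict)
    ss2 = self_score(da2, weights, params, strict=strict)
    smn = min_score(da1, da2, params)
    sim = _normalize(score, ss1, ss2, smn)
    return AlignmentResult(
        score=score,
        self_score_1=ss1,
        self_score_2=ss2,
        min_score=smn,
        similarity=sim,
        aligned_pairs=pairs,
    )


def _normalize(score: float, ss1: float, ss2: float, smn: float) -> float:
    d1, d2 = ss1 - smn, ss2 - smn
    if d1 <= 0 or d2 <= 0:
        raise ValueError(
            "degenerate normalization: self score does not exceed the "
            "all-gap minimum score"
        )
    sim = min((score - smn) / d1, (score - smn) / d2)
    if sim < -1e-9 or sim > 1 + 1e-9:
        raise AssertionError(f"similarity {sim} outside [0, 1]")
    return min(max(sim, 0.0), 1.0)


def similarity(
    da1: DomainArchitecture,
    da2: DomainArchitecture,
    weights: WeightTable,
    params: ScoringParams = ScoringParams(),
    strict: bool = True,
) -> float:
    """Normalized DA similarity in [0, 1]; 1 for identical DAs."""
    if da1.elements == da2.elements:
        return 1.0
    return align(da1, da2, weights, params, strict=strict, traceback=False).similarity


def all_against_all(
    das: Sequence[DomainArchitecture],
    weights: WeightTable,
    params: ScoringParams = ScoringParams(),
    strict: bool = True,
) -> np.ndarray:
    """Symmetric n x n similarity matrix over a DA list (diagonal = 1).

    Self-alignment scores are computed once per DA; each off-diagonal entry
    is computed once and mirrored.
    """
    n = len(das)
    if n < 1:
        raise ValueError("need at least one architecture")
    selfs = [self_score(d, weights, params, strict=strict) for d in das]
    sims = np.ones((n, n))
    for i in range(n):
        ei = das[i].elements
        for j in range(i + 1, n):
            if ei == das[j].elements:
                sims[i, j] = sims[j, i] = 1.0
                continue
            s = _score_matrix(ei, das[j].elements, weights, params, strict)
            score, *_ = _affine_dp(s, params.gap_open, params.gap_extend)
            smn = min_score(len(ei), len(das[j].elements), params)
            sims[i, j] = sims[j, i] = _normalize(score, selfs[i], selfs[j], smn)
    return sims
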