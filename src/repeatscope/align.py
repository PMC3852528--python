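"""Ungapped local alignment with Karlin-Altschul E-value statistics.

Annotation and all-by-all family clustering need BLAST-like similarity
search with E-value cutoffs. This module provides a self-contained
engine: word seeding (default word size 11, both strands) followed by
ungapped X-drop extension under an integer match/mismatch scheme
(default +4/-5), with E-values from the ungapped Karlin-Altschul theory,

    E = K * m * n * exp(-lambda * S),

where lambda solves sum_ij p_i p_j exp(lambda * s_ij) = 1 under uniform
base frequencies and K is computed numerically from the score
distribution (lattice convolution series). Gapped statistics are out of
scope.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import revcomp
from .assembly import _kmer_ints

_WORD_SIZE = 11
_XDROP = 40.0
_K_SERIES_TERMS = 60


def solve_lambda(match: int, mismatch: int, p_match: float = 0.25) -> float:
    """Positive root of p*exp(lambda*match) + (1-p)*exp(lambda*mismatch) = 1.

    ``mismatch`` is negative. Under uniform base frequencies the chance of
    a match between two random bases is 1/4.
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 and mismatch < 0")
    q = 1.0 - p_match

    def f(lam):
        return p_match * math.exp(lam * match) + q * math.exp(lam * mismatch) - 1.0

    # expected score must be negative for a positive root to exist
    if p_match * match + q * mismatch >= 0:
        raise ValueError("expected score must be negative")
    hi = 1e-3
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-12, hi, xtol=1e-14))


def solve_karlin_k(match: int, mismatch: int, p_match: float = 0.25) -> float:
    """Karlin-Altschul K for a two-valued lattice score distribution.

    Uses the classical series representation: with P_i the i-fold
    convolution of the per-column score distribution,

        sigma = sum_{i>=1} (1/i) [ sum_{j<=0} P_i(j) e^{lambda j}
                                   + sum_{j>0} P_i(j) ],
        K = delta * lambda * exp(-2 sigma) / (H * (1 - e^{-lambda delta})),

    where delta is the lattice span of attainable scores and H the
    relative entropy of the aligned-pair distribution.
    """
    lam = solve_lambda(match, mismatch, p_match)
    q = 1.0 - p_match
    delta = math.gcd(match, -mismatch)
    H = lam * (
        p_match * match * math.exp(lam * match) + q * mismatch * math.exp(lam * mismatch)
    )
    # P_i over the score lattice, accumulated by explicit convolution
    dist = {0: 1.0}
    sigma = 0.0
    for i in range(1, _K_SERIES_TERMS + 1):
        new: dict = defaultdict(float)
        for s, p in dist.items():
            new[s + match] += p * p_match
            new[s + mismatch] += p * q
        dist = dict(new)
        inner = 0.0
        for s, p in dist.items():
            inner += p * math.exp(lam * s) if s <= 0 else p
        sigma += inner / i
    return delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))


@dataclass
class ScoreScheme:
    """Integer match/mismatch scheme with its ungapped statistics.

    ``lambda_`` and ``k_param`` are derived numerically in
    ``__post_init__`` under uniform base frequencies; overriding them is
    possible but normally unnecessary.
    """

    match_reward: int = 4
    mismatch_penalty: int = -5
    lambda_: float = field(default=None)  # type: ignore[assignment]
    k_param: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.lambda_ is None:
            self.lambda_ = solve_lambda(self.match_reward, self.mismatch_penalty)
        if self.k_param is None:
            self.k_param = solve_karlin_k(self.match_reward, self.mismatch_penalty)

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.k_param * m * n * math.exp(-self.lambda_ * score)


@dataclass
class LocalHit:
    """One ungapped local alignment between a query and a subject."""

    score: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    identity: float
    e_value: float

    @property
    def match_length(self) -> int:
        return self.query_end - self.query_start


def _extend(q_codes, s_codes, q_pos, s_pos, word, scheme):
    """X-drop ungapped extension around a seeded word; returns
    (score, q_start, q_end, matches) on the oriented query."""
    m, x = scheme.match_reward, scheme.mismatch_penalty
    score = word * m
    # right extension
    best_right, right = 0, 0
    cur = 0
    i, j = q_pos + word, s_pos + word
    while i < q_codes.size and j < s_codes.size:
        cur += m if q_codes[i] == s_codes[j] else x
        if cur > best_right:
            best_right, right = cur, i - (q_pos + word) + 1
        if best_right - cur > _XDROP:
            break
        i += 1
        j += 1
    # left extension
    best_left, left = 0, 0
    cur = 0
    i, j = q_pos - 1, s_pos - 1
    while i >= 0 and j >= 0:
        cur += m if q_codes[i] == s_codes[j] else x
        if cur > best_left:
            best_left, left = cur, q_pos - i
        if best_left - cur > _XDROP:
            break
        i -= 1
        j -= 1
    q_start = q_pos - left
    q_end = q_pos + word + right
    total = score + best_left + best_right
    length = q_end - q_start
    matches = round((total - x * length) / (m - x))  # from score = m*mt + x*(L-mt)
    return total, q_start, q_end, matches


def all_local_hits(query: str, subject: str, scheme: ScoreScheme | None = None,
                   e_cutoff: float = 10.0, word_size: int = _WORD_SIZE) -> list:
    """All ungapped seed-extension hits with E-value <= cutoff.

    Both strands of the query are searched; at most one hit is kept per
    (strand, diagonal). Hits are sorted by (E-value, subject start).
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    if scheme is None:
        scheme = ScoreScheme()
    m, n = len(query), len(subject)
    s_kmers = _kmer_ints(subject, word_size)
    s_index = defaultdict(list)
    for pos, val in enumerate(s_kmers):
        if val >= 0:
            s_index[int(val)].append(pos)
    s_codes = np.frombuffer(subject.encode(), dtype=np.uint8)
    hits = []
    for strand in ("+", "-"):
        oriented = query if strand == "+" else revcomp(query)
        q_codes = np.frombuffer(oriented.encode(), dtype=np.uint8)
        q_kmers = _kmer_ints(oriented, word_size)
        done_diag = {}
        for q_pos in range(q_kmers.size):
            val = int(q_kmers[q_pos])
            if val < 0 or val not in s_index:
                continue
            for s_pos in s_index[val]:
                diag = s_pos - q_pos
                span = done_diag.get(diag)
                if span is not None and span[0] <= q_pos < span[1]:
                    continue  # inside an already-extended region
                score, q_start, q_end, matches = _extend(
                    q_codes, s_codes, q_pos, s_pos, word_size, scheme
                )
                done_diag[diag] = (q_start, q_end)
                ev = scheme.evalue(score, m, n)
                if ev <= e_cutoff:
                    length = q_end - q_start
                    s_start = q_start + diag
                    hits.append(
                        LocalHit(
                            score=score,
                            query_start=q_start if strand == "+" else m - q_end,
                            query_end=q_end if strand == "+" else m - q_start,
                            subject_start=s_start,
                            subject_end=s_start + length,
                            strand=strand,
                            identity=matches / length,
                            e_value=ev,
                        )
                    )
    hits.sort(key=lambda h: (h.e_value, h.subject_start, h.strand))
    return hits


def local_align(query: str, subject: str, scheme: ScoreScheme | None = None,
                word_size: int = _WORD_SIZE):
    """Best ungapped local alignment between two sequences, or None when no
    word seed yields a positive extension."""
    hits = all_local_hits(query, subject, scheme, e_cutoff=math.inf, word_size=word_size)
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.score, h.subject_start, h.strand))
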