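"""Independent brute-force oracles used to check the implementation.

Everything here recomputes quantities by direct enumeration from first
principles — per-pair loops over sequence sets, Mann-Whitney pair counting —
and deliberately shares no code with the package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def kmer_sets(seqs: list[str], lenk: int) -> tuple[list[str], dict[str, set[int]], dict]:
    """All unique k-mers (first-seen order), their occurrence sets, and
    per-(kmer, seq) term frequencies, by direct scanning."""
    kmers: list[str] = []
    seen: dict[str, set[int]] = {}
    tf: dict[tuple[str, int], int] = {}
    for i, s in enumerate(seqs):
        for start in range(len(s) - lenk + 1):
            k = s[start : start + lenk]
            if k not in seen:
                seen[k] = set()
                kmers.append(k)
            seen[k].add(i)
            tf[(k, i)] = tf.get((k, i), 0) + 1
    return kmers, seen, tf


def brute_force_views(seqs: list[str], lenk: int):
    """The four edge-weight matrices by O(m^2 n) enumeration.

    Returns (kmers, Wco, Wsim, Wjac, Winclu) with rows/columns in the
    oracle's own first-seen k-mer order.
    """
    n = len(seqs)
    kmers, sk, tf = kmer_sets(seqs, lenk)
    m = len(kmers)
    Wco = np.zeros((m, m))
    Wsim = np.zeros((m, m))
    Wjac = np.zeros((m, m))
    Winclu = np.zeros((m, n))
    for p in range(m):
        for j in range(m):
            inter = len(sk[kmers[p]] & sk[kmers[j]])
            union = len(sk[kmers[p]] | sk[kmers[j]])
            Wjac[p, j] = inter / union
            Wsim[p, j] = sum(a != b for a, b in zip(kmers[p], kmers[j]))
            if p != j and inter > 0:
                P_p = len(sk[kmers[p]]) / n
                P_j = len(sk[kmers[j]]) / n
                Q = inter / n
                Wco[p, j] = -math.log(Q / (P_p * P_j))
    for p in range(m):
        num = len(sk[kmers[p]])
        for i in range(n):
            count = tf.get((kmers[p], i), 0)
            if count > 0:
                Winclu[p, i] = count * math.log(n / num)
    return kmers, Wco, Wsim, Wjac, Winclu


def mann_whitney_auc(y, scores) -> float:
    """ROC AUC as P(score+ > score-) + 1/2 P(tie), by pair enumeration."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def pr_staircase_area(y, scores) -> float:
    """Step-interpolated PR area: sum over ranked positives of
    precision-at-that-rank weighted by the recall increment."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    n_pos = int(y.sum())
    area = 0.0
    tp = 0
    for rank, label in enumerate(y_sorted, start=1):
        if label == 1:
            tp += 1
            area += (tp / rank) * (1 / n_pos)
    return area
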