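"""Multi-view heterogeneous graph over k-mer and sequence nodes.

Four edge views connect the m unique k-mers and the n sequences of a
prepared corpus:

* coexisting  (k-mer <-> k-mer): -log of the ratio of the joint occurrence
  probability to the product of marginals, i.e. negated pointwise mutual
  information over sequence-level presence; an edge exists only where the
  pair co-occurs in at least one sequence.
* similarity  (k-mer <-> k-mer): Hamming distance between the two strings.
* jaccard     (k-mer <-> k-mer): intersection-over-union of the two k-mers'
  sequence-occurrence sets.
* inclusive   (k-mer  ->  sequence): tf-idf, term frequency times
  log(n / document frequency).

Row-normalized copies of the three k-mer views serve as the initial node
embeddings for the GNN.  Because the coexisting view is signed, rows are
normalized by their L1 norm by default (the signed-sum variant is kept as a
strict mode); all-zero rows stay zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import KmerVocabulary, SequenceSet, build_vocabulary


@dataclass
class MultiViewGraph:
    """The four weight matrices plus row-normalized initial embeddings."""

    vocab: KmerVocabulary
    Wco: np.ndarray  # (m, m) signed
    Wsim: np.ndarray  # (m, m) integers 0..lenk
    Wjac: np.ndarray  # (m, m) in [0, 1]
    Winclu: np.ndarray  # (m, n) nonnegative
    Ect: np.ndarray  # (m, m) row-normalized Wco
    Est: np.ndarray  # (m, m) row-normalized Wsim
    Ejt: np.ndarray  # (m, m) row-normalized Wjac
    seq_ids: list[str]

    @property
    def m(self) -> int:
        return self.Wco.shape[0]

    @property
    def n(self) -> int:
        return self.Winclu.shape[1]


def coexisting_weight(num_p: int, num_j: int, nums_pj: int, n: int) -> float:
    """Edge weight for one k-mer pair from raw sequence-level counts:
    -log(Q / (P(p) P(j))) with P = num/n, Q = nums/n (natural log).

    Returns -inf-free values only; callers must ensure nums_pj > 0."""
    P_p, P_j, Q = num_p / n, num_j / n, nums_pj / n
    return float(-np.log(Q / (P_p * P_j)))


def coexisting_weights(vocab: KmerVocabulary, n: int | None = None) -> np.ndarray:
    """All pairwise coexisting weights; pairs never co-occurring and the
    diagonal carry 0 (no edge)."""
    n = vocab.n if n is None else n
    num = vocab.num().astype(float)
    nums = vocab.nums().astype(float)
    P = num / n
    Q = nums / n
    with np.errstate(divide="ignore", invalid="ignore"):
        W = -np.log(Q / np.outer(P, P))
    W[nums == 0] = 0.0
    np.fill_diagonal(W, 0.0)
    return W


def similarity_weights(vocab: KmerVocabulary) -> np.ndarray:
    """Pairwise Hamming distances between k-mer strings (diagonal 0)."""
    enc = np.array([[ord(c) for c in k] for k in vocab.kmers], dtype=np.uint8)
    return (enc[:, None, :] != enc[None, :, :]).sum(axis=2).astype(float)


def jaccard_weights(vocab: KmerVocabulary) -> np.ndarray:
    """Pairwise Jaccard index of sequence-occurrence sets (diagonal 1)."""
    inter = vocab.nums().astype(float)
    num = vocab.num().astype(float)
    union = num[:, None] + num[None, :] - inter
    return inter / union


def inclusive_weights(vocab: KmerVocabulary, n: int | None = None) -> np.ndarray:
    """tf-idf weight between each k-mer and each sequence containing it."""
    n = vocab.n if n is None else n
    num = vocab.num().astype(float)
    idf = np.log(n / num)
    return vocab.tf.astype(float) * idf[:, None]


def row_normalize(matrix: np.ndarray, mode: str = "l1") -> np.ndarray:
    """Divide each row by its L1 norm (``mode='l1'``) or by its signed sum
    (``mode='signed'``); all-zero rows are left unchanged."""
    M = np.asarray(matrix, dtype=float)
    if mode == "l1":
        denom = np.abs(M).sum(axis=1)
    elif mode == "signed":
        denom = M.sum(axis=1)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    safe = np.where(denom == 0, 1.0, denom)
    return M / safe[:, None]


def build_graph(
    records: SequenceSet,
    lenk: int = 5,
    sim_transform: str = "hamming",
    normalize: str = "l1",
) -> MultiViewGraph:
    """Construct all four views and the initial embeddings for a corpus.

    ``sim_transform='lenk-minus-hamming'`` converts the similarity view to
    lenk - Hamming so that more-similar pairs carry larger weights; the
    default keeps the raw distance.
    """
    if len(records) == 0:
        raise ValueError("cannot build a graph from an empty corpus")
    vocab = build_vocabulary(records, lenk)
    Wco = coexisting_weights(vocab)
    Wsim = similarity_weights(vocab)
    if sim_transform == "lenk-minus-hamming":
        Wsim = lenk - Wsim
        np.fill_diagonal(Wsim, 0.0)
    elif sim_transform != "hamming":
        raise ValueError(f"unknown sim_transform {sim_transform!r}")
    Wjac = jaccard_weights(vocab)
    Winclu = inclusive_weights(vocab)
    return MultiViewGraph(
        vocab=vocab,
        Wco=Wco,
        Wsim=Wsim,
        Wjac=Wjac,
        Winclu=Winclu,
        Ect=row_normalize(Wco, normalize),
        Est=row_normalize(Wsim, normalize),
        Ejt=row_normalize(Wjac, normalize),
        seq_ids=records.ids,
    )
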