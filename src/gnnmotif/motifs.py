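"""Variable-length TFBS and motif extraction from trained embeddings.

The trained model leaves every k-mer with an embedding (a row of Msc) and
every sequence with an embedding (a row of Esq) in the same space (which is
why dsq must equal dc + ds + dj).  A k-mer/sequence affinity score — the
dot product by default in the discovery pipeline, cosine similarity as an
option — is computed separately
over the positive corpus (MI1) and the negative corpus (MI0).  The grand
mean of MI0 is the background noise level; subtracting it from MI1 gives a
denoised score, and every k-mer with a strictly positive denoised score in
a positive sequence becomes a seed.

Each seed occurrence is expanded around its centre base ck into a left and
a right flanking k-mer (kl, kr).  The pair is merged into a candidate TFBS
of length 2*lenk when its coexisting weight computed on positive-corpus
counts is smaller (i.e. more enriched, the weight being a negated PMI) than
the same weight computed on negative-corpus counts — the background
coexisting probability.  A pair that never co-occurs in negatives has
background +inf, so any positive-corpus evidence accepts; a pair with no
positive-corpus co-occurrence is rejected outright.  Overlapping candidates
within a sequence are unioned transitively, which is what produces binding
sites — and therefore motifs — of different lengths.

Extracted site subsequences are grouped by exact length and greedily
clustered against running consensi (at most 25% mismatches to join);
clusters with enough members become position weight matrices under a small
pseudocount.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .graph import MultiViewGraph
from .model import ForwardOutputs, ModelDims
from .sequences import (
    DNA_ALPHABET,
    KmerVocabulary,
    SequenceSet,
    build_vocabulary,
)

logger = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}


# ---------------------------------------------------------------------------
# affinity scores and denoising


def mutual_information(
    Esc_rows: np.ndarray, Esq_rows: np.ndarray, metric: str = "cosine"
) -> np.ndarray:
    """k-mer x sequence affinity matrix between embedding rows.

    Rows of both inputs must have the same width (dsq = dc + ds + dj).
    Cosine similarity is the default scorer; zero vectors score 0 against
    everything.
    """
    Esc_rows = np.atleast_2d(np.asarray(Esc_rows, dtype=float))
    Esq_rows = np.atleast_2d(np.asarray(Esq_rows, dtype=float))
    if Esc_rows.shape[1] != Esq_rows.shape[1]:
        raise ValueError(
            "k-mer and sequence embeddings have different widths "
            f"({Esc_rows.shape[1]} vs {Esq_rows.shape[1]}); set dsq = dc + ds + dj"
        )
    dots = Esc_rows @ Esq_rows.T
    if metric == "dot":
        return dots
    if metric != "cosine":
        raise ValueError(f"unknown affinity metric {metric!r}")
    nk = np.linalg.norm(Esc_rows, axis=1)
    ns = np.linalg.norm(Esq_rows, axis=1)
    denom = np.outer(nk, ns)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, dots / np.where(denom == 0, 1.0, denom), 0.0)
    return out


def denoise(MI1: np.ndarray, MI0: np.ndarray) -> tuple[np.ndarray, float]:
    """Subtract the grand mean of the negative-corpus matrix from every
    entry of the positive-corpus matrix."""
    MI0 = np.asarray(MI0, dtype=float)
    if MI0.size == 0:
        raise ValueError("background matrix is empty: no negative sequences")
    noise = float(MI0.mean())
    return np.asarray(MI1, dtype=float) - noise, noise


def select_seeds(dnmi_col: np.ndarray, kmer_rows: list[int]) -> list[int]:
    """Rows (k-mer ids) with strictly positive denoised affinity for one
    sequence; an empty seed set is a valid outcome."""
    return [p for p in kmer_rows if dnmi_col[p] > 0]


# ---------------------------------------------------------------------------
# seed expansion and the background coexisting-probability merge test


@dataclass(frozen=True)
class SeedExpansion:
    ck: int
    kl: tuple[int, int]
    kr: tuple[int, int]
    candidate: tuple[int, int]  # always 2*lenk long


def expand_seed(strk: int, lenk: int, seq_len: int) -> SeedExpansion | None:
    """Left/right flanking k-mers around the centre of a seed occurrence.

    ck = strk + ceil((lenk-1)/2); kl = [ck-lenk+1, ck]; kr = [ck+1, ck+lenk].
    The expansion is skipped (None, logged) when either flank leaves the
    sequence, so every surviving candidate has length exactly 2*lenk.
    """
    ck = strk + math.ceil((lenk - 1) / 2)
    kl = (ck - lenk + 1, ck)
    kr = (ck + 1, ck + lenk)
    if kl[0] < 1 or kr[1] > seq_len:
        logger.debug("seed at %d: flank outside [1, %d], skipped", strk, seq_len)
        return None
    return SeedExpansion(ck=ck, kl=kl, kr=kr, candidate=(kl[0], kr[1]))


def coexisting_weight_from_vocab(
    vocab: KmerVocabulary, kmer_a: str, kmer_b: str
) -> float | None:
    """Coexisting weight of a k-mer pair from one corpus's counts;
    None when the pair (or either k-mer) never co-occurs there."""
    pa, pb = vocab.index.get(kmer_a), vocab.index.get(kmer_b)
    if pa is None or pb is None:
        return None
    both = int((vocab.occurrence[pa] & vocab.occurrence[pb]).sum())
    if both == 0:
        return None
    num = vocab.num()
    n = vocab.n
    P_a, P_b, Q = num[pa] / n, num[pb] / n, both / n
    return float(-np.log(Q / (P_a * P_b)))


def coexist_test(
    kl_kmer: str,
    kr_kmer: str,
    pos_vocab: KmerVocabulary,
    neg_vocab: KmerVocabulary,
) -> bool:
    """Accept the merge iff the pair's coexisting weight in positives is
    below its background weight in negatives.

    No positive-corpus co-occurrence -> reject (no evidence); no
    negative-corpus co-occurrence -> background +inf, accept.
    """
    wco = coexisting_weight_from_vocab(pos_vocab, kl_kmer, kr_kmer)
    if wco is None:
        return False
    bwco = coexisting_weight_from_vocab(neg_vocab, kl_kmer, kr_kmer)
    if bwco is None:
        return True
    return wco < bwco


# ---------------------------------------------------------------------------
# interval merging and motif assembly


@dataclass(frozen=True)
class TFBSInterval:
    """An extracted binding-site interval, 1-based inclusive."""

    seq_index: int  # index into the positive corpus
    start: int
    end: int
    merged: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def merge_overlaps(candidates: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union intervals sharing >= 1 position, transitively; intervals that
    are merely adjacent stay separate.  Output is sorted and disjoint."""
    if not candidates:
        return []
    ivs = sorted(set(candidates))
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:  # shares a position
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class Motif:
    """A motif: aligned same-length TFBSs summarized as counts and a PWM."""

    pwm: np.ndarray  # (4, L) column-stochastic
    counts: np.ndarray  # (4, L) integer base counts
    nsites: int
    consensus: str
    members: list[TFBSInterval] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.pwm.shape[1]


@dataclass
class MotifSet:
    motifs: list[Motif]
    tfbs: list[TFBSInterval]
    noise: float  # background affinity level subtracted from MI1

    def lengths(self) -> list[int]:
        return [iv.length for iv in self.tfbs]


def _counts_matrix(seqs: list[str]) -> np.ndarray:
    counts = np.zeros((4, len(seqs[0])), dtype=np.int64)
    for s in seqs:
        for j, b in enumerate(s):
            counts[_BASE_INDEX[b], j] += 1
    return counts


def _consensus(counts: np.ndarray) -> str:
    return "".join(DNA_ALPHABET[i] for i in counts.argmax(axis=0))


def build_motifs(
    tfbs_seqs: list[tuple[TFBSInterval, str]],
    min_sites: int = 5,
    pseudocount: float = 0.25,
    max_mismatch_frac: float = 0.25,
) -> list[Motif]:
    """Group site subsequences by exact length, then greedily cluster.

    Within a length group, each site joins the first cluster whose running
    consensus it matches with at most ``max_mismatch_frac`` mismatching
    positions, else it founds a new cluster.  Clusters with at least
    ``min_sites`` members are emitted as PWMs: (count + pseudocount) /
    (nsites + 4 * pseudocount) per cell.
    """
    by_len: dict[int, list[tuple[TFBSInterval, str]]] = {}
    for iv, s in tfbs_seqs:
        by_len.setdefault(len(s), []).append((iv, s))
    motifs: list[Motif] = []
    for length in sorted(by_len):
        clusters: list[dict] = []  # {"seqs", "members", "counts"}
        max_mm = int(max_mismatch_frac * length)
        for iv, s in by_len[length]:
            placed = False
            for cl in clusters:
                cons = _consensus(cl["counts"])
                mm = sum(a != b for a, b in zip(s, cons))
                if mm <= max_mm:
                    cl["seqs"].append(s)
                    cl["members"].append(iv)
                    for j, b in enumerate(s):
                        cl["counts"][_BASE_INDEX[b], j] += 1
                    placed = True
                    break
            if not placed:
                clusters.append(
                    {"seqs": [s], "members": [iv], "counts": _counts_matrix([s])}
                )
        for cl in clusters:
            nsites = len(cl["seqs"])
            if nsites < min_sites:
                continue
            counts = cl["counts"]
            pwm = (counts + pseudocount) / (nsites + 4 * pseudocount)
            motifs.append(
                Motif(
                    pwm=pwm,
                    counts=counts,
                    nsites=nsites,
                    consensus=_consensus(counts),
                    members=list(cl["members"]),
                )
            )
    motifs.sort(key=lambda m: (-m.nsites, m.width, m.consensus))
    return motifs


# ---------------------------------------------------------------------------
# end-to-end discovery


def discover_motifs(
    graph: MultiViewGraph,
    outputs: ForwardOutputs,
    records: SequenceSet,
    dims: ModelDims = ModelDims(),
    metric: str = "dot",
    min_sites: int = 5,
    pseudocount: float = 0.25,
    max_mismatch_frac: float = 0.25,
) -> MotifSet:
    """Run the full extraction over a prepared corpus and trained model.

    ``records`` must be the exact corpus the graph was built from (same
    order); positives and negatives are separated by label internally.
    """
    dims.require_mi_compatible()
    labels = records.labels
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(neg_idx) == 0:
        raise ValueError("motif discovery needs negative sequences for the background")
    lenk = graph.vocab.lenk

    positives = records.subset(labels == 1)
    negatives = records.subset(labels == 0)
    pos_vocab = build_vocabulary(positives, lenk)
    neg_vocab = build_vocabulary(negatives, lenk)

    # affinity over the label-restricted vocabularies and corpora
    full_index = graph.vocab.index
    pos_rows_full = [full_index[k] for k in pos_vocab.kmers]
    neg_rows_full = [full_index[k] for k in neg_vocab.kmers]
    MI1 = mutual_information(
        outputs.Msc[pos_rows_full], outputs.Esq[pos_idx], metric=metric
    )
    MI0 = mutual_information(
        outputs.Msc[neg_rows_full], outputs.Esq[neg_idx], metric=metric
    )
    dnMI1, noise = denoise(MI1, MI0)

    all_sites: list[TFBSInterval] = []
    tfbs_seqs: list[tuple[TFBSInterval, str]] = []
    for i, rec in enumerate(positives):
        kmer_rows = list(pos_vocab.positions[i].keys())
        seeds = select_seeds(dnMI1[:, i], kmer_rows)
        candidates: list[tuple[int, int]] = []
        for p in seeds:
            kmer = pos_vocab.kmers[p]
            for strk in pos_vocab.positions[i][p]:
                exp = expand_seed(strk, lenk, len(rec.bases))
                if exp is None:
                    continue
                kl_kmer = rec.bases[exp.kl[0] - 1 : exp.kl[1]]
                kr_kmer = rec.bases[exp.kr[0] - 1 : exp.kr[1]]
                if coexist_test(kl_kmer, kr_kmer, pos_vocab, neg_vocab):
                    candidates.append(exp.candidate)
        merged = merge_overlaps(candidates)
        for s, e in merged:
            iv = TFBSInterval(seq_index=i, start=s, end=e,
                              merged=(e - s + 1) > 2 * lenk)
            all_sites.append(iv)
            tfbs_seqs.append((iv, rec.bases[s - 1 : e]))
    motifs = build_motifs(
        tfbs_seqs,
        min_sites=min_sites,
        pseudocount=pseudocount,
        max_mismatch_frac=max_mismatch_frac,
    )
    return MotifSet(motifs=motifs, tfbs=all_sites, noise=noise)


# ---------------------------------------------------------------------------
# scoring against a planted ground truth


def compare_pwms(pwm_a: np.ndarray, pwm_b: np.ndarray,
                 min_overlap: int = 4) -> tuple[float, int]:
    """Best column-wise Pearson correlation between two PWMs over all
    offsets with at least ``min_overlap`` overlapping columns.

    Returns (best r, offset of pwm_b relative to pwm_a).
    """
    a, b = np.asarray(pwm_a, float), np.asarray(pwm_b, float)
    wa, wb = a.shape[1], b.shape[1]
    best_r, best_off = -1.0, 0
    for off in range(-(wb - min_overlap), wa - min_overlap + 1):
        a_lo, a_hi = max(0, off), min(wa, off + wb)
        if a_hi - a_lo < min_overlap:
            continue
        blk_a = a[:, a_lo:a_hi].ravel()
        blk_b = b[:, a_lo - off : a_hi - off].ravel()
        sa, sb = blk_a.std(), blk_b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.corrcoef(blk_a, blk_b)[0, 1])
        if r > best_r:
            best_r, best_off = r, off
    return best_r, best_off


def planted_site_recall(motif_set: MotifSet, truth_sites: list[list]) -> float:
    """Fraction of planted intervals overlapped (>= 1 base) by at least one
    reported TFBS in the same sequence."""
    by_seq: dict[int, list[TFBSInterval]] = {}
    for iv in motif_set.tfbs:
        by_seq.setdefault(iv.seq_index, []).append(iv)
    total = hit = 0
    for i, sites in enumerate(truth_sites):
        for site in sites:
            total += 1
            if any(iv.start <= site.end and site.start <= iv.end
                   for iv in by_seq.get(i, ())):
                hit += 1
    return hit / total if total else float("nan")
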