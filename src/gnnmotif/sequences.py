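"""Sequence corpus preparation.

Turns footprint intervals or raw FASTA records into the labeled, split,
k-merized corpus that the multi-view graph builder consumes.  Positives are
fixed-length windows (101 bp by default) centred on ATAC-seq footprints;
negatives are per-sequence base shuffles, so each negative preserves the
base composition of its positive partner and the classification task is
"does this composition arrangement look like a bound site".

Coordinates are 1-based inclusive internally; BED input/output converts
to/from 0-based half-open at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
_VALID_BASES = frozenset(DNA_ALPHABET)


@dataclass
class SequenceRecord:
    """One labeled DNA sequence.

    label 1 marks an original (positive) sequence, label 0 its shuffled
    negative partner; ``paired_id`` links the two so they can be kept in
    the same train/val/test split.
    """

    id: str
    bases: str
    label: int = 1
    split: str | None = None
    paired_id: str | None = None

    def __len__(self) -> int:
        return len(self.bases)


class SequenceSet:
    """Ordered collection of :class:`SequenceRecord` with array views."""

    def __init__(self, records: Sequence[SequenceRecord]):
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def splits(self) -> list[str | None]:
        return [r.split for r in self.records]

    def subset(self, mask) -> "SequenceSet":
        return SequenceSet([r for r, keep in zip(self.records, mask) if keep])

    def by_label(self, label: int) -> "SequenceSet":
        return SequenceSet([r for r in self.records if r.label == label])

    def by_split(self, split: str) -> "SequenceSet":
        return SequenceSet([r for r in self.records if r.split == split])

    def split_mask(self, split: str) -> np.ndarray:
        return np.array([r.split == split for r in self.records], dtype=bool)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a contig, optionally scored."""

    contig: str
    start: int
    end: int
    score: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )


def trim_footprint(
    interval: GenomicInterval,
    flank: int = 50,
    contig_length: int | None = None,
) -> GenomicInterval | None:
    """Centre a fixed window of ``2*flank + 1`` bases on a footprint.

    The centre is ``floor((start + end) / 2)`` in 1-based coordinates, so a
    footprint at [c, c] yields [c - flank, c + flank].  Windows that fall off
    the contig are skipped (``None``) with a logged warning.
    """
    center = (interval.start + interval.end) // 2
    start, end = center - flank, center + flank
    if start < 1 or (contig_length is not None and end > contig_length):
        logger.warning(
            "window [%d, %d] exceeds bounds of %s; footprint skipped",
            start, end, interval.contig,
        )
        return None
    return GenomicInterval(interval.contig, start, end)


def rank_and_intersect_footprints(
    primary: Sequence[GenomicInterval],
    secondary: Sequence[GenomicInterval],
    top_n: int = 1500,
) -> list[GenomicInterval]:
    """Keep the ``top_n`` highest-scored primary footprints that overlap
    at least one secondary footprint by >= 1 base.

    Score ties are broken by (contig, start) ascending so the selection is
    stable across runs.
    """
    if any(iv.score is None for iv in primary):
        raise ValueError("primary footprints must carry a numeric score")
    ranked = sorted(primary, key=lambda iv: (-iv.score, iv.contig, iv.start))
    top = ranked[:top_n]
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in secondary:
        by_contig.setdefault(iv.contig, []).append(iv)
    kept = [
        iv for iv in top
        if any(iv.overlaps(o) for o in by_contig.get(iv.contig, ()))
    ]
    if not kept:
        logger.warning("no primary footprints overlap the secondary set")
    return kept


def make_negative(record: SequenceRecord, rng: np.random.Generator) -> SequenceRecord:
    """Shuffle all bases of a positive sequence into its negative partner.

    The negative has the same length and exactly the same base multiset:
    only the arrangement is destroyed.
    """
    if record.label != 1:
        raise ValueError("negatives are derived from positive (label 1) records")
    shuffled = "".join(rng.permutation(list(record.bases)))
    return SequenceRecord(
        id=f"{record.id}_shuf",
        bases=shuffled,
        label=0,
        split=record.split,
        paired_id=record.id,
    )


def drop_ambiguous(records: SequenceSet) -> SequenceSet:
    """Drop records containing letters outside A/C/G/T (k-mer identity is
    undefined over N); the number dropped is logged."""
    kept = [r for r in records if set(r.bases) <= _VALID_BASES]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("dropped %d records with non-ACGT letters", n_dropped)
    return SequenceSet(kept)


def split_dataset(
    records: SequenceSet,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SequenceSet:
    """Assign train/val/test splits to positive/negative pairs.

    A positive and its shuffled partner always land in the same split so
    neither composition nor content leaks across splits.  Validation and
    test sizes are the rounded targets; training takes the remainder.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    positives = [r for r in records if r.label == 1]
    partner_of = {r.paired_id: r for r in records if r.label == 0}
    pairs = [(pos, partner_of.get(pos.id)) for pos in positives]
    n_pairs = len(pairs)
    if n_pairs < 10:
        raise ValueError(f"need >= 10 positive/negative pairs, got {n_pairs}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pairs)
    n_val = round(fractions[1] * n_pairs)
    n_test = round(fractions[2] * n_pairs)
    n_train = n_pairs - n_val - n_test
    assignment = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    out = []
    for rank, pair_idx in enumerate(order):
        pos, neg = pairs[pair_idx]
        split = assignment[rank]
        pos = replace(pos, split=split)
        out.append(pos)
        if neg is not None:
            out.append(replace(neg, split=split))
    # preserve original record order
    new_by_id = {r.id: r for r in out}
    return SequenceSet([new_by_id.get(r.id, r) for r in records])


def prepare_corpus(
    positives: SequenceSet,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SequenceSet:
    """Full prep: drop ambiguous records, pair each positive with a base
    shuffle, and assign paired splits.  Positives and negatives interleave
    (pos, neg, pos, neg, ...) in the returned set."""
    clean = drop_ambiguous(positives)
    rng = np.random.default_rng(seed)
    paired: list[SequenceRecord] = []
    for rec in clean:
        pos = replace(rec, label=1)
        paired.append(pos)
        paired.append(make_negative(pos, rng))
    return split_dataset(SequenceSet(paired), fractions=fractions, seed=seed)


# ---------------------------------------------------------------------------
# k-mer vocabulary


def extract_kmers(bases: str, lenk: int) -> list[tuple[str, int]]:
    """All k-mers of a sequence with their 1-based start positions, step 1.

    A sequence of length L yields exactly L - lenk + 1 entries; sequences
    shorter than lenk yield an empty list with a warning.
    """
    if len(bases) < lenk:
        logger.warning("sequence of length %d shorter than lenk=%d", len(bases), lenk)
        return []
    return [(bases[i : i + lenk], i + 1) for i in range(len(bases) - lenk + 1)]


@dataclass
class KmerVocabulary:
    """All unique k-mers of a corpus with occurrence statistics.

    Rows index the m unique k-mers in first-seen order, columns the n
    sequences.  ``occurrence[p, i]`` flags whether k-mer p occurs in
    sequence i; ``tf[p, i]`` counts how many times.  Per-(sequence, k-mer)
    start positions support seed expansion during motif discovery.
    """

    lenk: int
    kmers: list[str]
    occurrence: np.ndarray  # (m, n) bool
    tf: np.ndarray  # (m, n) int
    positions: list[dict[int, list[int]]]  # per sequence: kmer row -> sorted 1-based starts
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {k: p for p, k in enumerate(self.kmers)}

    @property
    def m(self) -> int:
        return len(self.kmers)

    @property
    def n(self) -> int:
        return self.occurrence.shape[1]

    def num(self) -> np.ndarray:
        """num(k(p)): number of sequences containing each k-mer."""
        return self.occurrence.sum(axis=1).astype(np.int64)

    def nums(self) -> np.ndarray:
        """nums(p, j): number of sequences containing both k-mers."""
        occ = self.occurrence.astype(np.int64)
        return occ @ occ.T

    def sk(self, kmer: str) -> set[int]:
        """Sk(k): the set of sequence indices containing the k-mer."""
        return set(np.flatnonzero(self.occurrence[self.index[kmer]]).tolist())

    def contains(self, kmer: str) -> bool:
        return kmer in self.index

    def starts(self, seq_idx: int, kmer: str) -> list[int]:
        p = self.index.get(kmer)
        if p is None:
            return []
        return self.positions[seq_idx].get(p, [])


def build_vocabulary(records: SequenceSet, lenk: int) -> KmerVocabulary:
    """Index every unique k-mer across the corpus with all counts."""
    if len(records) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    index: dict[str, int] = {}
    per_seq: list[dict[int, list[int]]] = []
    for rec in records:
        seq_pos: dict[int, list[int]] = {}
        for kmer, start in extract_kmers(rec.bases, lenk):
            p = index.setdefault(kmer, len(index))
            seq_pos.setdefault(p, []).append(start)
        per_seq.append(seq_pos)
    m, n = len(index), len(records)
    tf = np.zeros((m, n), dtype=np.int64)
    for i, seq_pos in enumerate(per_seq):
        for p, starts in seq_pos.items():
            tf[p, i] = len(starts)
    kmers = [None] * m
    for k, p in index.items():
        kmers[p] = k
    return KmerVocabulary(
        lenk=lenk,
        kmers=list(kmers),
        occurrence=tf > 0,
        tf=tf,
        positions=per_seq,
        index=index,
    )


# ---------------------------------------------------------------------------
# BED plumbing for footprint input


def read_scored_bed(path) -> list[GenomicInterval]:
    """Read a BED3+score file (TOBIAS/Hint-ATAC style) into 1-based
    inclusive intervals.  A missing or non-numeric score column rejects
    the file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected BED with a score in column 4")
    try:
        scores = df.iloc[:, 3].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: score column is not numeric") from exc
    return [
        GenomicInterval(str(c), int(s) + 1, int(e), score=float(sc))
        for c, s, e, sc in zip(df[0], df[1], df[2], scores)
    ]


def read_bed3(path) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        GenomicInterval(str(c), int(s) + 1, int(e))
        for c, s, e in zip(df[0], df[1], df[2])
    ]
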