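"""Planted-motif corpus simulation.

Generates fixed-length DNA sequences (101 bp by default, matching the
footprint-window convention) with 1-3 motif instances per positive sequence
sampled column-wise from configurable PWMs, over an i.i.d. background.  The
ground truth records every planted interval, so graph construction,
training and motif extraction can all be scored against a known answer.

Background positions are i.i.d. by default because the matched negatives
downstream are per-sequence base shuffles — an i.i.d. background is the
corresponding null.  An optional first-order Markov background is available
for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import DNA_ALPHABET, SequenceRecord, SequenceSet

_BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}


def pwm_information_content(pwm: np.ndarray) -> np.ndarray:
    """Per-column information content in bits: 2 + sum_b p_b * log2(p_b)."""
    p = np.asarray(pwm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=0)


def make_pwm(width: int, ic_per_col: float, rng_seed: int) -> np.ndarray:
    """Sample a 4 x width PWM whose mean per-column information content is
    within 0.15 bits of the request.

    Columns are Dirichlet draws sharpened by a per-column temperature found
    by bisection, so each column individually hits the target IC.  ic = 2
    forces point-mass columns (a consensus); ic = 0 forces uniform columns.
    """
    if width < 4:
        raise ValueError("motif width must be >= 4")
    if not 0.0 <= ic_per_col <= 2.0:
        raise ValueError("information content per column must lie in [0, 2] bits")
    rng = np.random.default_rng(rng_seed)
    cols = []
    for _ in range(width):
        if ic_per_col >= 2.0 - 1e-12:
            col = np.zeros(4)
            col[rng.integers(4)] = 1.0
        elif ic_per_col <= 1e-12:
            col = np.full(4, 0.25)
        else:
            base = rng.dirichlet(np.ones(4))
            # avoid exact zeros so the temperature sweep is smooth
            base = (base + 1e-6) / (base + 1e-6).sum()
            col = _sharpen_to_ic(base, ic_per_col)
        cols.append(col)
    pwm = np.column_stack(cols)
    assert np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9)
    return pwm


def _sharpen_to_ic(col: np.ndarray, target_ic: float) -> np.ndarray:
    """Raise a probability column to a power t (renormalized) chosen by
    bisection so its information content matches target_ic."""

    def ic_at(t: float) -> float:
        q = col ** t
        q = q / q.sum()
        return float(pwm_information_content(q[:, None])[0])

    lo, hi = 0.0, 1.0
    while ic_at(hi) < target_ic and hi < 1e4:
        lo, hi = hi, hi * 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if ic_at(mid) < target_ic:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    q = col ** t
    return q / q.sum()


@dataclass
class PlantedMotifConfig:
    """Conditions for one simulated corpus of positive sequences."""

    n_pos: int = 150
    seq_len: int = 101
    motifs: list[np.ndarray] = field(default_factory=list)  # 4 x width PWMs
    instances_per_seq: tuple[int, int] = (1, 3)
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    markov_order: int = 0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_pos < 1 or self.seq_len < 1:
            raise ValueError("n_pos and seq_len must be positive")
        if not self.motifs:
            if self.instances_per_seq[1] > 0:
                raise ValueError("instances requested but no motifs configured")
        for pwm in self.motifs:
            pwm = np.asarray(pwm)
            if pwm.shape[0] != 4 or pwm.shape[1] < 4:
                raise ValueError("each PWM must be 4 x width with width >= 4")
            if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError("PWM columns must sum to 1")
        lo, hi = self.instances_per_seq
        if lo < 0:
            raise ValueError("instances_per_seq min must be >= 0")
        if self.motifs:
            min_w = min(np.asarray(p).shape[1] for p in self.motifs)
            if hi > self.seq_len // min_w:
                raise ValueError(
                    "instances_per_seq max exceeds floor(seq_len / min motif width)"
                )
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")


@dataclass(frozen=True)
class PlantedSite:
    """One planted motif instance, 1-based inclusive coordinates."""

    motif_id: int
    start: int
    end: int


@dataclass
class GroundTruth:
    """Per-sequence planted intervals; sites within a sequence never overlap."""

    sites: list[list[PlantedSite]]

    def n_sites(self) -> int:
        return sum(len(s) for s in self.sites)


def _sample_site(pwm: np.ndarray, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=pwm[:, j]) for j in range(pwm.shape[1])]
    return "".join(DNA_ALPHABET[c] for c in cols)


def _sample_background(length: int, cfg: PlantedMotifConfig,
                       rng: np.random.Generator) -> np.ndarray:
    probs = np.asarray(cfg.background)
    if cfg.markov_order == 0:
        return rng.choice(4, size=length, p=probs)
    # first-order chain with stationary start; transition rows biased toward
    # the configured composition
    out = np.empty(length, dtype=int)
    out[0] = rng.choice(4, p=probs)
    trans = 0.5 * np.eye(4) + 0.5 * np.tile(probs, (4, 1))
    trans = trans / trans.sum(axis=1, keepdims=True)
    for i in range(1, length):
        out[i] = rng.choice(4, p=trans[out[i - 1]])
    return out


def _place_sites(widths: list[int], seq_len: int, rng: np.random.Generator,
                 max_tries: int = 200) -> list[int]:
    """Non-overlapping uniform-random start positions (1-based) for the given
    widths, by bounded rejection sampling."""
    for _ in range(max_tries):
        starts = []
        taken: list[tuple[int, int]] = []
        ok = True
        for w in widths:
            start = int(rng.integers(1, seq_len - w + 2))
            iv = (start, start + w - 1)
            if any(iv[0] <= e and s <= iv[1] for s, e in taken):
                ok = False
                break
            taken.append(iv)
            starts.append(start)
        if ok:
            return starts
    raise RuntimeError(
        f"could not place {len(widths)} non-overlapping instances of widths "
        f"{widths} in a {seq_len} bp sequence after {max_tries} tries"
    )


def simulate_dataset(config: PlantedMotifConfig) -> tuple[SequenceSet, GroundTruth]:
    """Draw the positive corpus and its ground truth.

    Each sequence is background with a per-sequence uniform-random number of
    motif instances (motif identity uniform over the configured PWMs) written
    over it at non-overlapping positions.  Byte-identical under a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    records: list[SequenceRecord] = []
    truth: list[list[PlantedSite]] = []
    lo, hi = config.instances_per_seq
    for i in range(config.n_pos):
        baseline = _sample_background(config.seq_len, config, rng)
        bases = [DNA_ALPHABET[b] for b in baseline]
        n_inst = int(rng.integers(lo, hi + 1)) if config.motifs else 0
        motif_ids = [int(rng.integers(len(config.motifs))) for _ in range(n_inst)]
        widths = [np.asarray(config.motifs[mid]).shape[1] for mid in motif_ids]
        starts = _place_sites(widths, config.seq_len, rng) if n_inst else []
        sites = []
        for mid, w, start in zip(motif_ids, widths, starts):
            site = _sample_site(np.asarray(config.motifs[mid]), rng)
            bases[start - 1 : start - 1 + w] = list(site)
            sites.append(PlantedSite(motif_id=mid, start=start, end=start + w - 1))
        sites.sort(key=lambda s: s.start)
        records.append(SequenceRecord(id=f"pos_{i}", bases="".join(bases), label=1))
        truth.append(sites)
    return SequenceSet(records), GroundTruth(sites=truth)


def write_ground_truth(truth: GroundTruth, records: SequenceSet, path) -> None:
    """BED-like TSV (sequence_id, start-1, end, motif_id), 0-based half-open."""
    with open(path, "w") as fh:
        for rec, sites in zip(records, truth.sites):
            for site in sites:
                fh.write(f"{rec.id}\t{site.start - 1}\t{site.end}\tmotif_{site.motif_id}\n")
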