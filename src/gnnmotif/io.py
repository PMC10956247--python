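"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython; MEME minimal motif format, prediction/manifest
TSVs and Matrix Market exports are written here.  All writers that the CLI
uses are atomic: content lands in a temp file next to the target and is
renamed into place, so a failed run never leaves a partial output.
"""

from __future__ import annotations

import contextlib
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .motifs import Motif, MotifSet, TFBSInterval
from .sequences import SequenceRecord, SequenceSet

logger = logging.getLogger(__name__)


@contextlib.contextmanager
def atomic_write(path, mode: str = "w"):
    """Write to a temp file in the target directory, rename on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(FileNotFoundError):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> SequenceSet:
    """Read a multi-record FASTA, order-preserving, bases uppercased, ids
    taken from the header up to the first whitespace."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: empty or missing FASTA file")
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise ValueError(f"{path}: line 1: expected a '>' FASTA header")
    records = [
        SequenceRecord(id=rec.id, bases=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no records parsed")
    return SequenceSet(records)


def write_fasta(records: SequenceSet, path) -> None:
    bio = [
        BioSeqRecord(Seq(r.bases), id=r.id, description="") for r in records
    ]
    with atomic_write(path) as fh:
        SeqIO.write(bio, fh, "fasta")


# ---------------------------------------------------------------------------
# corpus manifest and predictions


def write_manifest(records: SequenceSet, path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "label": [r.label for r in records],
            "split": [r.split or "" for r in records],
            "paired_id": [r.paired_id or "" for r in records],
        }
    )
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "paired_id": str},
                     keep_default_na=False)
    required = {"id", "label", "split"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: manifest must carry columns {sorted(required)}")
    return df


def apply_manifest(records: SequenceSet, manifest: pd.DataFrame) -> SequenceSet:
    """Attach labels/splits/pairings from a manifest to FASTA records."""
    meta = manifest.set_index("id")
    out = []
    for r in records:
        row = meta.loc[r.id]
        out.append(
            SequenceRecord(
                id=r.id,
                bases=r.bases,
                label=int(row["label"]),
                split=str(row["split"]) or None,
                paired_id=str(row.get("paired_id", "")) or None,
            )
        )
    return SequenceSet(out)


def write_predictions(ids, labels, scores, splits, path) -> None:
    df = pd.DataFrame({"id": ids, "label": labels, "score": scores,
                       "split": splits})
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme(motifs: list[Motif], path,
               background=(0.25, 0.25, 0.25, 0.25)) -> None:
    """MEME minimal format: version header, ACGT alphabet, strands, one
    letter-probability block per motif with width and nsites."""
    if not motifs:
        logger.warning("writing a MEME file with no motifs (header only)")
    with atomic_write(path) as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*background))
        for idx, motif in enumerate(motifs, start=1):
            name = f"MOTIF_{idx}_{motif.consensus}"
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {motif.width} "
                f"nsites= {motif.nsites} E= 0\n"
            )
            for col in motif.pwm.T:
                fh.write(" ".join(f"{p:.6f}" for p in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[Motif]:
    """Parse the bundled writer's MEME minimal output back into motifs."""
    motifs: list[Motif] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("MOTIF "):
            header = None
            j = i + 1
            while j < len(lines) and not lines[j].startswith("letter-probability"):
                j += 1
            if j == len(lines):
                raise ValueError(f"{path}: MOTIF block without a matrix")
            header = lines[j]
            fields = header.replace("=", " ").split()
            w = int(fields[fields.index("w") + 1])
            nsites = int(fields[fields.index("nsites") + 1])
            rows = []
            for k in range(j + 1, j + 1 + w):
                rows.append([float(x) for x in lines[k].split()])
            pwm = np.array(rows).T  # (4, w)
            from .sequences import DNA_ALPHABET

            consensus = "".join(DNA_ALPHABET[c] for c in pwm.argmax(axis=0))
            counts = np.rint(pwm * nsites).astype(int)
            motifs.append(Motif(pwm=pwm, counts=counts, nsites=nsites,
                                consensus=consensus))
            i = j + 1 + w
        else:
            i += 1
    return motifs


# ---------------------------------------------------------------------------
# TFBS output


def write_tfbs_bed(motif_set: MotifSet, seq_ids: list[str], path) -> None:
    """Extracted sites as BED (0-based half-open) keyed by sequence id."""
    with atomic_write(path) as fh:
        for iv in motif_set.tfbs:
            fh.write(f"{seq_ids[iv.seq_index]}\t{iv.start - 1}\t{iv.end}\ttfbs\n")


def write_tfbs_fasta(motif_set: MotifSet, positives: SequenceSet, path) -> None:
    recs = []
    for k, iv in enumerate(motif_set.tfbs):
        rec = positives[iv.seq_index]
        recs.append(
            SequenceRecord(
                id=f"{rec.id}:{iv.start}-{iv.end}",
                bases=rec.bases[iv.start - 1 : iv.end],
            )
        )
    write_fasta(SequenceSet(recs), path)


# ---------------------------------------------------------------------------
# optional Matrix Market export of the graph views


def export_graph_mtx(graph, outdir) -> None:
    from scipy import io as spio
    from scipy import sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("Wco", "Wsim", "Wjac", "Winclu"):
        spio.mmwrite(outdir / f"{name}.mtx", sparse.coo_matrix(getattr(graph, name)))
    with atomic_write(outdir / "kmer_index.tsv") as fh:
        for p, k in enumerate(graph.vocab.kmers):
            fh.write(f"{p}\t{k}\n")
    with atomic_write(outdir / "sequence_index.tsv") as fh:
        for i, sid in enumerate(graph.seq_ids):
            fh.write(f"{i}\t{sid}\n")
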