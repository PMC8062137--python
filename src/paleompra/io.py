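"""File-format helpers: FASTA, BED, TSV, MEME minimal motifs, run manifests.

Sequence I/O goes through Biopython; motif I/O uses the minimal MEME text
format with a side table for TF attribution and direct/inferred status.
All tables are plain TSV so a run is fully inspectable with standard tools.
Oligo FASTA IDs encode ``oligo_id|allele``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import OligoPair
from .motifs import PWM


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_oligo_fasta(library: list[OligoPair], path) -> None:
    """Library FASTA with one record per sequence, IDs ``oligo_id|allele``."""
    seqs: dict[str, str] = {}
    for o in library:
        if o.oligo_class == "test":
            seqs[f"{o.oligo_id}|modern"] = o.modern_seq
            seqs[f"{o.oligo_id}|archaic"] = o.archaic_seq
        else:
            seqs[f"{o.oligo_id}|{o.oligo_class}"] = o.modern_seq
    write_fasta(seqs, path)


def write_bed(intervals: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    """BED (0-based half-open) with optional extra columns after chrom/start/end."""
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_meme(pwms: list[PWM], path, background: np.ndarray | None = None) -> None:
    """Minimal MEME motif format; TF names travel as the alternate motif name."""
    bg = background if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id} {pwm.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" {:.6f} {:.6f} {:.6f} {:.6f}\n".format(*row))
            fh.write("\n")


def read_meme(path, meta: pd.DataFrame | None = None) -> list[PWM]:
    """Parse minimal MEME motifs; ``meta`` (motif_id, tf, source) overrides labels."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    lookup = meta.set_index("motif_id") if meta is not None else None
    out = []
    for m in parsed:
        mat = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        mat = mat / mat.sum(axis=1, keepdims=True)
        motif_id = m.name
        tf = getattr(m, "alt_id", None) or motif_id
        source = "direct"
        if lookup is not None and motif_id in lookup.index:
            tf = lookup.loc[motif_id, "tf"]
            source = lookup.loc[motif_id, "source"]
        out.append(PWM(motif_id=motif_id, tf_name=str(tf), matrix=mat, source=source))
    return out


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, seed: int, params: dict, artifacts: list[str | Path],
                   stage_counts: dict | None = None) -> dict:
    """JSON run manifest: seed, parameters, per-stage record counts, file digests."""
    base = Path(path).parent
    manifest = {
        "seed": seed,
        "parameters": params,
        "stage_counts": stage_counts or {},
        "artifacts": {
            str(Path(a).relative_to(base)) if str(a).startswith(str(base)) else str(a):
                file_sha256(a)
            for a in artifacts
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
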