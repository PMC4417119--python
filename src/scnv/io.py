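"""Readers/writers for the tab-separated artifacts of the pipeline.

All genomic coordinates written by this package are 0-based, half-open.
"""

from __future__ import annotations

import os

import pandas as pd


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a bins x cells (or cells x bins) matrix TSV with index."""
    matrix.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    """Write read starts as BED6 (0-based, half-open; end = pos + 1)."""
    out = pd.DataFrame({
        "chrom": reads["chrom"], "start": reads["pos"],
        "end": reads["pos"] + 1, "name": ".", "score": 0,
        "strand": reads["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_segments(seg, path) -> None:
    """Per-cell segment table (0-based, half-open bin and bp coordinates)."""
    seg.segments.to_csv(path, sep="\t", index=False)


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    return {name: str(rec[:]) for name, rec in Fasta(os.fspath(path)).items()}
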