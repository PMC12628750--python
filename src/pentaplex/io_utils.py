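"""FASTQ/FASTA/TSV helpers and provenance headers.

All tabular outputs start with ``#``-prefixed provenance comments (tool
version, config hash, seed) so any result file can be regenerated from its
own header.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import json
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO

from . import __version__


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file (gzip-aware)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTA file (gzip-aware)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq).upper()


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality: int = 30) -> None:
    """Write (read_id, seq) pairs as FASTQ with a constant quality score."""
    qchar = chr(quality + 33)
    with _open_text(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qchar * len(seq)}\n")


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def provenance_lines(config: dict) -> list[str]:
    """Provenance comment block: version, config hash, full config as JSON."""
    payload = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    return [
        f"# pentaplex {__version__}",
        f"# config-sha256 {digest}",
        f"# config {payload}",
    ]


def write_tsv(df: pd.DataFrame, path: str | Path, config: dict | None = None) -> None:
    """Write a TSV with a '#'-prefixed provenance header, atomically."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    buf = io.StringIO()
    if config is not None:
        buf.write("\n".join(provenance_lines(config)) + "\n")
    df.to_csv(buf, sep="\t", index=False)
    tmp.write_text(buf.getvalue())
    tmp.replace(path)


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV, skipping '#' provenance comments."""
    return pd.read_csv(path, sep="\t", comment="#")
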