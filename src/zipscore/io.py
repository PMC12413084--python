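"""FASTA input, tabular output, and run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .profiler import ProteinRecord

logger = logging.getLogger(__name__)


def read_fasta(path) -> list:
    """Parse a FASTA file into :class:`ProteinRecord` objects.

    The id is the header token before the first whitespace; sequences are
    uppercased; trailing/internal ``*`` stop codons are stripped with a
    warning; alignment gaps (``-``/``.``) are rejected.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.warning("record %s: stripping %d stop codon(s)",
                           rec.id, seq.count("*"))
            seq = seq.replace("*", "")
        if "-" in seq or "." in seq:
            raise ValueError(f"record {rec.id!r} contains alignment gaps")
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, description=rec.description,
                                     sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for lo in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[lo:lo + width] + "\n")


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a TSV/CSV with headers and 4-decimal float formatting."""
    if df.empty:
        logger.warning("writing header-only table to %s", path)
    df.to_csv(path, sep=sep, index=False, float_format="%.4f")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, inputs: dict | None = None) -> Path:
    """Record config, seeds, package version and input hashes for a run.

    Everything except the timestamp is a pure function of the run inputs, so
    outputs are regenerable bit-exactly from the manifest.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "zipscore_version": __version__,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in (inputs or {}).items()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
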