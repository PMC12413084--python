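"""Dense score tables over every hexapeptide of an alphabet.

The full canonical table holds one float32 score per hexapeptide, 20**6 =
64,000,000 entries (256 MB), indexed by the base-20 positional code of the
sequence.  Tables are built in batches from a trained model, persisted in a
small self-describing binary format, and can be memory-mapped so that
profiling a proteome never loads the whole table eagerly.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass

import numpy as np

from .alphabet import (
    DEFAULT_ALPHABET,
    AminoAlphabet,
    digits_to_onehot,
    hex_index,
    indices_to_digits,
    indices_to_seqs,
)
from .model import ScoreModel

logger = logging.getLogger(__name__)

_MAGIC = b"ZIPT"
_VERSION = 1


@dataclass
class ScoreTable:
    """Scores for all ``len(alphabet)**6`` hexapeptides plus provenance."""

    scores: np.ndarray            # float32, possibly a memmap
    alphabet: AminoAlphabet = DEFAULT_ALPHABET
    model_id: str = ""

    def __post_init__(self):
        if len(self.scores) != self.alphabet.n_hexapeptides:
            raise ValueError(
                f"table length {len(self.scores)} does not match "
                f"{self.alphabet.size}**6 = {self.alphabet.n_hexapeptides}"
            )

    def __len__(self) -> int:
        return len(self.scores)

    def lookup(self, seq: str) -> float:
        """Stored score of one hexapeptide (validates residues)."""
        return float(self.scores[hex_index(seq, self.alphabet)])

    def lookup_indices(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(self.scores)[indices]

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        header = _pack_header(self.alphabet.letters, self.model_id,
                              len(self.scores))
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(np.ascontiguousarray(
                self.scores, dtype="<f4").tobytes())

    @classmethod
    def load(cls, path, mmap: bool = True) -> "ScoreTable":
        with open(path, "rb") as fh:
            letters, model_id, n, offset = _read_header(fh, path)
        if mmap:
            scores = np.memmap(path, dtype="<f4", mode="r", offset=offset, shape=(n,))
        else:
            scores = np.fromfile(path, dtype="<f4", offset=offset, count=n)
        return cls(scores=scores, alphabet=AminoAlphabet(letters), model_id=model_id)

    def to_csv(self, path, chunk_size: int = 1 << 16) -> None:
        """Interoperability export: ``sequence,score`` (not the canonical format)."""
        with open(path, "w") as fh:
            fh.write("sequence,score\n")
            for lo in range(0, len(self.scores), chunk_size):
                idx = np.arange(lo, min(lo + chunk_size, len(self.scores)))
                seqs = indices_to_seqs(idx, self.alphabet)
                vals = np.asarray(self.scores[lo:lo + len(idx)])
                fh.writelines(f"{s},{v:.4f}\n" for s, v in zip(seqs, vals))


def _pack_header(letters: str, model_id: str, n: int) -> bytes:
    lb = letters.encode("ascii")
    mb = model_id.encode("utf-8")
    return (_MAGIC + struct.pack("<HH", _VERSION, len(lb)) + lb
            + struct.pack("<H", len(mb)) + mb + struct.pack("<Q", n))


def _read_header(fh, path):
    magic = fh.read(4)
    if magic != _MAGIC:
        raise ValueError(f"{path}: not a zipscore table file")
    version, alen = struct.unpack("<HH", fh.read(4))
    if version != _VERSION:
        raise ValueError(f"{path}: unsupported table version {version}")
    letters = fh.read(alen).decode("ascii")
    (mlen,) = struct.unpack("<H", fh.read(2))
    model_id = fh.read(mlen).decode("utf-8")
    (n,) = struct.unpack("<Q", fh.read(8))
    return letters, model_id, n, fh.tell()


def build_table(model: ScoreModel, batch_size: int = 1 << 16,
                log_every: int = 1_000_000) -> ScoreTable:
    """Score every hexapeptide of the model's alphabet.

    Enumeration runs in index order in fixed-size batches so memory stays
    bounded; for the full canonical alphabet this materialises all
    64,000,000 entries.
    """
    alphabet = model.alphabet
    n = alphabet.n_hexapeptides
    scores = np.empty(n, dtype=np.float32)
    next_log = log_every
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        digits = indices_to_digits(np.arange(lo, hi), alphabet)
        scores[lo:hi] = model.predict_onehot(digits_to_onehot(digits, alphabet))
        if hi >= next_log:
            logger.info("scored %d / %d hexapeptides", hi, n)
            next_log += log_every
    return ScoreTable(scores=scores, alphabet=alphabet, model_id=model.model_id())


def negative_score_summary(scores) -> dict | None:
    """Mean and sample sd of the strictly negative scores; None if there are none."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score collection")
    neg = arr[arr < 0]
    if neg.size == 0:
        return None
    sd = float(np.std(neg, ddof=1)) if neg.size > 1 else 0.0
    return {"mean": float(neg.mean()), "sd": sd, "n": int(neg.size)}
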