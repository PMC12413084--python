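"""Amino-acid alphabet, hexapeptide validation, one-hot encoding and base-20 indexing.

Every hexapeptide over an N-letter alphabet maps bijectively to an integer in
``[0, N**6)`` by reading the sequence as a base-N number, most significant
position first.  The full canonical alphabet therefore indexes all
20**6 = 64,000,000 hexapeptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed default ordering used for encodings, indexing and score tables.
CANONICAL_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Length of the scored peptide window.
HEX_LENGTH = 6


class InvalidResidueError(ValueError):
    """A residue outside the alphabet, reported with its 1-based position."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"invalid residue {residue!r} at position {position} "
            f"(not in the alphabet)"
        )


@dataclass(frozen=True)
class AminoAlphabet:
    """Ordered residue alphabet.

    Reduced alphabets (fewer letters) are allowed and used for exhaustive
    oracle checks; the default is the 20 canonical amino acids in the fixed
    order ``ACDEFGHIKLMNPQRSTVWY``.
    """

    letters: str = CANONICAL_ORDER
    _ranks: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self):
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be distinct")
        if not self.letters.isupper() or not self.letters.isalpha():
            raise ValueError("alphabet letters must be uppercase single letters")
        object.__setattr__(
            self, "_ranks", {c: i for i, c in enumerate(self.letters)}
        )

    @property
    def size(self) -> int:
        return len(self.letters)

    @property
    def n_hexapeptides(self) -> int:
        return self.size**HEX_LENGTH

    def rank(self, residue: str) -> int:
        try:
            return self._ranks[residue]
        except KeyError:
            raise InvalidResidueError(residue, 1) from None

    def __contains__(self, residue: str) -> bool:
        return residue in self._ranks

    def __len__(self) -> int:
        return len(self.letters)


DEFAULT_ALPHABET = AminoAlphabet()


def validate_hexapeptide(seq: str, alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> None:
    """Raise :class:`InvalidResidueError` / ``ValueError`` for a malformed hexapeptide."""
    if len(seq) != HEX_LENGTH:
        raise ValueError(f"hexapeptide must have length {HEX_LENGTH}, got {len(seq)}")
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise InvalidResidueError(ch, pos)


def seq_to_digits(seq: str, alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> np.ndarray:
    """Residue ranks of a hexapeptide, shape ``(6,)``."""
    validate_hexapeptide(seq, alphabet)
    return np.array([alphabet.rank(c) for c in seq], dtype=np.int64)


def seqs_to_digits(seqs, alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> np.ndarray:
    """Digit matrix ``(n, 6)`` for a collection of hexapeptides."""
    lut = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(alphabet.letters):
        lut[ord(c)] = i
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    if arr.size != HEX_LENGTH * len(seqs):
        raise ValueError("all sequences must have length 6")
    digits = lut[arr].reshape(len(seqs), HEX_LENGTH)
    if (digits < 0).any():
        row, col = np.argwhere(digits < 0)[0]
        raise InvalidResidueError(seqs[row][col], int(col) + 1)
    return digits


def encode_hexapeptide(seq: str, alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> np.ndarray:
    """One-hot encode a hexapeptide as a flat 6×N binary vector.

    Block ``p`` (0-based) of width ``len(alphabet)`` carries a single 1 at the
    alphabet rank of residue ``p``.
    """
    digits = seq_to_digits(seq, alphabet)
    return digits_to_onehot(digits[None, :], alphabet)[0]


def digits_to_onehot(digits: np.ndarray, alphabet: AminoAlphabet = DEFAULT_ALPHABET,
                     dtype=np.float32) -> np.ndarray:
    """One-hot matrix ``(n, 6 * len(alphabet))`` from a digit matrix ``(n, 6)``."""
    n = digits.shape[0]
    width = HEX_LENGTH * alphabet.size
    out = np.zeros((n, width), dtype=dtype)
    cols = digits + alphabet.size * np.arange(HEX_LENGTH)[None, :]
    out[np.arange(n)[:, None], cols] = 1
    return out


def hex_index(seq: str, alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> int:
    """Base-N positional index of a hexapeptide, position 0 most significant."""
    digits = seq_to_digits(seq, alphabet)
    return int(digits_to_indices(digits[None, :], alphabet)[0])


def index_to_hex(i: int, alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> str:
    """Inverse of :func:`hex_index`."""
    if not 0 <= i < alphabet.n_hexapeptides:
        raise ValueError(
            f"index {i} out of range [0, {alphabet.n_hexapeptides})"
        )
    digits = indices_to_digits(np.array([i], dtype=np.int64), alphabet)[0]
    return "".join(alphabet.letters[d] for d in digits)


def digits_to_indices(digits: np.ndarray, alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> np.ndarray:
    """Vectorized base-N packing of digit rows to indices."""
    base = alphabet.size
    powers = base ** np.arange(HEX_LENGTH - 1, -1, -1, dtype=np.int64)
    return digits.astype(np.int64) @ powers


def indices_to_digits(indices: np.ndarray, alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> np.ndarray:
    """Vectorized base-N unpacking of indices to digit rows ``(n, 6)``."""
    base = alphabet.size
    idx = np.asarray(indices, dtype=np.int64)
    out = np.empty(idx.shape + (HEX_LENGTH,), dtype=np.int64)
    rem = idx.copy()
    for p in range(HEX_LENGTH - 1, -1, -1):
        out[..., p] = rem % base
        rem //= base
    return out


def indices_to_seqs(indices: np.ndarray, alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> list:
    """Hexapeptide strings for an index array."""
    digits = indices_to_digits(indices, alphabet)
    letters = np.frombuffer(alphabet.letters.encode("ascii"), dtype=np.uint8)
    chars = letters[digits]
    return [bytes(row).decode("ascii") for row in chars]
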