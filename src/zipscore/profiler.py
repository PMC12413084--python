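"""Per-protein zipper profiles and the Zif / pAD amyloid metrics.

A protein of length L yields L−5 overlapping hexapeptide windows, each scored
and called a zipper when its score is ≤ −23 REU.  Two summary metrics follow:

* **Zif** (zipper fraction) — the fraction of windows called zippers.
* **pAD** (putative amyloid-forming domain) — the 75-residue stretch holding
  the most zipper segments, reported as that count, the density
  count/window-length, and *all* tied window start positions.  Proteins
  shorter than the window report the whole-protein zipper count instead.

Putative transmembrane stretches (19-mers with mean Kyte–Doolittle hydropathy
above 1.6) can mask zipper segments out of the metrics while the raw calls
remain available: membrane-spanning hydrophobic runs score like zippers but
are presumed sequestered by the bilayer.

All reported coordinates are 1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .alphabet import DEFAULT_ALPHABET, HEX_LENGTH, AminoAlphabet
from .model import ZIPPER_THRESHOLD, ScoreModel
from .table import ScoreTable

#: Length of the hydropathy window used to flag transmembrane stretches.
TM_WINDOW = 19
#: Mean Kyte–Doolittle hydropathy above which a 19-mer is taken as transmembrane.
TM_GRAVY_CUTOFF = 1.6
#: Default pAD window length in residues.
PAD_WINDOW = 75


class NonCanonicalSequenceError(ValueError):
    """Protein contains a residue outside the scoring alphabet.

    Such proteins are withheld from scoring and from every derived metric;
    callers at proteome scale flag the record as unscoreable instead of
    propagating the error.
    """

    def __init__(self, protein_id: str, residue: str, position: int):
        self.protein_id = protein_id
        self.residue = residue
        self.position = position
        super().__init__(
            f"protein {protein_id!r}: non-canonical residue {residue!r} "
            f"at position {position}; profile withheld"
        )


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TMRegion:
    """Maximal union of qualifying 19-mers, 1-based inclusive."""

    start: int
    end: int

    def __post_init__(self):
        if self.end - self.start + 1 < TM_WINDOW:
            raise ValueError(f"TM region [{self.start},{self.end}] shorter than {TM_WINDOW}")


class WindowCall(NamedTuple):
    start: int          # 1-based residue position of the window's first residue
    hexapeptide: str
    score: float
    is_zipper: bool
    reliable: bool
    tm_masked: bool


@dataclass
class ZipperProfile:
    """Scored hexapeptide windows of one protein (vectorised storage)."""

    protein_id: str
    sequence: str
    scores: np.ndarray          # float32, length L-5
    threshold: float = ZIPPER_THRESHOLD
    tm_masked: np.ndarray | None = None
    reliable: np.ndarray = field(default=None)

    def __post_init__(self):
        n = max(len(self.sequence) - HEX_LENGTH + 1, 0)
        if len(self.scores) != n:
            raise ValueError("window count must be max(L-5, 0)")
        if self.reliable is None:
            self.reliable = np.array(
                ["P" not in self.sequence[i:i + HEX_LENGTH] for i in range(n)]
            )
        if self.tm_masked is None:
            self.tm_masked = np.zeros(n, dtype=bool)

    @property
    def n_windows(self) -> int:
        return len(self.scores)

    @property
    def is_zipper(self) -> np.ndarray:
        return np.asarray(self.scores) <= self.threshold

    @property
    def starts(self) -> np.ndarray:
        return np.arange(1, self.n_windows + 1)

    def windows(self) -> Iterator[WindowCall]:
        zip_calls = self.is_zipper
        for i in range(self.n_windows):
            yield WindowCall(
                start=i + 1,
                hexapeptide=self.sequence[i:i + HEX_LENGTH],
                score=float(self.scores[i]),
                is_zipper=bool(zip_calls[i]),
                reliable=bool(self.reliable[i]),
                tm_masked=bool(self.tm_masked[i]),
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows())


@dataclass(frozen=True)
class PADResult:
    window_length: int
    count: int
    density: float
    start_positions: tuple
    whole_protein: bool


# ---------------------------------------------------------------------------
# windowing and scoring


def extract_windows(protein: ProteinRecord,
                    alphabet: AminoAlphabet = DEFAULT_ALPHABET) -> list:
    """All (1-based start, hexapeptide) windows; raises for non-canonical residues."""
    seq = protein.sequence
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise NonCanonicalSequenceError(protein.id, ch, pos)
    return [(i + 1, seq[i:i + HEX_LENGTH])
            for i in range(max(len(seq) - HEX_LENGTH + 1, 0))]


def _window_digits(seq: str, alphabet: AminoAlphabet) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(alphabet.letters):
        lut[ord(c)] = i
    residues = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(seq) - HEX_LENGTH + 1
    return np.lib.stride_tricks.sliding_window_view(residues, HEX_LENGTH)[:n]


def _score_digits(digits: np.ndarray, source) -> np.ndarray:
    from .alphabet import digits_to_indices

    if isinstance(source, ScoreTable):
        return source.lookup_indices(digits_to_indices(digits, source.alphabet))
    if isinstance(source, ScoreModel):
        return source.predict_digits(digits)
    if hasattr(source, "score_indices"):  # synthetic ground-truth scorer
        return source.score_indices(digits_to_indices(digits, source.alphabet))
    raise TypeError(f"cannot score with source of type {type(source).__name__}")


def score_protein(protein: ProteinRecord, source,
                  threshold: float = ZIPPER_THRESHOLD) -> ZipperProfile:
    """Score every hexapeptide window of a protein against a table or model."""
    alphabet = source.alphabet
    extract_windows(protein, alphabet)  # validates residues
    if len(protein) < HEX_LENGTH:
        scores = np.empty(0, dtype=np.float32)
    else:
        digits = _window_digits(protein.sequence, alphabet)
        scores = np.asarray(_score_digits(digits, source), dtype=np.float32)
    return ZipperProfile(protein_id=protein.id, sequence=protein.sequence,
                         scores=scores, threshold=threshold)


# ---------------------------------------------------------------------------
# metrics


def _counted_calls(profile: ZipperProfile, masked: bool,
                   drop_unreliable: bool) -> np.ndarray:
    calls = profile.is_zipper.copy()
    if masked:
        calls &= ~profile.tm_masked
    if drop_unreliable:
        calls &= profile.reliable
    return calls


def compute_zif(profile: ZipperProfile, masked: bool = False,
                drop_unreliable: bool = False) -> float | None:
    """Fraction of hexapeptide windows called zippers.

    The denominator is always the total window count; masking only removes
    calls from the numerator.  Returns None for proteins too short to have a
    window.
    """
    if profile.n_windows == 0:
        return None
    return float(_counted_calls(profile, masked, drop_unreliable).sum()
                 / profile.n_windows)


def compute_pad(profile: ZipperProfile, window_length: int = PAD_WINDOW,
                masked: bool = False, drop_unreliable: bool = False) -> PADResult:
    """Highest zipper-segment count over sliding residue windows.

    A zipper segment counts toward a window when all six of its residues lie
    inside it (segment start s satisfies w ≤ s ≤ w + window_length − 6 for a
    window starting at w).  All tied best starts are reported.  Proteins
    shorter than the window report the whole-protein count.
    """
    if window_length < HEX_LENGTH:
        raise ValueError(f"window_length must be >= {HEX_LENGTH}")
    calls = _counted_calls(profile, masked, drop_unreliable)
    length = len(profile.sequence)
    if length < window_length:
        count = int(calls.sum())
        return PADResult(window_length=window_length, count=count,
                         density=count / window_length,
                         start_positions=(1,), whole_protein=True)
    # indicator over segment starts 1..L-5; window w counts starts in
    # [w, w + window_length - 6] -> sliding sum of width window_length - 5
    width = window_length - HEX_LENGTH + 1
    ind = calls.astype(np.int64)
    n_windows = length - window_length + 1
    if len(ind) < width:  # L >= window_length guarantees len(ind) >= width
        ind = np.pad(ind, (0, width - len(ind)))
    sums = np.convolve(ind, np.ones(width, dtype=np.int64), mode="valid")[:n_windows]
    best = int(sums.max())
    starts = tuple(int(w) for w in np.flatnonzero(sums == best) + 1)
    return PADResult(window_length=window_length, count=best,
                     density=best / window_length,
                     start_positions=starts, whole_protein=False)


# ---------------------------------------------------------------------------
# transmembrane masking


def detect_tm_regions(protein: ProteinRecord) -> list:
    """Maximal unions of 19-mers with mean Kyte–Doolittle hydropathy > 1.6."""
    seq = protein.sequence
    if len(seq) < TM_WINDOW:
        return []
    values = np.array([KYTE_DOOLITTLE[c] for c in seq], dtype=float)
    window_means = (
        np.convolve(values, np.ones(TM_WINDOW), mode="valid") / TM_WINDOW
    )
    qualifying = np.flatnonzero(window_means > TM_GRAVY_CUTOFF) + 1  # 1-based
    regions = []
    for s in qualifying:
        end = int(s) + TM_WINDOW - 1
        if regions and s <= regions[-1][1]:  # overlaps previous union
            regions[-1][1] = end
        else:
            regions.append([int(s), end])
    return [TMRegion(a, b) for a, b in regions]


def apply_tm_mask(profile: ZipperProfile, regions) -> ZipperProfile:
    """Mark windows sharing at least one residue with any TM region.

    Scores and zipper calls are untouched — masking affects only how the
    metrics aggregate, so raw and masked views coexist on the same profile.
    """
    length = len(profile.sequence)
    mask = np.zeros(profile.n_windows, dtype=bool)
    for region in regions:
        if region.start < 1 or region.end > length:
            raise ValueError(
                f"TM region [{region.start},{region.end}] outside sequence "
                f"bounds 1..{length}"
            )
        # window starting at s covers s..s+5; overlap iff s <= end and s+5 >= start
        lo = max(region.start - HEX_LENGTH + 1, 1)
        hi = min(region.end, profile.n_windows)
        if lo <= hi:
            mask[lo - 1:hi] = True
    return ZipperProfile(
        protein_id=profile.protein_id, sequence=profile.sequence,
        scores=profile.scores, threshold=profile.threshold,
        tm_masked=mask | profile.tm_masked, reliable=profile.reliable,
    )
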