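"""Proteome-scale scanning, ranking, correlations, and score–composition analyses.

``scan_proteome`` applies the profiler and the physicochemical metrics to
every FASTA record (splice variants stay separate rows; proteins with
non-canonical residues are kept as flagged, metric-free rows).  The
score-table aggregations — binned mean score versus weighted residue-type
count, per-position per-residue mean scores, and the interface/solvent
charge-placement comparison — stream over the table in fixed-size chunks so
the full 64-million-entry table never has to be held beyond its memory map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import HEX_LENGTH, indices_to_digits
from .model import ZIPPER_THRESHOLD
from .profiler import (
    PAD_WINDOW,
    NonCanonicalSequenceError,
    apply_tm_mask,
    compute_pad,
    compute_zif,
    detect_tm_regions,
    score_protein,
)
from .seqmetrics import (
    DEFAULT_SCHEME,
    PARTITION_GROUPS,
    ResidueTypeScheme,
    compute_metrics,
)
from .table import ScoreTable

logger = logging.getLogger(__name__)


def scan_proteome(records, source, threshold: float = ZIPPER_THRESHOLD,
                  pad_window: int = PAD_WINDOW, mask_tm: bool = True,
                  drop_unreliable: bool = False,
                  scheme: ResidueTypeScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """One row of zipper metrics + physicochemical metrics per protein record.

    Raw and TM-masked Zif/pAD are reported side by side when ``mask_tm`` is
    on.  Unscoreable records (non-canonical residues) keep their row with
    ``unscoreable=True`` and NaN metrics; their count is logged.
    """
    records = list(records)
    if not records:
        raise ValueError("empty proteome: no records to scan")
    rows = []
    n_skipped = 0
    for rec in records:
        row = {"id": rec.id, "length": len(rec.sequence), "unscoreable": False}
        try:
            profile = score_protein(rec, source, threshold)
        except NonCanonicalSequenceError:
            row["unscoreable"] = True
            n_skipped += 1
            rows.append(row)
            continue
        if mask_tm:
            profile = apply_tm_mask(profile, detect_tm_regions(rec))
        row["n_windows"] = profile.n_windows
        row["zif"] = compute_zif(profile, masked=False,
                                 drop_unreliable=drop_unreliable)
        pad = compute_pad(profile, pad_window, masked=False,
                          drop_unreliable=drop_unreliable)
        row["pad_count"] = pad.count
        row["pad_density"] = pad.density
        row["pad_starts"] = ",".join(map(str, pad.start_positions))
        row["pad_whole_protein"] = pad.whole_protein
        if mask_tm:
            row["zif_masked"] = compute_zif(profile, masked=True,
                                            drop_unreliable=drop_unreliable)
            pad_m = compute_pad(profile, pad_window, masked=True,
                                drop_unreliable=drop_unreliable)
            row["pad_count_masked"] = pad_m.count
            row["pad_density_masked"] = pad_m.density
            row["pad_starts_masked"] = ",".join(map(str, pad_m.start_positions))
        metrics = compute_metrics(rec.sequence, scheme)
        row["molecular_weight"] = metrics.molecular_weight
        row["gravy"] = metrics.gravy
        row["aliphatic_index"] = metrics.aliphatic_index
        row["instability_index"] = metrics.instability_index
        row["stability_class"] = metrics.stability_class
        row["net_charge"] = metrics.net_charge
        for group in (*PARTITION_GROUPS, "beta_branched"):
            row[f"pct_{group}"] = metrics.composition[group]
        rows.append(row)
    if n_skipped:
        logger.info("skipped %d protein(s) with non-canonical residues", n_skipped)
    return pd.DataFrame(rows)


def rank_and_summarize(table: pd.DataFrame, metric: str = "zif",
                       top_n: int | None = None, masked: bool = False) -> tuple:
    """Rank scoreable proteins by Zif or pAD and summarise the metric.

    Returns ``(ranked_frame, {"mean", "sd", "n"})``; sd is the sample
    standard deviation (0 for a single protein).  Ties break by id so
    rankings are reproducible.
    """
    if metric not in {"zif", "pad"}:
        raise ValueError("metric must be 'zif' or 'pad'")
    column = {"zif": "zif", "pad": "pad_count"}[metric]
    if masked:
        column += "_masked"
    scoreable = table[~table["unscoreable"]].dropna(subset=[column])
    if scoreable.empty:
        raise ValueError("no scoreable proteins to rank")
    ranked = scoreable.sort_values([column, "id"],
                                   ascending=[False, True], kind="mergesort")
    if top_n is not None:
        ranked = ranked.head(top_n)
    values = scoreable[column].to_numpy(dtype=float)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return ranked.reset_index(drop=True), {
        "mean": float(values.mean()), "sd": sd, "n": int(len(values)),
    }


def pearson_correlation(x, y) -> float | None:
    """Pearson's r; None when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def composition_correlations(table: pd.DataFrame, metric_column: str = "zif",
                             groups=(*PARTITION_GROUPS, "beta_branched")) -> pd.DataFrame:
    """Pearson correlation of a proteome metric against each type percentage."""
    scoreable = table[~table["unscoreable"]].dropna(subset=[metric_column])
    rows = []
    for group in groups:
        r = pearson_correlation(scoreable[f"pct_{group}"], scoreable[metric_column])
        rows.append({"metric": metric_column, "group": group,
                     "r": np.nan if r is None else r, "n": len(scoreable)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# score-table aggregations (streamed)


@dataclass
class _BinAccumulator:
    """Running mean/sd per half-integer bin (bin index = 2 × weighted count)."""

    n_bins: int

    def __post_init__(self):
        self.count = np.zeros(self.n_bins, dtype=np.int64)
        self.total = np.zeros(self.n_bins)
        self.total_sq = np.zeros(self.n_bins)

    def add(self, bins: np.ndarray, values: np.ndarray):
        self.count += np.bincount(bins, minlength=self.n_bins)
        self.total += np.bincount(bins, weights=values, minlength=self.n_bins)
        self.total_sq += np.bincount(bins, weights=values**2, minlength=self.n_bins)

    def frame(self, bin_scale: float = 0.5) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = self.total / self.count
            var = (self.total_sq - self.count * mean**2) / np.maximum(self.count - 1, 1)
        sd = np.sqrt(np.maximum(var, 0.0))
        sd[self.count < 2] = np.where(self.count[self.count < 2] == 1, 0.0, np.nan)
        mean[self.count == 0] = np.nan
        return pd.DataFrame({
            "count": np.arange(self.n_bins) * bin_scale,
            "n": self.count, "mean": mean, "sd": sd,
        })


def _iter_chunks(table: ScoreTable, chunk_size: int):
    n = len(table)
    scores = np.asarray(table.scores)
    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        digits = indices_to_digits(np.arange(lo, hi), table.alphabet)
        yield digits, scores[lo:hi].astype(np.float64)


def score_vs_composition(table: ScoreTable, group: str,
                         scheme: ResidueTypeScheme = DEFAULT_SCHEME,
                         negative_only: bool = False,
                         chunk_size: int = 1 << 20) -> pd.DataFrame:
    """Mean ± sd score binned by the weighted count of a residue-type group.

    Weighted counts (tyrosine counts 0.5 toward aromatic and polar) are
    binned at 0.5 resolution from 0 to 6.  With ``negative_only`` the
    aggregation is restricted to scores < 0.
    """
    weights = scheme.weight_vector(group, table.alphabet.letters)
    acc = _BinAccumulator(n_bins=2 * HEX_LENGTH + 1)
    for digits, values in _iter_chunks(table, chunk_size):
        counts = weights[digits].sum(axis=1)
        bins = np.rint(2 * counts).astype(np.int64)
        if negative_only:
            keep = values < 0
            bins, values = bins[keep], values[keep]
        acc.add(bins, values)
    return acc.frame()


def positional_mean_scores(table: ScoreTable,
                           chunk_size: int = 1 << 20) -> np.ndarray:
    """(A, 6) matrix: mean score of hexapeptides with residue a at position p.

    Over a full table each cell averages ``A**5`` scores.
    """
    a = table.alphabet.size
    totals = np.zeros((HEX_LENGTH, a))
    counts = np.zeros((HEX_LENGTH, a), dtype=np.int64)
    for digits, values in _iter_chunks(table, chunk_size):
        for p in range(HEX_LENGTH):
            totals[p] += np.bincount(digits[:, p], weights=values, minlength=a)
            counts[p] += np.bincount(digits[:, p], minlength=a)
    with np.errstate(invalid="ignore"):
        means = totals / counts
    return means.T


def interface_charge_analysis(table: ScoreTable,
                              interface_positions=(2, 4, 6),
                              scheme: ResidueTypeScheme = DEFAULT_SCHEME,
                              chunk_size: int = 1 << 20) -> dict:
    """Mean score vs charged-residue count at interface vs solvent positions.

    ``interface_positions`` are 1-based hexapeptide positions presumed to
    face the dry zipper interface (default: the even positions); the
    complement faces solvent.  Charged residues are the positive and
    negative type groups combined.
    """
    positions = sorted(set(interface_positions))
    if not positions or not all(1 <= p <= HEX_LENGTH for p in positions) \
            or len(positions) >= HEX_LENGTH:
        raise ValueError(
            "interface_positions must be a non-empty proper subset of 1..6"
        )
    charged = (scheme.weight_vector("positive", table.alphabet.letters)
               + scheme.weight_vector("negative", table.alphabet.letters))
    iface = np.array([p - 1 for p in positions])
    other = np.array([p for p in range(HEX_LENGTH) if p not in set(iface)])
    acc = {"interface": _BinAccumulator(2 * HEX_LENGTH + 1),
           "solvent": _BinAccumulator(2 * HEX_LENGTH + 1)}
    for digits, values in _iter_chunks(table, chunk_size):
        cw = charged[digits]
        acc["interface"].add(
            np.rint(2 * cw[:, iface].sum(axis=1)).astype(np.int64), values)
        acc["solvent"].add(
            np.rint(2 * cw[:, other].sum(axis=1)).astype(np.int64), values)
    return {side: a.frame() for side, a in acc.items()}
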