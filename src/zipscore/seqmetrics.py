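"""Physicochemical and compositional protein metrics (ProtParam conventions).

Molecular weight, GRAVY and the instability index delegate to Biopython's
ProtParam implementation (average isotopic masses + one water; mean
Kyte–Doolittle hydropathy; Guruprasad dipeptide weights).  The aliphatic
index (Ikai 1980 mole-percent formula), residue-type composition with the
tyrosine 0.5/0.5 aromatic–polar split, and the integer net charge are
computed here directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Residue-type groups with per-residue weights.  Tyrosine is half aromatic,
#: half polar.  beta_branched overlaps the others and is excluded from the
#: partition that sums to 100%.
DEFAULT_TYPE_GROUPS: dict = {
    "hydrophobic": {"A": 1, "V": 1, "I": 1, "L": 1, "M": 1},
    "aromatic": {"F": 1, "W": 1, "Y": 0.5},
    "positive": {"H": 1, "K": 1, "R": 1},
    "negative": {"D": 1, "E": 1},
    "polar": {"N": 1, "Q": 1, "S": 1, "T": 1, "Y": 0.5},
    "special": {"C": 1, "G": 1, "P": 1},
    "beta_branched": {"I": 1, "T": 1, "V": 1},
}

#: Groups forming a partition of the canonical alphabet (used for the
#: sums-to-100 invariant and proteome-wide composition columns).
PARTITION_GROUPS = ("hydrophobic", "aromatic", "positive", "negative",
                    "polar", "special")

INSTABILITY_BOUNDARY = 40.0


@dataclass(frozen=True)
class ResidueTypeScheme:
    """Mapping of residue-type names to weighted residue sets."""

    groups: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_GROUPS))

    def weight_vector(self, group: str, letters: str) -> np.ndarray:
        """Per-letter weights of a group over an alphabet string."""
        weights = self.groups[group]
        return np.array([weights.get(c, 0.0) for c in letters], dtype=float)


DEFAULT_SCHEME = ResidueTypeScheme()


def _require_canonical(sequence: str, op: str) -> None:
    if not sequence:
        raise ValueError(f"{op}: empty sequence")
    bad = set(sequence) - CANONICAL_RESIDUES
    if bad:
        raise ValueError(f"{op}: non-canonical residue(s) {sorted(bad)}")


def molecular_weight(sequence: str) -> float:
    """Average-isotopic molecular weight in Da (residue masses + one water)."""
    _require_canonical(sequence, "molecular_weight")
    return float(ProteinAnalysis(sequence).molecular_weight())


def gravy(sequence: str, convention: str = "mean") -> float:
    """Grand average of hydropathy over the Kyte–Doolittle scale.

    ``convention="mean"`` is the ProtParam definition and the default; the
    raw sum is exposed as ``convention="sum"``.
    """
    _require_canonical(sequence, "gravy")
    total = sum(KYTE_DOOLITTLE[c] for c in sequence)
    if convention == "sum":
        return float(total)
    if convention == "mean":
        return float(total / len(sequence))
    raise ValueError(f"unknown GRAVY convention {convention!r}")


def aliphatic_index(sequence: str) -> float:
    """Ikai (1980) aliphatic index: X_A + 2.9·X_V + 3.9·(X_I + X_L).

    X are mole percents; the value estimates the relative volume occupied by
    aliphatic side chains and ranges over [0, 390].
    """
    _require_canonical(sequence, "aliphatic_index")
    n = len(sequence)
    x = {c: 100.0 * sequence.count(c) / n for c in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def instability_index(sequence: str) -> tuple:
    """Guruprasad instability index and its stability class.

    Returns ``(value, "stable" | "unstable")``; values below 40 predict
    in-vitro stability (the boundary itself is classed unstable).
    """
    _require_canonical(sequence, "instability_index")
    if len(sequence) < 2:
        raise ValueError("instability_index: sequence must have length >= 2")
    value = float(ProteinAnalysis(sequence).instability_index())
    return value, ("stable" if value < INSTABILITY_BOUNDARY else "unstable")


def composition_by_residue(sequence: str) -> dict:
    """Percent of each residue relative to total length (non-canonical kept)."""
    if not sequence:
        raise ValueError("composition_by_residue: empty sequence")
    n = len(sequence)
    return {c: 100.0 * sequence.count(c) / n for c in sorted(set(sequence))}


def composition_by_type(sequence: str,
                        scheme: ResidueTypeScheme = DEFAULT_SCHEME) -> dict:
    """Weighted percent composition by residue type.

    Tyrosine contributes weight 0.5 to both the aromatic and polar bins, so
    the partition groups sum to 100% on canonical-only sequences.  Residues
    outside the canonical alphabet are tallied under ``non_canonical``.
    """
    if not sequence:
        raise ValueError("composition_by_type: empty sequence")
    n = len(sequence)
    out = {}
    for group, weights in scheme.groups.items():
        out[group] = 100.0 * sum(weights.get(c, 0.0) for c in sequence) / n
    out["non_canonical"] = (
        100.0 * sum(1 for c in sequence if c not in CANONICAL_RESIDUES) / n
    )
    return out


def net_charge(sequence: str) -> int:
    """Integer net charge: (#H + #K + #R) − (#D + #E).

    Histidine counts +1, consistent with the positive residue-type group;
    this is a counting convention, not a pKa model.
    """
    _require_canonical(sequence, "net_charge")
    pos = sum(sequence.count(c) for c in "HKR")
    neg = sum(sequence.count(c) for c in "DE")
    return pos - neg


@dataclass(frozen=True)
class PhysChemMetrics:
    molecular_weight: float
    gravy: float
    aliphatic_index: float
    instability_index: float
    stability_class: str
    composition: dict
    net_charge: int


def compute_metrics(sequence: str,
                    scheme: ResidueTypeScheme = DEFAULT_SCHEME) -> PhysChemMetrics:
    """All physicochemical metrics for one canonical protein sequence."""
    ii, cls = instability_index(sequence)
    return PhysChemMetrics(
        molecular_weight=molecular_weight(sequence),
        gravy=gravy(sequence),
        aliphatic_index=aliphatic_index(sequence),
        instability_index=ii,
        stability_class=cls,
        composition=composition_by_type(sequence, scheme),
        net_charge=net_charge(sequence),
    )
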