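"""Pairwise distance estimators for nucleotide and protein alignments.

Provides the uncorrected p-distance and the three single-parameter
corrections used throughout the analysis: Jukes–Cantor for nucleotides,
Poisson for amino acids, and Kimura's empirical protein distance for
tree building.  Saturated distances (p beyond the model's domain) are
represented by ``math.inf`` — a value-level marker rather than an
exception, so matrices over divergent sequence sets still build; tree
construction refuses matrices containing saturated entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

SATURATED = math.inf

_NT_AMBIG = frozenset("-N")
_AA_AMBIG = frozenset("-X*")


class DistanceError(ValueError):
    pass


def p_distance(a: str, b: str, ambiguous: Iterable[str] = _NT_AMBIG) -> float:
    """Proportion of differing sites among pairwise-comparable columns.

    Columns where either symbol is a gap or ambiguous character are
    excluded (pairwise deletion).  Raises if no column is comparable.
    """
    if len(a) != len(b):
        raise DistanceError(f"unequal lengths: {len(a)} vs {len(b)}")
    skip = frozenset(ambiguous)
    compared = diffs = 0
    for x, y in zip(a, b):
        if x in skip or y in skip:
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise DistanceError("no comparable columns")
    return diffs / compared


def jc69(p: float) -> float:
    """Jukes–Cantor distance, d = -(3/4) ln(1 - 4p/3); inf when p >= 0.75."""
    if p < 0:
        raise DistanceError(f"p-distance must be non-negative, got {p}")
    if p >= 0.75:
        return SATURATED
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def poisson_aa(p: float) -> float:
    """Poisson-corrected amino-acid distance, d = -ln(1 - p); inf when p >= 1."""
    if p < 0:
        raise DistanceError(f"p-distance must be non-negative, got {p}")
    if p >= 1:
        return SATURATED
    return -math.log1p(-p)


def kimura_protein(p: float) -> float:
    """Kimura's empirical protein distance, d = -ln(1 - p - 0.2 p^2)."""
    if p < 0:
        raise DistanceError(f"p-distance must be non-negative, got {p}")
    x = p + 0.2 * p * p
    if x >= 1:
        return SATURATED
    return -math.log1p(-x)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix; saturated entries are ``inf``."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise DistanceError("matrix shape does not match ids")
        if not np.allclose(np.diag(v), 0):
            raise DistanceError("diagonal must be zero")
        finite = np.isfinite(v)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            v[finite & finite.T], v.T[finite & finite.T]
        ):
            raise DistanceError("matrix must be symmetric")

    @property
    def saturated(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


_METRICS = ("p_nt", "p_aa", "jc69", "poisson", "kimura")


def distance_matrix(
    rows: Sequence[tuple[str, str]], metric: str = "p_nt"
) -> DistanceMatrix:
    """All pairwise distances under the chosen metric.

    ``rows`` are (id, aligned sequence) pairs — nucleotide rows for
    ``p_nt``/``jc69``, amino-acid rows for ``p_aa``/``poisson``/``kimura``.
    Per-pair saturation propagates as ``inf`` entries, not exceptions.
    """
    if metric not in _METRICS:
        raise DistanceError(f"unknown metric {metric!r}; choose from {_METRICS}")
    if len(rows) < 2:
        raise DistanceError("need at least 2 sequences")
    ambiguous = _NT_AMBIG if metric in ("p_nt", "jc69") else _AA_AMBIG
    correct = {
        "p_nt": lambda p: p,
        "p_aa": lambda p: p,
        "jc69": jc69,
        "poisson": poisson_aa,
        "kimura": kimura_protein,
    }[metric]
    n = len(rows)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(rows[i][1], rows[j][1], ambiguous)
            m[i, j] = m[j, i] = correct(p)
    return DistanceMatrix(ids=tuple(r[0] for r in rows), values=m)


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square-format distance matrix (saturated entries as inf)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, rid in enumerate(dm.ids):
            vals = " ".join(f"{v:.8f}" if math.isfinite(v) else "inf" for v in dm.values[i])
            fh.write(f"{rid:<10s} {vals}\n")
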