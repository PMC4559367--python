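"""Column-wise conservation profiles: Shannon entropy and consensus divergence.

Entropy treats the gap as a character in its own right (a 5th character
for nucleotides, a 21st for amino acids), so a column that is entirely
indels within one gene group scores 0 for that group — which makes
per-group profiles over a shared master alignment directly comparable
even where the two genes differ in length.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqcore import GAP, CodonAlignment, protein_rows

logger = logging.getLogger(__name__)

ALPHABET_SIZES = {"nt5": 5, "aa21": 21}


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column Shannon entropy in bits, gap counted as a character."""

    H: np.ndarray
    alphabet: str
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"column": np.arange(1, len(self.H) + 1), "H_bits": self.H})


def shannon_entropy(rows: Sequence[tuple[str, str]], alphabet: str = "nt5") -> EntropyProfile:
    """H = -sum p_c log2 p_c per column over the observed characters.

    The gap is one of the characters, so an all-gap column has a single
    character class and entropy exactly 0.
    """
    if alphabet not in ALPHABET_SIZES:
        raise ValueError(f"alphabet must be one of {sorted(ALPHABET_SIZES)}")
    if not rows:
        raise ValueError("empty alignment")
    length = len(rows[0][1])
    n = len(rows)
    H = np.zeros(length)
    for c in range(length):
        counts = Counter(seq[c] for _, seq in rows)
        # + 0.0 normalises the -0.0 arising from a single character class
        H[c] = -sum((k / n) * math.log2(k / n) for k in counts.values() if k) + 0.0
    return EntropyProfile(H=H, alphabet=alphabet, n_sequences=n)


def group_entropy_profiles(
    rows: Sequence[tuple[str, str]],
    groups: Mapping[str, str],
    alphabet: str = "nt5",
) -> dict[str, EntropyProfile]:
    """One entropy profile per group, on the shared master alignment.

    Columns stay aligned across groups, so profiles can be overlaid; a
    column that is all indels in one group scores 0 in that group's
    profile.
    """
    out: dict[str, EntropyProfile] = {}
    for g in sorted(set(groups.values())):
        sub = [(rid, seq) for rid, seq in rows if groups.get(rid) == g]
        if sub:
            out[g] = shannon_entropy(sub, alphabet)
    return out


def consensus(rows: Sequence[tuple[str, str]], column: int) -> str | None:
    """Most frequent non-gap symbol at a 1-based column; ties alphabetical.

    Returns ``None`` for an all-gap column.
    """
    counts = Counter(seq[column - 1] for _, seq in rows if seq[column - 1] != GAP)
    if not counts:
        return None
    top = max(counts.values())
    return min(sym for sym, k in counts.items() if k == top)


@dataclass(frozen=True)
class SiteDivergence:
    column: int
    consensus: str
    divergent_fraction: float
    composition: tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class DivergenceSiteReport:
    sites: tuple[SiteDivergence, ...]
    threshold: float
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "column": s.column,
                    "consensus": s.consensus,
                    "divergent_fraction": s.divergent_fraction,
                    "composition": ";".join(f"{sym}:{k}" for sym, k in s.composition),
                }
                for s in self.sites
            ],
            columns=["column", "consensus", "divergent_fraction", "composition"],
        )


def divergence_sites(
    rows: Sequence[tuple[str, str]],
    threshold: float = 0.05,
    min_coverage: int = 1,
) -> DivergenceSiteReport:
    """Columns where at least ``threshold`` of sequences differ from consensus.

    Gaps are excluded from both numerator and denominator; the boundary is
    inclusive ("at least").  Columns with fewer than ``min_coverage``
    non-gap symbols are skipped with a log message.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    length = len(rows[0][1])
    sites: list[SiteDivergence] = []
    for col in range(1, length + 1):
        counts = Counter(seq[col - 1] for _, seq in rows if seq[col - 1] != GAP)
        covered = sum(counts.values())
        if covered < min_coverage:
            logger.debug("column %d below coverage %d; skipped", col, min_coverage)
            continue
        cons = consensus(rows, col)
        divergent = covered - counts[cons]
        frac = divergent / covered
        if frac >= threshold and divergent > 0:
            sites.append(
                SiteDivergence(
                    column=col,
                    consensus=cons,
                    divergent_fraction=frac,
                    composition=tuple(sorted(counts.items())),
                )
            )
    return DivergenceSiteReport(
        sites=tuple(sites), threshold=threshold, n_sequences=len(rows)
    )


def protein_divergence_sites(
    aln: CodonAlignment, ids: Sequence[str], threshold: float = 0.05, code: int = 1
) -> DivergenceSiteReport:
    """Amino-acid divergence sites for a subset of a codon alignment."""
    aa = protein_rows(aln.subset(ids), code)
    return divergence_sites(list(aa.records), threshold=threshold)
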