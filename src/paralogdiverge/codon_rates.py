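"""Nei–Gojobori (NG86) synonymous/nonsynonymous rate estimation.

The NG86 method summarises selection on a pair of coding sequences by
counting, per codon, the fractional numbers of synonymous (S) and
nonsynonymous (N) *sites* — how many of the nine single-nucleotide
neighbours of the codon preserve the encoded amino acid — and, per
differing codon pair, the synonymous and nonsynonymous *differences*
(Sd, Nd), averaging over every mutational pathway between the two
codons.  The proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor
corrected to Ks and Ka; their ratio estimates the selection intensity
omega (Ka/Ks << 1: purifying selection, ~1: neutrality).

Conventions (kept MEGA-comparable):

* mutations creating stop codons count as nonsynonymous in the site
  fractions, so syn + nonsyn sites = 3 per codon;
* pathways passing through a stop codon are excluded from the pathway
  average, renormalising over the remaining orderings;
* codon pairs whose every pathway crosses a stop are excluded from both
  the difference and site totals (logged);
* undefined ratios (Ks = 0) are ``None`` end-to-end — never 0 or inf.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distances import distance_matrix, jc69
from .seqcore import GAP, CodonAlignment, protein_rows, stop_codons, translate_codon

logger = logging.getLogger(__name__)

_NUCS = "ACGT"


class RateError(ValueError):
    pass


@dataclass(frozen=True)
class CodonSiteCount:
    codon: str
    syn_sites: float
    nonsyn_sites: float


@lru_cache(maxsize=None)
def count_sites(codon: str, code: int = 1) -> CodonSiteCount:
    """Fractional synonymous/nonsynonymous site counts of one codon.

    Each of the nine single-nucleotide neighbours is classified under the
    active genetic code; neighbours that are stop codons count as
    nonsynonymous, so the two fractions always sum to 3.
    """
    _validate_codon(codon, code)
    aa = translate_codon(codon, code)
    syn = 0.0
    for pos in range(3):
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant not in stop_codons(code) and translate_codon(mutant, code) == aa:
                syn += 1.0 / 3.0
    return CodonSiteCount(codon=codon, syn_sites=syn, nonsyn_sites=3.0 - syn)


def _validate_codon(codon: str, code: int) -> None:
    if len(codon) != 3 or any(c not in _NUCS for c in codon):
        raise RateError(f"not an unambiguous codon: {codon!r}")
    if codon in stop_codons(code):
        raise RateError(f"stop codon {codon!r} not allowed")


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str, code: int = 1) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    For codons differing at k positions, every one of the k! orderings of
    single-nucleotide steps is walked; orderings whose intermediate (or
    final-step) codon is a stop are discarded and the average is taken
    over the remaining pathways, so syn + nonsyn = k exactly.  Returns
    ``None`` when every pathway is blocked by a stop codon (the caller
    excludes such codon pairs).
    """
    _validate_codon(codon_a, code)
    _validate_codon(codon_b, code)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return (0.0, 0.0)
    stops = stop_codons(code)
    valid = 0
    syn_total = nonsyn_total = 0.0
    for order in itertools.permutations(diff_pos):
        current = codon_a
        path_syn = path_nonsyn = 0.0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in stops:
                ok = False
                break
            if translate_codon(nxt, code) == translate_codon(current, code):
                path_syn += 1
            else:
                path_nonsyn += 1
            current = nxt
        if ok:
            valid += 1
            syn_total += path_syn
            nonsyn_total += path_nonsyn
    if valid == 0:
        return None
    return (syn_total / valid, nonsyn_total / valid)


@dataclass(frozen=True)
class PairwiseRates:
    """NG86 output for one sequence pair."""

    id_a: str
    id_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    codons_compared: int

    @property
    def pS(self) -> float:
        return self.Sd / self.S

    @property
    def pN(self) -> float:
        return self.Nd / self.N

    @property
    def Ks(self) -> float:
        return jc69(self.pS)

    @property
    def Ka(self) -> float:
        return jc69(self.pN)

    @property
    def ratio(self) -> float | None:
        ks, ka = self.Ks, self.Ka
        if ks == 0 or not math.isfinite(ks) or not math.isfinite(ka):
            return None
        return ka / ks


def pairwise_ng86(
    aln: CodonAlignment, id_a: str, id_b: str, code: int = 1
) -> PairwiseRates:
    """NG86 rates for one pair of rows of a codon alignment.

    Codon columns with a gap, an N, or a stop codon in either row are
    skipped, as are pairs whose every mutational pathway crosses a stop.
    """
    ca, cb = aln.codons(id_a), aln.codons(id_b)
    stops = stop_codons(code)
    S = N = Sd = Nd = 0.0
    compared = 0
    for col, (x, y) in enumerate(zip(ca, cb), start=1):
        if GAP in x or GAP in y or "N" in x or "N" in y:
            continue
        if x in stops or y in stops:
            logger.debug("skipping stop codon at column %d (%s/%s)", col, id_a, id_b)
            continue
        d = count_differences(x, y, code)
        if d is None:
            logger.warning(
                "column %d (%s vs %s): every pathway %s->%s crosses a stop; excluded",
                col, id_a, id_b, x, y,
            )
            continue
        sx, sy = count_sites(x, code), count_sites(y, code)
        S += 0.5 * (sx.syn_sites + sy.syn_sites)
        N += 0.5 * (sx.nonsyn_sites + sy.nonsyn_sites)
        Sd += d[0]
        Nd += d[1]
        compared += 1
    if compared == 0:
        raise RateError(f"no comparable codons between {id_a} and {id_b}")
    return PairwiseRates(id_a=id_a, id_b=id_b, S=S, N=N, Sd=Sd, Nd=Nd, codons_compared=compared)


@dataclass(frozen=True)
class RateSummary:
    """Per-group means of the five rate statistics.

    ``mean_kaks`` is the mean of per-pair Ka/Ks ratios (not the ratio of
    mean Ka to mean Ks); pairs with an undefined ratio are excluded from
    that mean and counted in ``n_undefined_ratios``.
    """

    group: str
    mean_nt_rate: float
    mean_aa_rate: float
    mean_ka: float
    mean_ks: float
    mean_kaks: float | None
    n_pairs: int
    n_undefined_ratios: int
    codons_analysed: int


def rate_summary(
    aln: CodonAlignment,
    group_ids: Sequence[str],
    label: str = "",
    code: int = 1,
    complete_deletion: bool = True,
) -> RateSummary:
    """Whole-group rate battery over all within-group pairs.

    With ``complete_deletion`` (the default for table-style summaries),
    codon columns containing any gap or N in any group member are removed
    first; ``codons_analysed`` reports the retained count.
    """
    from .seqcore import complete_codon_columns

    if len(group_ids) < 2:
        raise RateError("rate_summary needs at least 2 in-group sequences")
    sub = aln.subset(group_ids)
    if complete_deletion:
        sub = complete_codon_columns(sub)
    nt_rows = [(rid, sub.row(rid)) for rid in group_ids]
    aa = protein_rows(sub, code)
    aa_rows = [(rid, aa.row(rid)) for rid in group_ids]
    nt_dm = distance_matrix(nt_rows, "jc69")
    aa_dm = distance_matrix(aa_rows, "poisson")
    kas, kss, ratios = [], [], []
    n_undef = 0
    for i, j in itertools.combinations(range(len(group_ids)), 2):
        pr = pairwise_ng86(sub, group_ids[i], group_ids[j], code)
        kas.append(pr.Ka)
        kss.append(pr.Ks)
        if pr.ratio is None:
            n_undef += 1
        else:
            ratios.append(pr.ratio)
    if n_undef:
        logger.info("%s: %d pair(s) with undefined Ka/Ks excluded from the ratio mean",
                    label or "group", n_undef)
    n_pairs = len(kas)
    iu = np.triu_indices(len(group_ids), k=1)
    return RateSummary(
        group=label,
        mean_nt_rate=float(np.mean(nt_dm.values[iu])),
        mean_aa_rate=float(np.mean(aa_dm.values[iu])),
        mean_ka=float(np.mean(kas)),
        mean_ks=float(np.mean(kss)),
        mean_kaks=float(np.mean(ratios)) if ratios else None,
        n_pairs=n_pairs,
        n_undefined_ratios=n_undef,
        codons_analysed=sub.n_codons,
    )


def rate_contrast(summary_a: RateSummary, summary_b: RateSummary) -> float:
    """Ratio of the two groups' mean Ka/Ks ratios (group a over group b)."""
    if summary_a.mean_kaks is None or summary_b.mean_kaks is None:
        raise RateError("both groups need a defined mean Ka/Ks")
    if summary_b.mean_kaks == 0:
        raise RateError("denominator group has mean Ka/Ks = 0")
    return summary_a.mean_kaks / summary_b.mean_kaks


@dataclass(frozen=True)
class KaKsProfile:
    """Per-codon-column pooled NG86 counts and the column Ka/Ks values.

    Counts are pooled over all requested pairs (single-pair single-codon
    ratios are almost always 0/0); the column ratio is
    (Nd/N)/(Sd/S) with no distance correction at single-column scale.
    ``ratio[c]`` is ``None`` (undefined, distinct from 0) where pooled
    Sd = 0 or no pair is comparable at the column.
    """

    columns: tuple[int, ...]  # 1-based codon columns
    Sd: np.ndarray
    Nd: np.ndarray
    S: np.ndarray
    N: np.ndarray
    n_pairs: np.ndarray
    ratio: tuple[float | None, ...]
    window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon_column": self.columns,
                "nt_offset": [3 * (c - 1) for c in self.columns],
                "Sd": self.Sd,
                "Nd": self.Nd,
                "S": self.S,
                "N": self.N,
                "n_pairs": self.n_pairs,
                "kaks": [r if r is not None else np.nan for r in self.ratio],
            }
        )


def per_codon_profile(
    aln: CodonAlignment,
    pairs: Iterable[tuple[str, str]],
    window: int = 1,
    code: int = 1,
) -> KaKsProfile:
    """Ka/Ks profile along the alignment from pooled pairwise counts.

    ``window`` (odd, >= 1) pools counts over a centred window of codon
    columns before forming the ratio; the default 1 evaluates each codon
    on its own.
    """
    if window < 1 or window % 2 == 0:
        raise RateError("window must be an odd integer >= 1")
    pairs = list(pairs)
    nc = aln.n_codons
    Sd = np.zeros(nc)
    Nd = np.zeros(nc)
    S = np.zeros(nc)
    N = np.zeros(nc)
    n_pairs = np.zeros(nc, dtype=int)
    stops = stop_codons(code)
    codon_rows = {rid: aln.codons(rid) for rid in {i for p in pairs for i in p}}
    for id_a, id_b in pairs:
        ca, cb = codon_rows[id_a], codon_rows[id_b]
        for c in range(nc):
            x, y = ca[c], cb[c]
            if GAP in x or GAP in y or "N" in x or "N" in y or x in stops or y in stops:
                continue
            d = count_differences(x, y, code)
            if d is None:
                continue
            sx, sy = count_sites(x, code), count_sites(y, code)
            S[c] += 0.5 * (sx.syn_sites + sy.syn_sites)
            N[c] += 0.5 * (sx.nonsyn_sites + sy.nonsyn_sites)
            Sd[c] += d[0]
            Nd[c] += d[1]
            n_pairs[c] += 1
    half = window // 2
    ratios: list[float | None] = []
    for c in range(nc):
        lo, hi = max(0, c - half), min(nc, c + half + 1)
        sd, nd = Sd[lo:hi].sum(), Nd[lo:hi].sum()
        s, n = S[lo:hi].sum(), N[lo:hi].sum()
        if n_pairs[lo:hi].sum() == 0 or sd == 0 or s == 0 or n == 0:
            ratios.append(None)
        else:
            ratios.append(float((nd / n) / (sd / s)))
    cols = aln.source_columns or tuple(range(1, nc + 1))
    return KaKsProfile(
        columns=tuple(cols), Sd=Sd, Nd=Nd, S=S, N=N,
        n_pairs=n_pairs, ratio=tuple(ratios), window=window,
    )
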