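"""End-to-end analysis of a two-paralog family.

Runs the full battery on a labelled codon alignment: per-group rate
summaries (nucleotide, amino-acid, Ka, Ks, mean Ka/Ks), the Ka/Ks
ratio-of-ratios contrast with a per-column significance test, per-codon
Ka/Ks profiles, per-group entropy profiles and divergence sites, NJ
trees at the nucleotide and protein level with the clade branch-length
contrast, and (when a size table is supplied) the gene-size contrast.

The contrast significance test is a paired Wilcoxon signed-rank across
codon columns on pooled per-site nonsynonymous (resp. synonymous)
difference rates of the two groups: columns evolve nearly independently,
so pairing by column gives a calibrated test even though pairwise
sequence comparisons within a group are strongly correlated.  Because a
run tests several contrasts at once, the report's boolean flags apply a
Holm-Bonferroni correction so the chance of any false flag across the
battery stays at the configured alpha; the raw p-values are reported
alongside.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from . import __version__
from .codon_rates import KaKsProfile, RateSummary, per_codon_profile, rate_contrast, rate_summary
from .distances import distance_matrix
from .profiles import DivergenceSiteReport, EntropyProfile, group_entropy_profiles, protein_divergence_sites
from .seqcore import (
    CodonAlignment,
    GeneSizeTable,
    complete_codon_columns,
    protein_rows,
    read_fasta,
    read_gene_sizes,
    read_metadata,
)
from .trees import CladeRateContrast, PhyloTree, clade_contrast, nj_tree, write_newick

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Plain-text (YAML) configuration of one pipeline run."""

    fasta: str = ""
    metadata: str = ""
    gene_sizes: str = ""
    groups: tuple[str, str] = ("P1", "P2")
    clade: str = ""  # restrict to one clade label; empty = all
    exclude: tuple[str, ...] = ()  # ids dropped before any analysis
    code: int = 1
    divergence_threshold: float = 0.05
    profile_window: int = 1
    tree_metric: str = "kimura"
    alpha: float = 0.05
    seed: int = 0
    outdir: str = ""

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("groups", "exclude"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    summaries: dict[str, RateSummary]
    kaks_contrast: float | None
    ka_contrast_p: float
    ks_contrast_p: float
    profiles: dict[str, KaKsProfile]
    entropy_nt: dict[str, EntropyProfile]
    entropy_aa: dict[str, EntropyProfile]
    divergence: dict[str, DivergenceSiteReport]
    tree_protein: PhyloTree
    tree_nucleotide: PhyloTree
    clade_contrast_protein: CladeRateContrast
    clade_contrast_nucleotide: CladeRateContrast
    gene_size_fold: float | None
    gene_size_p: float | None
    flags: dict[str, bool]
    provenance: dict[str, object]


def gene_size_contrast(
    table: GeneSizeTable, group_a: str = "P1", group_b: str = "P2"
) -> tuple[float, float]:
    """Geometric-mean fold (b over a) and Welch p-value on log sizes.

    Gene sizes span orders of magnitude, so location is compared on the
    log scale; the fold is the ratio of geometric means.
    """
    a = np.asarray(table.sizes(group_a), dtype=float)
    b = np.asarray(table.sizes(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise PipelineError("gene_size_contrast needs >= 2 sizes per group")
    la, lb = np.log(a), np.log(b)
    fold = float(np.exp(lb.mean() - la.mean()))
    if np.allclose(la.std(), 0) and np.allclose(lb.std(), 0) and np.isclose(la.mean(), lb.mean()):
        return fold, 1.0
    p = float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
    return fold, p


def _per_column_rate_test(
    aln: CodonAlignment,
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    code: int,
    kind: str,
) -> float:
    """Paired Wilcoxon across codon columns on pooled per-site difference
    rates (kind = 'nonsyn' or 'syn') of the two groups."""
    pairs_a = list(itertools.combinations(ids_a, 2))
    pairs_b = list(itertools.combinations(ids_b, 2))
    prof_a = per_codon_profile(aln, pairs_a, code=code)
    prof_b = per_codon_profile(aln, pairs_b, code=code)
    if kind == "nonsyn":
        xa = np.divide(prof_a.Nd, prof_a.N, out=np.zeros_like(prof_a.Nd), where=prof_a.N > 0)
        xb = np.divide(prof_b.Nd, prof_b.N, out=np.zeros_like(prof_b.Nd), where=prof_b.N > 0)
    else:
        xa = np.divide(prof_a.Sd, prof_a.S, out=np.zeros_like(prof_a.Sd), where=prof_a.S > 0)
        xb = np.divide(prof_b.Sd, prof_b.S, out=np.zeros_like(prof_b.Sd), where=prof_b.S > 0)
    usable = (prof_a.n_pairs > 0) & (prof_b.n_pairs > 0)
    diff = xa[usable] - xb[usable]
    diff = diff[diff != 0]
    if len(diff) < 6:
        return 1.0
    return float(stats.wilcoxon(diff).pvalue)


def _holm_flags(pvals: Mapping[str, float], alpha: float) -> dict[str, bool]:
    """Holm-Bonferroni step-down rejection decisions at family-wise alpha."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    flags: dict[str, bool] = {}
    rejecting = True
    for rank, (name, p) in enumerate(items):
        rejecting = rejecting and p < alpha / (m - rank)
        flags[name] = rejecting
    return flags


def analyze_family(
    aln: CodonAlignment,
    gene_sizes: GeneSizeTable | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the whole battery on an in-memory labelled codon alignment."""
    cfg = config or AnalysisConfig()
    ga, gb = cfg.groups
    work = aln
    if cfg.exclude:
        keep = [i for i in work.ids if i not in set(cfg.exclude)]
        if not keep:
            raise PipelineError("all sequences excluded")
        work = work.subset(keep)
    if cfg.clade:
        ids = [i for i in work.ids if work.meta[i].clade == cfg.clade]
        work = work.subset(ids)
    ids_a = work.ids_by(paralog=ga)
    ids_b = work.ids_by(paralog=gb)
    for label, ids in ((ga, ids_a), (gb, ids_b)):
        if len(ids) < 2:
            raise PipelineError(f"group {label!r} has fewer than 2 sequences after filtering")

    summaries = {
        ga: rate_summary(work, ids_a, label=ga, code=cfg.code),
        gb: rate_summary(work, ids_b, label=gb, code=cfg.code),
    }
    try:
        contrast = rate_contrast(summaries[ga], summaries[gb])
    except Exception:
        contrast = None
    ka_p = _per_column_rate_test(work, ids_a, ids_b, cfg.code, "nonsyn")
    ks_p = _per_column_rate_test(work, ids_a, ids_b, cfg.code, "syn")

    profiles = {
        g: per_codon_profile(work, list(itertools.combinations(ids, 2)),
                             window=cfg.profile_window, code=cfg.code)
        for g, ids in ((ga, ids_a), (gb, ids_b))
    }
    groups_map = {i: work.meta[i].paralog for i in work.ids if i in work.meta}
    entropy_nt = group_entropy_profiles(list(work.records), groups_map, "nt5")
    aa_aln = protein_rows(work, cfg.code)
    entropy_aa = group_entropy_profiles(list(aa_aln.records), groups_map, "aa21")
    divergence = {
        g: protein_divergence_sites(work, ids, threshold=cfg.divergence_threshold, code=cfg.code)
        for g, ids in ((ga, ids_a), (gb, ids_b))
    }

    # trees on gap-free columns across all retained sequences
    core = complete_codon_columns(work)
    aa_core = protein_rows(core, cfg.code)
    dm_aa = distance_matrix(list(aa_core.records), cfg.tree_metric)
    dm_nt = distance_matrix(list(core.records), "jc69")
    tree_aa = nj_tree(dm_aa)
    tree_nt = nj_tree(dm_nt)
    cc_aa = clade_contrast(tree_aa, groups_map)
    cc_nt = clade_contrast(tree_nt, groups_map)

    fold = size_p = None
    if gene_sizes is not None:
        fold, size_p = gene_size_contrast(gene_sizes, ga, gb)

    # the run tests a battery of contrasts; flags control the family-wise
    # error across them (Holm-Bonferroni) at cfg.alpha
    pvals = {"kaks_contrast": ka_p, "ks_contrast": ks_p}
    if size_p is not None:
        pvals["gene_size"] = size_p
    flags = _holm_flags(pvals, cfg.alpha)
    flags.setdefault("gene_size", False)
    provenance = {
        "package_version": __version__,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "n_sequences": len(work.ids),
        "groups": {ga: len(ids_a), gb: len(ids_b)},
    }
    return AnalysisReport(
        summaries=summaries,
        kaks_contrast=contrast,
        ka_contrast_p=ka_p,
        ks_contrast_p=ks_p,
        profiles=profiles,
        entropy_nt=entropy_nt,
        entropy_aa=entropy_aa,
        divergence=divergence,
        tree_protein=tree_aa,
        tree_nucleotide=tree_nt,
        clade_contrast_protein=cc_aa,
        clade_contrast_nucleotide=cc_nt,
        gene_size_fold=fold,
        gene_size_p=size_p,
        flags=flags,
        provenance=provenance,
    )


def summary_table(report: AnalysisReport) -> "pd.DataFrame":
    """Table-style rate summary: rows = statistics, columns = groups."""
    import pandas as pd

    cols = {}
    for g, s in report.summaries.items():
        cols[g] = {
            "codons_analysed": s.codons_analysed,
            "nucleotide_rate_jc": s.mean_nt_rate,
            "amino_acid_rate_poisson": s.mean_aa_rate,
            "Ka": s.mean_ka,
            "Ks": s.mean_ks,
            "Ka/Ks (mean of pairwise ratios)": s.mean_kaks,
        }
    df = pd.DataFrame(cols)
    df.loc["Ka/Ks ratio-of-ratios"] = [report.kaks_contrast] + [None] * (len(cols) - 1)
    return df


def write_report(report: AnalysisReport, outdir: str | Path, config: AnalysisConfig) -> None:
    """Write every stage's output as plain-text tables plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary_table(report).to_csv(out / "rate_summary.tsv", sep="\t")
    for g, prof in report.profiles.items():
        prof.to_frame().to_csv(out / f"kaks_profile_{g}.tsv", sep="\t", index=False)
    for g, ep in report.entropy_nt.items():
        ep.to_frame().to_csv(out / f"entropy_nt_{g}.tsv", sep="\t", index=False)
    for g, ep in report.entropy_aa.items():
        ep.to_frame().to_csv(out / f"entropy_aa_{g}.tsv", sep="\t", index=False)
    for g, dv in report.divergence.items():
        dv.to_frame().to_csv(out / f"divergence_sites_{g}.tsv", sep="\t", index=False)
    write_newick(report.tree_protein, out / "tree_protein.nwk")
    write_newick(report.tree_nucleotide, out / "tree_nucleotide.nwk")
    lines = [
        f"Ka/Ks ratio-of-ratios: {report.kaks_contrast}",
        f"Ka contrast p (per-column Wilcoxon): {report.ka_contrast_p:.4g}",
        f"Ks contrast p (per-column Wilcoxon): {report.ks_contrast_p:.4g}",
        f"protein-tree depth ratio: {report.clade_contrast_protein.ratio}",
        f"nucleotide-tree depth ratio: {report.clade_contrast_nucleotide.ratio}",
        f"gene-size fold: {report.gene_size_fold}  p: {report.gene_size_p}",
        f"flags: {report.flags}",
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    manifest = {"provenance": report.provenance, "flags": report.flags}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    config.to_yaml(out / "config_used.yaml")


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Load inputs per the config, run :func:`analyze_family`, write outputs.

    Input nucleotide FASTA must already be a codon alignment (equal-length
    rows, frame-respecting gaps) — either externally aligned and
    back-translated, or produced by the simulator.
    """
    if not config.fasta or not config.metadata:
        raise PipelineError("config must name fasta and metadata inputs")
    meta = read_metadata(config.metadata)
    records = read_fasta(config.fasta, meta, code=config.code)
    if not records:
        raise PipelineError("no usable sequences in input")
    lengths = {len(r.nucleotides) for r in records}
    if len(lengths) != 1:
        raise PipelineError("input FASTA rows are not aligned (unequal lengths)")
    aln = CodonAlignment(
        records=tuple((r.id, r.nucleotides) for r in records),
        meta={r.id: r for r in records},
    )
    sizes = read_gene_sizes(config.gene_sizes) if config.gene_sizes else None
    report = analyze_family(aln, gene_sizes=sizes, config=config)
    if config.outdir:
        write_report(report, config.outdir, config)
    return report
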