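"""Codon-evolution simulator for duplicated gene families.

Generates column-true codon alignments along a species tree under an
acceptance/rejection codon process: nucleotide changes are proposed with
an optional transition/transversion bias kappa, proposals creating stop
codons are rejected, synonymous proposals are always accepted, and
nonsynonymous proposals are accepted with probability omega.  At low
divergence the expected pairwise Ka/Ks therefore equals omega — the
quantity the NG86 estimator targets — with no rate-matrix machinery.

Branch lengths are parameterised in expected synonymous substitutions
per synonymous site, so "equal Ks, different Ka" scenarios (the
signature of asymmetric paralog evolution) are built by sharing one
branch-length scale between two clades with different omega.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqcore import CodonAlignment, GeneSizeTable, SequenceRecord, sense_codons, stop_codons, translate_codon
from .trees import Node, PhyloTree, read_newick

_NUCS = "ACGT"
_TRANSITions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated clade.

    ``tree_length`` is the sum of all branch lengths in expected
    synonymous substitutions per synonymous site; ``omega`` <= 1 (the
    purifying-selection regime this generator supports).
    """

    n_taxa: int = 14
    n_codons: int = 300
    omega: float = 0.08
    kappa: float = 1.0
    tree_length: float = 0.5
    tree: str | None = None  # newick; generated when None
    stem_length: float = 0.5  # duplication-to-clade-root branch (paralog families)
    indel_rate: float = 0.0  # codon deletions per codon per unit branch length
    seed: int = 0
    code: int = 1

    def __post_init__(self):
        if self.omega < 0:
            raise SimulationError("omega must be >= 0")
        if self.omega > 1:
            raise SimulationError("omega > 1 (positive selection) is not supported")
        if self.kappa <= 0:
            raise SimulationError("kappa must be > 0")
        if self.n_codons < 1:
            raise SimulationError("n_codons must be >= 1")


@dataclass(frozen=True)
class SubstitutionEvent:
    branch: str  # name of the child node of the branch
    codon_index: int  # 0-based
    from_codon: str
    to_codon: str


@dataclass
class SimulatedFamily:
    alignment: CodonAlignment
    trees: dict[str, PhyloTree]
    true_omega: dict[str, float]
    events: list[SubstitutionEvent]
    deletions: dict[str, frozenset[int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# random trees

def random_tree(n_taxa: int, rng: np.random.Generator, tree_length: float = 0.5,
                prefix: str = "sp") -> PhyloTree:
    """Random bifurcating tree (Yule-like: uniform random joins, exponential
    branch lengths) rescaled so the branch lengths sum to ``tree_length``."""
    if n_taxa < 2:
        raise SimulationError("need at least 2 taxa")
    nodes = [Node(name=f"{prefix}{i + 1:02d}", length=float(rng.exponential(1.0)))
             for i in range(n_taxa)]
    k = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        k += 1
        parent = Node(name=f"n{k}", length=float(rng.exponential(1.0)),
                      children=[nodes[i], nodes[j]])
        nodes = [x for t, x in enumerate(nodes) if t not in (i, j)] + [parent]
    root = Node(name="root", children=nodes)
    tree = PhyloTree(root=root)
    total = tree.total_length()
    scale = tree_length / total

    def rescale(n: Node):
        if n.length is not None:
            n.length *= scale
        for c in n.children:
            rescale(c)

    rescale(root)
    return tree


# ---------------------------------------------------------------------------
# the codon process

def _neighbor_table(codon: str, kappa: float, omega: float, code: int):
    """Accepted-event rates for the nine single-nucleotide neighbours.

    Per position the three proposals carry weights kappa (transition) and
    1 (each transversion), normalised by (kappa + 2) so each nucleotide
    site proposes at rate 1; stop proposals get rate 0 and nonsynonymous
    ones are thinned by omega.  Returns (events, total_rate, syn_flux)
    where events are (rate, new_codon, is_synonymous).
    """
    aa = translate_codon(codon, code)
    stops = stop_codons(code)
    events = []
    total = syn_flux = 0.0
    for pos in range(3):
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            w = kappa if (codon[pos], nt) in _TRANSITions else 1.0
            rate = w / (kappa + 2.0)
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in stops:
                continue
            is_syn = translate_codon(mutant, code) == aa
            if is_syn:
                syn_flux += rate
            else:
                rate *= omega
                if rate == 0.0:
                    continue
            events.append((rate, mutant, is_syn))
            total += rate
    return events, total, syn_flux


class _CodonProcess:
    """Per-simulation cache of neighbour tables plus Gillespie stepping."""

    def __init__(self, kappa: float, omega: float, code: int):
        self.kappa, self.omega, self.code = kappa, omega, code
        self._cache: dict[str, tuple] = {}
        from .codon_rates import count_sites
        self._syn_sites = {c: count_sites(c, code).syn_sites for c in sense_codons(code)}

    def table(self, codon: str):
        t = self._cache.get(codon)
        if t is None:
            t = _neighbor_table(codon, self.kappa, self.omega, self.code)
            self._cache[codon] = t
        return t

    def evolve_branch(self, seq: list[str], t: float, rng: np.random.Generator,
                      log: list, branch_name: str) -> list[str]:
        """Evolve a codon sequence in place along a branch of length t.

        Time is rescaled event-by-event so that the instantaneous
        synonymous substitution rate per NG86 synonymous site is exactly
        one per unit branch length (for kappa = 1 the rescaling factor is
        identically 1).
        """
        seq = list(seq)
        rates = np.array([self.table(c)[1] for c in seq])
        syn_flux = sum(self.table(c)[2] for c in seq)
        syn_sites = sum(self._syn_sites[c] for c in seq)
        elapsed = 0.0
        while True:
            total = rates.sum()
            if total <= 0:
                break
            # one unit of branch length = one expected synonymous substitution
            # per synonymous site, i.e. syn_flux/syn_sites must integrate to t;
            # waiting times are Exp(total) in proposal units, converted by the
            # current flux-to-site ratio (exactly 1 when kappa = 1)
            convert = (syn_flux / syn_sites) if syn_sites > 0 and syn_flux > 0 else 1.0
            dt = rng.exponential(1.0 / total) * convert
            elapsed += dt
            if elapsed > t:
                break
            idx = rng.choice(len(seq), p=rates / total)
            events, tot_c, _ = self.table(seq[idx])
            probs = np.array([e[0] for e in events]) / tot_c
            choice = events[int(rng.choice(len(events), p=probs))]
            old = seq[idx]
            seq[idx] = choice[1]
            log.append(SubstitutionEvent(branch_name, int(idx), old, choice[1]))
            # incremental bookkeeping
            syn_flux += self.table(seq[idx])[2] - self.table(old)[2]
            syn_sites += self._syn_sites[seq[idx]] - self._syn_sites[old]
            rates[idx] = self.table(seq[idx])[1]
        return seq


def _random_root(n_codons: int, rng: np.random.Generator, code: int) -> list[str]:
    codons = sense_codons(code)
    return [codons[i] for i in rng.integers(0, len(codons), size=n_codons)]


def _simulate_clade(
    tree: PhyloTree,
    root_seq: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    suffix: str,
    stem_length: float = 0.0,
) -> tuple[dict[str, list[str]], dict[str, frozenset[int]], list[SubstitutionEvent]]:
    """Evolve one clade down a tree; returns leaf codon rows, per-leaf
    deleted-codon sets, and the substitution event log.

    ``stem_length`` evolves the ancestral sequence along a stem branch
    (the duplication-to-clade-root edge) before descending the tree.
    """
    process = _CodonProcess(config.kappa, config.omega, config.code)
    events: list[SubstitutionEvent] = []
    leaf_rows: dict[str, list[str]] = {}
    leaf_dels: dict[str, frozenset[int]] = {}
    if stem_length > 0:
        root_seq = process.evolve_branch(root_seq, stem_length, rng, events, "stem" + suffix)

    def walk(node: Node, seq: list[str], deleted: frozenset[int]):
        if node.length is not None:
            name = (node.name or "anon") + suffix
            seq = process.evolve_branch(seq, node.length, rng, events, name)
            if config.indel_rate > 0:
                deleted = deleted | _draw_deletions(
                    config, node.length, rng, len(seq)
                )
        if node.is_leaf:
            leaf_rows[node.name + suffix] = seq
            leaf_dels[node.name + suffix] = deleted
            return
        for child in node.children:
            walk(child, seq, deleted)

    walk(tree.root, root_seq, frozenset())
    return leaf_rows, leaf_dels, events


def _draw_deletions(
    config: SimulationConfig, t: float, rng: np.random.Generator, n_codons: int
) -> frozenset[int]:
    """Codon-aligned deletion runs (geometric length, mean 1.5 codons)."""
    n_events = rng.poisson(config.indel_rate * n_codons * t)
    deleted: set[int] = set()
    for _ in range(n_events):
        start = int(rng.integers(0, n_codons))
        run = int(rng.geometric(2.0 / 3.0))
        deleted.update(range(start, min(start + run, n_codons)))
    return frozenset(deleted)


def _rows_to_alignment(
    leaf_rows: dict[str, list[str]],
    leaf_dels: dict[str, frozenset[int]],
    paralog_of: dict[str, str],
    clade_label: str = "sim",
) -> CodonAlignment:
    records = []
    meta = {}
    for rid in sorted(leaf_rows):
        codons = list(leaf_rows[rid])
        for c in leaf_dels.get(rid, frozenset()):
            codons[c] = "---"
        row = "".join(codons)
        records.append((rid, row))
        species = rid.rsplit("_", 1)[0] if "_" in rid else rid
        meta[rid] = SequenceRecord(
            id=rid,
            nucleotides=row,
            species=species,
            paralog=paralog_of.get(rid, "unassigned"),
            clade=clade_label,
        )
    return CodonAlignment(records=tuple(records), meta=meta)


def simulate_codons(config: SimulationConfig) -> SimulatedFamily:
    """Simulate one clade of coding sequences along a species tree.

    The root sequence is drawn uniformly over sense codons; determinism is
    guaranteed by ``config.seed`` (same seed, byte-identical output).
    """
    rng = np.random.default_rng(config.seed)
    tree = (read_newick(config.tree) if config.tree
            else random_tree(config.n_taxa, rng, config.tree_length))
    root_seq = _random_root(config.n_codons, rng, config.code)
    rows, dels, events = _simulate_clade(tree, root_seq, config, rng, suffix="")
    aln = _rows_to_alignment(rows, dels, {rid: "P1" for rid in rows})
    return SimulatedFamily(
        alignment=aln,
        trees={"P1": tree},
        true_omega={"P1": config.omega},
        events=events,
        deletions=dels,
    )


def simulate_paralog_family(
    config1: SimulationConfig,
    config2: SimulationConfig,
    shared_tree: str | PhyloTree | None = None,
) -> SimulatedFamily:
    """Two paralog clades from one duplication on a shared species tree.

    Both clades descend from a common ancestral sequence and evolve along
    the *same* species tree with the same branch-length scale (equal
    expected synonymous divergence) but their own omega — the regime in
    which synonymous rates stay matched while nonsynonymous rates separate.
    """
    if config1.n_codons != config2.n_codons or config1.code != config2.code:
        raise SimulationError("paralog clades must share n_codons and genetic code")
    if config1.tree_length != config2.tree_length:
        raise SimulationError("paralog clades must share the synonymous branch scale")
    rng = np.random.default_rng(config1.seed)
    if shared_tree is None:
        tree = random_tree(config1.n_taxa, rng, config1.tree_length)
    elif isinstance(shared_tree, PhyloTree):
        tree = shared_tree
    else:
        tree = read_newick(shared_tree)
    root_seq = _random_root(config1.n_codons, rng, config1.code)
    rows1, dels1, ev1 = _simulate_clade(
        tree, root_seq, config1, rng, suffix="_P1", stem_length=config1.stem_length)
    rows2, dels2, ev2 = _simulate_clade(
        tree, root_seq, config2, rng, suffix="_P2", stem_length=config2.stem_length)
    paralog_of = {rid: "P1" for rid in rows1} | {rid: "P2" for rid in rows2}
    aln = _rows_to_alignment(rows1 | rows2, dels1 | dels2, paralog_of)
    return SimulatedFamily(
        alignment=aln,
        trees={"P1": tree, "P2": tree},
        true_omega={"P1": config1.omega, "P2": config2.omega},
        events=ev1 + ev2,
        deletions=dels1 | dels2,
    )


def simulate_gene_sizes(
    n_per_group: int,
    fold: float = 15.0,
    noise: float = 0.5,
    seed: int = 0,
    base_kb: float = 7.0,
) -> GeneSizeTable:
    """Log-normal gene sizes with a specified geometric-mean fold between
    the two paralog groups (group P2 larger by ``fold``).

    ``noise`` is the standard deviation of log sizes; ``base_kb`` the
    geometric-mean size of the compact paralog.
    """
    if fold <= 0:
        raise SimulationError("fold must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_per_group):
        sp = f"sp{i + 1:02d}"
        s1 = base_kb * math.exp(rng.normal(0.0, noise))
        s2 = base_kb * fold * math.exp(rng.normal(0.0, noise))
        rows.append((sp, "P1", float(s1)))
        rows.append((sp, "P2", float(s2)))
    return GeneSizeTable(rows=tuple(rows))

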