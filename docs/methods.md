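# Methods

## The question the package answers

After a gene duplication, the two copies share ancestry, genomic context
and (often) function, yet they need not evolve at the same rate.  The
analyses here separate two levels: the *nucleotide* level, where the
neutral mutation process acts, and the *protein* level, where purifying
selection filters nonsynonymous change.  The diagnostic pattern for
asymmetric protein evolution on a shared mutational background is
**equal synonymous rates (Ks) with separated nonsynonymous rates (Ka)**
between the two paralog clades.

## NG86 Ka/Ks estimation

For a codon with amino acid a, each of the nine single-nucleotide
neighbours is classified under the genetic code (standard code by
default, configurable by NCBI table id).  The synonymous site count of
the codon is the number of synonymous neighbours divided by 3; mutations
to stop codons count as nonsynonymous, so synonymous + nonsynonymous
sites = 3 exactly for every sense codon.  For a codon pair differing at
k ∈ {1,2,3} positions, the k! orderings of single-nucleotide steps are
walked; orderings that visit a stop codon are discarded and syn/nonsyn
step counts averaged over the remainder (so Sd + Nd = k whenever at
least one ordering survives).  Codon pairs whose every ordering is
blocked are excluded from both difference and site totals, which keeps
the count identities exact; this and the stop-as-nonsynonymous site
convention match the behaviour of the mainstream implementations, making
table-style outputs comparable to them.  Per pair, sites are averaged
across the two sequences and summed over comparable codon columns
(columns with a gap, N or stop in either row are skipped); pS = Sd/S and
pN = Nd/N are Jukes–Cantor corrected (d = −¾ ln(1 − 4p/3)) to Ks and Ka.

Undefined ratios (Ks = 0, or a saturated correction) are `None`
throughout — never conflated with 0 or infinity — and are excluded from,
but counted alongside, group means.

Group summaries report the **mean of per-pair Ka/Ks ratios**, not the
ratio of mean Ka to mean Ks.  The two differ materially whenever Ks
varies across pairs (a test pins a fixture where they differ by > 5%);
mean-of-ratios is the convention used here because it weights each
species pair equally.  It is upward-biased for shallow pairs (small Sd
in the denominator); at the default validation scale (14 taxa, 300
codons, total tree length 0.5) the bias is within a few percent, which
is why validation tolerances are ±25%.

## Distance corrections

- Jukes–Cantor (nucleotides): d = −¾ ln(1 − 4p/3), domain p < 0.75.
- Poisson (amino acids): d = −ln(1 − p), domain p < 1.
- Kimura protein: d = −ln(1 − p − 0.2p²), domain p + 0.2p² < 1
  (saturation just above p = 0.854).

Distances beyond the domain are a value-level *saturated* marker
(`inf`), not an exception, so matrices over divergent sets still build;
tree construction refuses saturated matrices.  p-distances use pairwise
deletion of gap/ambiguous columns; table-style group summaries first
restrict to codon columns complete within the group (the retained count
is reported as "codons analysed"), which is the single documented
trimming convention of this package.

## Per-codon profiles and conservation

The per-codon Ka/Ks profile pools Sd, Nd, S, N over all requested pairs
at each codon column (optionally a centred odd window) and reports
(Nd/N)/(Sd/S) with no distance correction at single-column scale —
single-column proportions are far too small for the correction to
matter, and pooling is required because single-pair single-codon ratios
are almost always 0/0.  Columns with pooled Sd = 0 are *undefined*,
reported distinctly from 0.  Reports give 1-based codon columns and the
nucleotide offset 3·(column − 1) from the start codon.

Shannon entropy is computed per column in bits with the gap as a genuine
character (5-letter nucleotide, 21-letter amino-acid alphabet); a column
that is entirely gaps within one gene group therefore scores exactly 0
for that group, so per-group profiles on a shared master alignment stay
column-comparable even between genes of different length.  Consensus is
the most frequent non-gap symbol, ties broken alphabetically; a
divergence site is a column whose non-consensus, non-gap fraction is ≥
the threshold (default 0.05, boundary inclusive, gaps excluded from
numerator and denominator).

## Trees and the clade contrast

Neighbor joining is the plain Saitou–Nei algorithm (minimise
Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·)); BioNJ's variance weighting is
deliberately omitted — at the divergences involved the matrices are
near-additive, where the two coincide, and plain NJ is verifiable
against exact additivity (a property test reconstructs random 4–12-leaf
trees to 1e-9).  Negative branch lengths are clamped to zero with the
deficit logged.  Unrooted trees carry a trifurcating root.

The clade contrast quantifies what a tree figure shows visually: per
paralog group, the total branch length of the minimal spanning subtree
of its leaves and the mean distance from the group's basal attachment
node to its tips (stem edge excluded); the ratio of mean depths is the
reported asymmetry.  Monophyly is checked via edge bipartitions on the
unrooted tree; violations demote to a warning and an MRCA fallback, not
an error, since real paralog trees can interleave a few taxa.  The
contrast is validated only against simulations (geometric-mean ratio ≈
amino-acid rate ratio under two-rate simulations, ≈ 1 under the null);
the ratio estimator is heavy-tailed at weak protein signal, which is why
validation uses ω = 0.2 vs 0.1 and total tree length 1.0.

## The simulator

`simulate_codons` evolves codon sequences down a species tree by a
Gillespie process.  Per codon, the nine single-nucleotide proposals
carry weights κ (transition) or 1 (transversion), normalised so each
nucleotide site proposes at rate 1; proposals creating stops have rate
0; synonymous proposals are always accepted and nonsynonymous ones
accepted with probability ω ≤ 1 (the purifying-selection regime; ω > 1
is rejected as unsupported).  The expected pairwise Ka/Ks at low
divergence therefore equals ω — the same estimand NG86 targets — with no
rate-matrix exponentiation, at the cost of being an approximation at
high divergence (multiple hits per codon).

Branch lengths are in **expected synonymous substitutions per synonymous
site**: waiting times are converted event-by-event by the current
synonymous-flux-to-synonymous-site ratio.  With the default κ = 1 this
conversion factor is identically 1 and the unit is exact; κ = 1 is the
default precisely so the simulated ω and the NG86 estimand coincide with
no transition-bias distortion (κ ≠ 1 is supported and recalibrated per
event).  Defaults mirror the asymmetric-paralog regime the analyses
exist for: 14 taxa per clade, 300 codons, ω 0.08 (fast copy) vs 0.03
(slow copy), total tree length 0.5, a 0.5 stem branch from the
duplication to each clade root (deep paralog split), no indels.  Random
species trees are Yule-like (uniform random joins, exponential edge
lengths, rescaled to the target total length).

`simulate_paralog_family` draws one ancestral sequence, evolves it along
each paralog's stem, then down the *same* species tree with each clade's
ω — equal synonymous scale by construction.  Every substitution is
logged (branch, codon, from, to); a test replays the log to reproduce
every leaf.  Optional deletions are codon-aligned runs (Poisson events,
geometric length, mean 1.5 codons); insertions and realistic indel
length spectra are not modelled.  Gene sizes are log-normal with a
specified geometric-mean fold between groups (default fold 15, log-sd
0.5, compact-copy geometric mean 7 kb).

What the simulator does *not* emulate: alignment error (its alignments
are column-true, so passing tests say nothing about aligner artefacts),
site-heterogeneous ω, codon usage bias away from uniform sense-codon
roots, positive selection, and insertion events.  Estimator validation
on simulated data bounds estimator error, not data-quality error.

## Contrast significance and the battery

The paralog contrast test must respect that the within-group pairwise
comparisons are strongly correlated (they share tree branches), so
taxon- or pair-level resampling is not calibrated.  Instead the test
pairs the two groups **by codon column**: per column, pooled per-site
nonsynonymous (resp. synonymous) difference rates are differenced
between groups and a Wilcoxon signed-rank is applied across columns,
which are nearly independent.  Measured null flag rates are ≈ 5% at
nominal α = 0.05 for both the Ka and Ks variants, and the Ks variant
doubles as a negative control (it should *not* flag under the
equal-synonymous-scale design).  Gene sizes use Welch's t on log sizes
(sizes span orders of magnitude; the fold is a ratio of geometric
means).  Because one run tests several contrasts, the report's boolean
flags are Holm–Bonferroni corrected so the family-wise false-flag rate
is α; raw p-values are always reported alongside.  The whole-battery
null calibration (ω₁ = ω₂, fold = 1) uses 6 taxa/clade, 150 codons and 7
sizes/group over 100 replicates — sizes chosen to keep the 100-replicate
battery fast while leaving each test enough data to be exercised.

## Numerical and interface choices

- log1p-based forms keep corrections accurate (and ≥ p) down to p ~ 1e-300.
- Entropy in log base 2 (bits).
- 1-based codon columns everywhere a human reads them; 0-based indices
  internally.
- CDS records whose ungapped length is not a multiple of 3, or with an
  internal stop, are excluded with a logged warning rather than trimmed
  — trimming could silently shift the reading frame.
- `.` normalised to `-`, U to T, input uppercased; duplicate ids are an
  error.
- All randomness flows through one numpy Generator seeded from a single
  integer; same seed, byte-identical outputs.
- Multiple sequence alignment is accepted, not computed: inputs are
  either externally aligned (protein alignment + CDS, back-translated
  in-package) or the simulator's column-true alignments.

## Known limitations

- NG86 with Jukes–Cantor correction underestimates at high divergence
  and ignores transition bias in site counting; the package reproduces
  the estimator faithfully rather than improving on it (no
  maximum-likelihood codon models).
- The Biopython NG86 cross-check agrees to within a few percent, not
  exactly: Biopython retains stop-crossing pathways in the average where
  this package excludes and renormalises.
- The mean-of-pairwise-ratios statistic is upward-biased for very
  shallow pairs; reports include pair counts so users can judge depth.
- The clade depth-ratio is a point estimate with heavy tails on weak
  signal; interpret it jointly with the Ka contrast p-value.
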