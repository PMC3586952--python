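# Methods

This note documents the models behind each module, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the numerical
conventions that matter for reproducing results.

## Synthetic data (simgen)

**Species trees.** Random trees follow a Yule process (successive random tip
splitting) with i.i.d. exponential branch lengths (default mean 0.1
substitutions/site; one free parameter, always positive).  When group sizes
are requested, the backbone over groups and each within-group subtree are
Yule trees, so groups are monophyletic by construction — the hypothesis
generator and the census require that.  `fungal_species_tree()` is the fixed
22-species study tree (4 outgroups, 6 microsporidia-like focal species, and
2/3/2/1/2/2 species for the chytrid, zygo, basidio, taphrino, saccharo and
pezizo groups) with ascomycota and dikarya as nested clades and the focal
clade sister to all other fungi.  Focal and outgroup branches default to
0.5–0.6 substitutions/site versus 0.2 elsewhere, emulating their elevated
divergence; both are constructor parameters because the diagnostics below
deliberately explore different regimes.

**Gene orders.** One ancestral contig of single-copy families evolves along
the species tree with Poisson event counts per branch (rates are events per
branch, independent of branch length — gene-order change is not clocklike in
these data and a per-branch rate keeps the parameters interpretable).
Inversions reverse a uniformly chosen block and flip strands; segmental
duplications copy a block of 1–4 genes tandemly (adjacent to the source),
which maximizes their confounding effect on neighborhood counts; gains insert
novel families; losses remove a random gene but never the last copy of its
family *within the evolving genome* — a strictly stronger guarantee than
keeping the family alive somewhere in the clade, chosen because a depth-first
simulation cannot see sibling lineages, and it keeps family bookkeeping
well-defined.  True orthology is tracked by lineage tokens: duplication
copies and gained genes get fresh tokens, so token equality is descent
without duplication, and tokens are unique per genome (1:1 by construction).

**Gene trees.** Birth–death evolution inside the species tree: each lineage
entering a branch draws exponential waiting times (rates per branch);
duplications split the lineage, losses end it.  Physical positions of events
scale with the branch length so gene-tree branch lengths stay in
substitutions/site.  Trees are conditioned on having at least two surviving
genes.  Every internal node records its true event
(`node.planted_event`); the per-tree duplication count is the planted truth
that reconciliation must recover (exactly, when the loss rate is zero —
with losses, unwitnessed duplications are invisible to any method).

**Alignments.** A reversible CTMC over the 20 amino acids with equal
exchangeabilities and configurable stationary frequencies (uniform by
default), normalized to one expected substitution per unit branch length.
This is deliberately the simplest correct model: the point of the simulator
is planted rate heterogeneity, not realism of the exchange matrix, and the
likelihood engine shares the same model class so that rate-assignment tests
are exact parameter-recovery tests.  Among-site rates follow a discretized
gamma with equal-probability categories represented by their medians,
rescaled to mean 1 (medians are the convention here; means would work
equally — the rescaling removes the difference in expectation).  Simulated
alignments are gap-free; tests that need gaps inject them explicitly.

**Randomized clades.** The replacement test's random rows are i.i.d. per
column, drawn either from that row's own non-gap composition (default —
preserves the compositional component of the attraction signal) or uniform;
gap patterns are preserved.

## Synteny

The relaxed rule reports a query gene pair (≤ 3 intervening genes) when
homologs of both genes co-occur in the target ≤ 4 genes apart, and every
intervening query gene that has target homologs has one near the target
locus.  "Near" is implemented as within 7 genes of either member of the
target pair, i.e. a window of fewer than 15 genes centred on the locus; the
window's anchor is a package choice since only its size is conventionally
stated.  The strict rule requires same query orientation, 1:1 orthologs ≤ 3
intervening genes apart in the target that also share an orientation with
each other (whole-pair inversions allowed — strand is only meaningful
pairwise), and discards the pair when an intervening query gene has a target
ortholog: unconditionally in `literal` mode, or only when that ortholog
falls outside the target interval in `interval_consistent` mode.  The
literal reading collapses perfectly colinear genomes to their 9 adjacencies
(any non-adjacent pair has intervening genes with orthologs); both readings
are exposed and `literal` is the default.

Counts are direction dependent and reported per direction.  The correction
groups pairs by (query pair, unordered family pair) and counts each group
once, so several paralogous target loci created by a recent segmental
duplication contribute one conserved pair.  Normalization is 1000 ×
count / shared genes, where the relaxed denominator is the number of query
genes whose family has a target member and the strict denominator is the
number of 1:1 ortholog pairs — gene-level counting units, stated explicitly
because "shared homologs" alone does not fix the unit.  Group comparisons
use Kruskal–Wallis with midrank ties (scipy), with the degenerate all-equal
case defined as H = 0, p = 1.

## Phylome census (treescan)

Rooting places the root on the terminal branch of the outgroup leaf with the
greatest mean path length to the in-group leaves (ties broken by leaf name).
Averaging over in-group leaves makes the choice robust to a single long
in-group branch; the metric is a package choice since "most distant" does
not name one.  Event labelling is the species-overlap rule with threshold
0: any shared species between the two child partitions marks a duplication.
Polytomies are resolved arbitrarily with zero-length branches before
labelling (the rule needs binary nodes) and flagged.

Classification requires the focal clade to be monophyletic; records failing
that are counted as `non_monophyletic_focal` rather than guessed, and
records whose outgroups are split are `non_monophyletic_outgroup` —
reporting them separately preserves the census denominator without forcing
artifacts into scenarios.  The sister partition's group content maps to:
single group → its letter; S+P, T+S+P, B+T+S+P, B+T+S+P+Z → those labels;
all six groups → `A`, except that when the chytrid and zygo leaves form a
clade inside the sister partition the label is `A-C+Z` (this is what
distinguishes the two basal hypotheses when the twelve generated topologies
are re-classified); a sister of exactly chytrids+zygos also maps to
`A-C+Z`; anything else is `other`.

Filters are strict inequalities — support > 0.8 on the node joining the
focal clade and its sister, consistency score > 0.75, alignment length >
500 — matching their verbal definitions ("higher than", "over", "larger
than").  The census tallies every eligible record (all six groups present,
outgroup present) overall and under each filter and their conjunction.

## Supertree

Reconciliation is the standard LCA mapping; a node is a duplication iff it
maps to the same species-tree node as one of its children.  Losses are not
part of the objective.  Gene trees are taken as rooted (the census pipeline
roots them); polytomies are folded pairwise, which leaves the mask-contain-
ment logic intact.  The exhaustive search enumerates all rooted topologies
(945 at six species; refused above eight) with ties broken by the smallest
canonical Newick; hill-climbing applies rooted NNI moves (swap a grandchild
with its uncle) first-improvement until a local optimum, with 50 seeded
restarts by default.  Scoring is vectorized: each gene tree is encoded once
as per-node species bitmasks and each candidate topology reduces to a
64-entry (2^n) lookup table from bitmask to LCA node, so a full 945-topology
scan over 200 gene trees takes well under a second.

## Alignment stratification (alignops)

The likelihood engine is Felsenstein pruning with per-node rescaling, gaps
as missing data, and the same model class as the simulator.  It exists to
rank sites by rate, not to replace an ML tree engine: only relative
per-category likelihoods matter for assignment, and the topology-test
machinery accepts externally computed site-likelihood matrices whenever
higher fidelity is wanted.  Rate assignment uses equal category priors, a
posterior per column proportional to `exp(lnL_k)`, and argmax with ties to
the slower category (deterministic and conservative: ambiguous sites are
kept longer during fastest-site removal).  The gamma shape can be supplied
or estimated by a 1-D grid maximization of the summed site likelihood
(geometric grid 0.1–5, 25 points — the likelihood in the shape is smooth
and unimodal in practice, and grid resolution is not critical for ranking
sites).  The shipped four-letter recoding groups residues by
physicochemistry (AGNPST / CHWY / DEKQR / FILMV); it is a package default,
configurable by file, since reduced alphabets differ across sources.
Variability partitions count distinct non-gap residues among focal rows
(≤2 / 3 / 4 / ≥5) and exclude columns whose focal rows are all gaps.

## Topology tests (topotest)

Hypotheses are built by pruning the focal clade (keeping its internal
structure intact — re-resolving it per alignment is out of scope) and
regrafting at each named position; the input tree must resolve the named
ancestral sets as clades.  Distinctness of the 12 unrooted topologies is
asserted after construction.

All tests run on shared RELL replicates (multinomial column weights), which
makes the conservativeness ordering an event-superset property rather than a
sampling accident.  Conventions, which follow the CONSEL behaviour:

* **BP** — fraction of replicates in which the tree has the best total.
* **KH** — tree *i* versus the best of the others; statistic
  `max_{j≠i} L_j − L_i` (negative for the best tree), p = fraction of
  centered replicate differences at least as large.  Signed and one-sided:
  for two trees this is the classic test and the p-value of a designated
  tree is uniform under the null (type-I error ≈ α); the best tree's p
  exceeds 0.5.  A symmetric two-sided variant was considered and rejected
  because it halves SH relative to KH on two trees, breaking the standard
  "SH is more conservative" guarantee.
* **WKH / WSH** — the same comparisons standardized by the replicate
  standard deviation of each pairwise difference.  For a single pair the
  standardization is monotone, so WKH usually equals KH; the weighting
  matters in the max over candidates (WSH).
* **SH** — worst-case centering: statistic `L_max − L_i` against the
  replicate distribution of `max_j (R̃_j − R̃_i)`.
* **PP** — BIC weights; with equal parameter counts these are likelihood
  weights.
* **AU / NP** — bootstrap probabilities at ten resample scales r ∈
  0.5–1.4 fitted by weighted least squares to
  `Φ⁻¹(1−bp(r)) = d√r + c/√r` (binomial weights); `p_AU = 1−Φ(d−c)`,
  `p_NP = 1−Φ(d+c)` (the smoothed scale-1 bootstrap probability).
  Degenerate bp (all 0 or all 1) short-circuits to 0/1; bp is clipped at
  half a replicate for the probit.

Confidence sets keep trees with p ≥ α (the operational reading of the
retention rule) and always include the best tree.

## LBA diagnostics (lba)

The bundled tree builder is classic neighbor joining with deterministic
label-order tie-breaks; negative branch lengths are clamped to zero with the
deficit moved to the sibling so path lengths are preserved.  Distances:
`p_distance`, `poisson_corrected` (−ln(1−p)), and `jc20`
(−(19/20)·ln(1−20p/19)), the transform under which distances are additive
for the bundled substitution model.  Any callable from alignment to tree can
replace NJ (the diagnostics' logic is builder-agnostic; ML builders plug in
via Newick round-trip).

*Random replacement*: per replica the focal rows are replaced
(composition-matched by default), the tree is rebuilt, and the focal
attachment edge in the pruned tree is classified with precedence: exact
match of the planted edge first, then any attachment whose flanking side
consists solely of outgroup leaves ("within the outgroups", including their
stem — except that in a rooted-style tree the outgroup stem *is* the planted
basal edge, which is why the planted-edge check comes first), else
elsewhere; non-monophyletic random clades count as elsewhere.  The
qualitative LBA signature (randoms attracted into the outgroups rather than
to the focal position) is demonstrated under saturated outgroups (terminal
branches 1.5, uncorrected p-distances): saturation compresses observed
distances below additivity most strongly for the longest paths, which is the
attraction mechanism itself.

*Parametric test*: families are simulated on a known tree with the focal
clade planted at a rival position (sister to chytrids), concatenated and
re-inferred; recovering the planted label shows the divergence level alone
does not force the clade basal.  The demonstration regime uses moderate
divergence (stems 0.3, focal terminals 0.25) with the consistent `jc20`
NJ — at the saturated regime above, distance methods do drag the clade
basal, which is precisely the artifact the diagnostic is designed to expose,
so the two regimes bracket the phenomenon.  The original study's simulation
parameters are unreported, hence every parameter is exposed rather than
fixed.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen to keep
Monte-Carlo noise well inside the asserted margins: 20 genome pairs of ≤ 200
genes for detector/oracle equivalence; 500 random gene trees for the
reconciliation oracle; 100 (tests) or 50 (script) runs of 200 gene trees for
supertree recovery; 500-tree censuses; 5000-column alignments for rate
recovery; 1000 (tests) or 500 (script) null simulations at 300 sites / 400
replicates for KH calibration; 100 replacement replicas.  Real phylomes are
one to two orders of magnitude larger; nothing in the algorithms is specific
to these sizes.

## Limitations

The simulator omits indels, codon structure, compositional heterogeneity
across lineages, heterotachy and alignment error, so passing recovery tests
demonstrates correctness of the algorithms under their own model class, not
robustness of the biology to those factors.  Alignment construction,
consistency scoring and ML/Bayesian tree inference are consumed as inputs
(metadata, Newick, site-lnL matrices), never reimplemented.  The census
treats non-monophyletic focal clades as their own category; analyses that
force-classify them would need a different convention.  Branch lengths are
not re-optimized per hypothesis in the test battery; matrices computed with
fixed lengths favour the tree the lengths came from, so externally optimized
matrices should be used for publication-grade comparisons.
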