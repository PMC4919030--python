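# Methods

This note documents the models, algorithms and numerical choices behind
`hrsurvey`, and what the synthetic benchmarks do and do not establish.

## Scope and philosophy

The package implements the computational chain of a protein-domain homology
survey — pairwise significance, curated profile HMM, architecture
resolution, ML phylogenetics — as a library whose every stage is testable
against synthetic data with known ground truth.  Database-scale inputs
(genome collections, Pfam profiles, PDB chains) are out of scope; where a
published survey scans thousands of genomes, `hrsurvey` plants domains into
generated proteomes and measures recovery.  Passing benchmarks therefore
demonstrate *correctness of the machinery under the generator's
assumptions*, not performance on real proteomes (see Limitations).

## Pairwise significance (module `pairwise`)

Smith–Waterman local alignment with affine gaps under BLOSUM50
(open −10, extend −2; a length-k gap costs `open + k·extend`, the
FASTA-suite convention, so a single-residue gap costs −12).  The DP is
filled over anti-diagonals (vectorised); the score-only path is used for
the shuffle null and is cross-checked in tests against biopython's
`PairwiseAligner` and against top-down and path-enumeration oracles.

Significance follows the classic shuffle procedure: the subject is
uniformly permuted `n_shuffles = 200` times (Fisher–Yates via numpy
permutation), each permutation re-aligned, and a Gumbel fitted to the null
scores by the method of moments, λ = π/(σ√6), μ = mean − γ_Euler/λ.  The
expect value is reported under the single-comparison convention
E() = p = 1 − exp(−e^{−λ(S−μ)}); `p·n_shuffles` is available as an
alternative normalisation.  A subject invariant under permutation (e.g. a
homopolymer) gives a zero-variance null and raises a typed error.  The
homology cutoff is strict: E() < 10⁻³.

Traceback tie-breaks are fixed for reproducibility: diagonal over
subject-gap over query-gap; the lexicographically smallest
(query_end, subject_end) end cell; gap closure preferred over extension on
ties.  Percent identity uses all aligned columns (including gap columns) as
the denominator by default; `identity_denominator="matched"` switches to
matched columns only.  `X` scores 0 against everything.

## Profile HMM (module `phmm`)

A simplified Plan7 architecture: per node a match, insert and delete state;
uniform local entry into and exit out of any node (probability 1/M each);
flanking residues emitted by the background, contributing zero log-odds.
There is no I→D or D→I edge.  Scores are log₂-odds against the background.

Construction from a seed alignment: columns with non-gap occupancy ≥ 0.5
become match nodes; match emissions are Laplace-smoothed counts
(pseudocount 1); transition probabilities are counted from per-row state
paths with pseudocount 1 per outcome; insert emissions equal the
background.  The background defaults to the LG equilibrium frequencies —
the same distribution the synthetic generator uses for decoys — so
calibration and discrimination refer to the same null.

**Anchor weighting.** The O₂-binding family is defined less by overall
identity than by its iron-coordination site (5×His, 1×Glu, 1×Asp).  For an
anchor `(column, residue, weight)` the residue's raw count is multiplied by
the weight (default 5.0) before smoothing.  The default magnitude is a
design choice; the tested property is directional — weighting widens the
score gap between anchor-preserving and anchor-violating homologs.

Scanning: local Viterbi over (position × node) with delete chains handled
by a telescoped max-plus prefix scan (so the recurrence stays vectorised
over nodes); the forward score uses the same structure with
`logaddexp.accumulate`.  Tests verify Viterbi and forward against explicit
path enumeration on tiny models, and forward ≥ Viterbi generally.
Multi-hit scanning takes the best envelope and recurses into the flanks.

E-values: a Gumbel is fitted (same moment estimator) to Viterbi bit scores
of `n_random ≥ 100` background sequences; `E = database_size · P(S ≥ s)`.

Two distinct coverages are computed and named explicitly, because survey
prose often conflates them: `reference_coverage` (fraction of profile nodes
spanned; seed collection requires > 0.95 against the reference) and
`protein_coverage` (fraction of the protein inside the hit envelope; hits
with protein coverage < 0.85 are classified *long*, else *single_domain*;
the inequality is strict at the boundary, so 0.85 exactly is
single-domain).

Seed collection mirrors the survey's first pass: keep database sequences
whose best pairwise alignment to a reference covers > 95% of that reference
with shuffle E() < 10⁻⁵.  Sequences whose raw local score is below a
prescreen threshold (default 40) are skipped without shuffling; at that
score the null cannot approach the cutoff (E ≈ 10⁻⁵ requires roughly
μ + 38/λ ≈ 70 here), so the prescreen affects time only.

Profiles serialise to a versioned plain-text format (`HRSURVEY-PHMM 1`)
with `%.12e` fields; round-trips are lossless to 12 significant digits.

## Architectures (module `arch`)

Overlap resolution is greedy in ascending E-value; a hit is rejected if its
envelope shares ≥ 1 residue with an accepted hit (a tolerance flag allows
small overlaps).  Ties break by longer envelope, then profile id, then
envelope position — the accepted set is invariant to input order, and a
structurally different second implementation serves as a test oracle.

Unannotated regions of ≥ 50 residues count as *orphan elongations* (the
published notion is qualitative; 50 is this package's explicit choice) and
participate in terminus classification: the focal domain is N-terminal if
no accepted domain or orphan region precedes it, C-terminal symmetrically,
only-domain if both, internal otherwise.  File coordinates are 1-based
inclusive; in-memory coordinates 0-based half-open.

## Alignment (module `msa`)

k-mer (k = 3) set distances, `d = 1 − shared/min`, feed average-linkage
UPGMA (ties broken lexicographically) to give a guide tree; profiles are
merged bottom-up by global affine profile–profile alignment with
average-of-pairs column scores (gap vs residue scores `gap_extend`, gap–gap
0; once a gap, always a gap).  A single progressive pass replaces iterative
refinement deliberately: at the package's scale the downstream
parameter-recovery tests gate alignment quality, and the planted-homolog
column-pair recall test requires ≥ 90% recovered homologous pairs at
divergence 0.3.

## Phylogenetics (module `phylo`)

Model: LG exchangeabilities and equilibrium frequencies (shipped as a
checksummed plain-text asset) with Q normalised to one expected
substitution per site; rate heterogeneity by a discrete gamma with six
equal-weight categories, category rate = conditional mean of its quantile
slice (so the mean rate is exactly 1; a quadrature oracle checks the
slice means to 1e-6).  P(t) = exp(Qt) via the symmetric eigendecomposition
of D_π^{1/2} Q D_π^{-1/2}; rows are clipped/renormalised against round-off
and checked to sum to 1 within 1e-10.

Likelihood: Felsenstein pruning over unique site patterns, vectorised over
gamma categories; gaps and X are missing data (partials of ones).  No
scaling is applied — at the package's tree sizes (≤ ~20 tips) double
precision does not underflow; the 3-taxon enumeration oracle agrees to
1e-10 relative error and the pulley principle holds numerically.

Search: NJ (Saitou–Nei, negative estimates clamped to 0) on pairwise ML
distances; per-branch bounded scalar optimisation (Brent in
[1e-8, 20], iterated to likelihood change < 1e-6, monotone by
construction — a candidate step is kept only if the exactly re-evaluated
likelihood does not decrease); NNI hill-climbing with local re-optimisation
of the five branches around each candidate edge, accepting the best
improving move per round.  SPR moves are omitted by design: validation
relies on simulation recovery (RF = 0 on the fixed 8-taxon benchmark in
≥ 8/10 seeds), not on matching any particular optimiser's optimum.

aLRT supports: per internal branch, statistic 2(ℓ_best − ℓ_second) against
the better of the two NNI alternatives after local re-optimisation;
support = 1 − p under the ½χ²₀ + ½χ²₁ mixture (the parametric variant; a
zero statistic gives support 0).  A negative statistic — the search missed
a better neighbour — is clamped to 0 with a warning, which is conservative
for the collapse step.  Branches with support < 0.6 are contracted into
polytomies (idempotent; the contracted branch length is dropped).

Rooting: midpoint (root at the middle of the longest tip-to-tip path,
verified against an all-pairs oracle; re-rooting preserves the unrooted
metric) or outgroup (root on the branch above the smallest clade containing
the outgroup — the explicit mechanism for "rooted following a guide
tree").  Monophyly is exact tip-set equality of some clade.  The bootstrap
resamples columns and rebuilds trees per replicate, by default with
NJ on ML distances (full NNI search per replicate available by flag),
reporting bipartition frequencies.

Gamma-shape estimation is one-dimensional: coarse log-grid, then bounded
golden-section refinement alternated with branch re-optimisation.  On
simulations at α = 1.151 (500 sites, 8 taxa) the estimate lands in
[0.7, 1.8] in ≥ 8/10 seeds; joint branch/shape co-optimisation would
tighten this but is deliberately not implemented.

## Synthetic data (module `synth`)

The generator emulates the statistical structure the survey machinery
assumes:

* **Templates.** The focal template is 118 residues with the seven
  iron-site anchors at myohemerythrin-like spacings; non-anchor consensus
  residues are drawn from LG equilibrium frequencies.  The sister (HHE-like)
  family shares length but differs at ≥ 40% of positions and three anchor
  residues.  Two anchor-free decoy families (60 and 200 residues) share
  < 20% identity with the focal consensus.
* **Homologs.** Per-site substitution with probability 1 − exp(−d) at
  divergence d; anchors substitute with the residual probability
  (1 − anchor_conservation)·that, anchor_conservation defaulting to 0.95.
  Replacement residues are uniform over the 19 alternatives (so every
  substitution is visible); the tree-based simulator instead uses the full
  LG CTMC with exact matrix exponentials and per-site gamma categories.
* **Proteomes.** Architectures are segment lists (domain / linker /
  orphan); linker and orphan lengths are geometric with configurable mean
  (default 30; orphans 80 where they must exceed the 50-residue orphan
  threshold).  Background proteins draw residues from LG equilibrium and
  lengths uniformly in 100–400.  Planted divergences default to
  uniform(0.1, 1.5) — the true divergence distribution of the family is
  unknown, so this range is a free parameter covering easy to hard cases;
  recovery benchmarks use the harder-edged 0.1–0.5 slice.
* Everything is driven by explicit integer seeds; identical inputs and
  seeds give byte-identical outputs.  The pipeline fans one master seed
  into per-stage seeds through `SeedSequence` spawn keys, which keeps the
  stage streams disjoint (two stages seeded with the same small integer
  would otherwise replay the same residue stream).

Not emulated: indels along trees (columns are homologous by construction),
codon structure, compositional bias across proteomes, realistic taxon
sampling, and contaminating partial domains.  Benchmarks passing here say
the pipeline is correct under these assumptions; sensitivity on real
proteomes with indels and biased composition is untested by design.

## Validation benchmarks (module `benchmarks`, `scripts/acceptance.py`)

* Planted-domain recovery: 200 planted focal domains (divergence ≤ 0.5,
  varied architectures) among 2000 decoys; protein-level sensitivity and
  FDR at E < 10⁻⁵ with a database size of 2200.
* Monophyly recovery: 300 sites simulated on a two-clade tree (planted
  family vs sister family, internal branch 0.4), full ML + aLRT + collapse
  at 0.6 + midpoint root; fraction of 10 seeds with the planted family
  monophyletic.
* Gumbel fit recovery on 10⁴ synthetic draws; topology (RF = 0) and
  gamma-shape recovery on the fixed 8-taxon tree at α = 1.151, 500 sites,
  10 seeds.

Problem sizes were chosen so a full reproduction run completes in a few
minutes on one CPU while keeping every statistic's sampling error well
inside its acceptance band.

## Known limitations

* The Plan7 simplification (uniform entry/exit, no Dirichlet-mixture
  priors, no MSV/forward filters) is not bit-compatible with HMMER; E-value
  calibration is per-profile empirical rather than analytic.
* The E() normalisation of the shuffle test is a stated convention;
  published identity values are convention-stable but expect values are
  comparable only in order of magnitude.
* The aligner has no iterative refinement; very gappy families would
  degrade profile quality.
* NNI-only topology search can stop at local optima on larger or harder
  trees than those validated here; the aLRT warning surfaces such cases.
* Trees beyond ~200 tips and alignments beyond ~1000 sequences are outside
  the intended scale.
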