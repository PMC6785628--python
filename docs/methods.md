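# Methods

`mitosel` analyses molecular adaptation in mitochondrial protein-coding
genes on a fixed phylogeny.  It chains four statistical components: codon
models of selection with likelihood-ratio tests, marginal ancestral
amino-acid reconstruction, detection of convergent/parallel substitutions
between designated lineages, and an expected-count significance test for
those substitutions.  A stochastic simulator with recorded ground truth
makes every stage testable without external data.  This note documents the
models, the defaults and why they were chosen, and what the validation
studies do and do not show.

## Likelihood engine

All inference rests on continuous-time Markov substitution models over
nucleotides (4 states), amino acids (20) or sense codons (60 under the
vertebrate mitochondrial code, NCBI translation table 2, in which AGA and
AGG are stops in addition to TAA/TAG).  A model is a generator Q scaled so
that one unit of branch length equals one expected substitution per site at
equilibrium.  Transition matrices P(t) = exp(Qt) are computed by
eigendecomposition of the π^½-symmetrised generator for time-reversible
models, falling back to scipy's `expm` otherwise.

Tree likelihoods use Felsenstein pruning over unique site patterns with
per-pattern rescaling (toggleable, and verified equivalent on short
alignments).  Gaps and ambiguity codes map to a missing state that the
pruning marginalises over.  Among-site rate variation is the standard
+I+G mixture: a rate-0 invariant class with weight I plus k discrete-gamma
categories (mean-of-equal-mass-bin discretisation, k=4 default, category
weights (1−I)/k).  Extremely large gamma shapes — one fitted mitogenome
partition reports α ≈ 87, i.e. near rate homogeneity — are accepted and
collapse gracefully to equal rates if the quantile computation degenerates.

Branch lengths are fitted by bounded quasi-Newton (L-BFGS-B) on log
lengths, bounds [1e-8, 50] expected substitutions/site, with multi-starts
at {1.0, 0.1} × a pairwise-mismatch heuristic; fitted lengths below 1e-5
are reported as 0 (numerically indistinguishable from a zero branch).  The
gamma shape can be co-estimated for amino-acid models.

Nucleotide models: GTR with +I+G; TrN and TVM are constrained GTR
parameterisations rather than separate code paths.  Amino-acid models:
mtMAM (default) and mtREV24 empirical exchangeabilities, shipped as
plain-text tables; these are the standard choices for vertebrate
mitochondrial proteins.

## Selection tests

Codon substitution follows the GY94 mechanism: zero rate for multi-position
codon changes; single-position changes proportional to the target codon
frequency, times κ for transitions, times ω for amino-acid-altering
changes.  Codon frequencies are F3x4 by default (position-specific
nucleotide frequencies with a 0.5 pseudocount), with F1x4 and equal
available; the choice is recorded in every fit.

*One-ratio (M0)*: a single ω shared by all branches and sites, jointly
optimised with κ and all branch lengths.  An alignment with no variation
sets a `degenerate` flag (ω unidentifiable) instead of returning a silent
number.

*Branch-site Model A*: four site classes — 0 (ω0 < 1 everywhere), 1
(ω = 1 everywhere), 2a (ω0 background / ω2 foreground) and 2b (1
background / ω2 foreground) with proportions p0, p1 and
p2a : p2b = p0 : p1.  The null fixes ω2 = 1.  All class matrices share one
scale factor, the class-proportion-weighted mean rate of the *background*
process, so a branch length is the expected substitutions/codon for a
background-average site; the simulator uses the identical convention.
Optimisation is L-BFGS-B on transformed parameters (log κ, softmax
proportions, logit ω0, log(ω2−1)) from a 2×2 grid of starts
(ω2 ∈ {1.5, 5} × p2 ∈ {0.05, 0.2}); the alternative additionally
warm-starts from the null optimum (at ω2 = 1+1e-8 and ω2 = 3), which
guards against the boundary local optima this surface is known for and
enforces the nesting inequality numerically.  By default both fits
re-optimise branch lengths; a `share_lengths` flag fixes them at a
one-ratio prefit, which is used by the pipeline and the simulation studies
for speed.

The LRT compares 2Δℓ to χ²₁ (negative differences clamp to zero); the
conservative 50:50 χ²₀:χ²₁ boundary mixture is available behind a flag.
Per-site posteriors over the four classes are naive empirical Bayes at the
fitted parameters; "positively selected site" means P(2a)+P(2b) ≥ 0.95.
Raw p-values are always reported; any multiple-testing correction across
genes × branches is left to the user.

## Ancestral reconstruction

Reconstruction is marginal and empirical-Bayes: at fixed (fitted) branch
lengths and model, a tipward pass computes partial likelihoods and a
rootward pass computes the complementary messages; their product gives each
internal node's posterior over the 20 amino acids, with the rate mixture
marginalised via per-site category weights.  Reconstruction operates at the
amino-acid level (codon alignments are translated first) under mtMAM+G;
this matches how amino-acid change tables are produced in this literature.
MAP ties are broken alphabetically (deterministic) and counted.

Per-branch substitutions compare MAP(parent) to the child state (observed
residue at leaves; MAP at internal nodes).  Sites with a missing child
state are skipped and tallied.  Records where either endpoint posterior is
below p_min = 0.7 are flagged low-confidence but retained — by default no
posterior filter is applied before convergence calling.

## Convergence and parallelism

At one site, two non-nested branches show a *parallel* change when the same
ancestral residue gave the same derived residue on both, and a *convergent*
change when different ancestral residues arrived at a common derived
residue distinct from both ancestors (if the derived state equals one
ancestor, only one branch changed — classified as neither).  Events are
reported pairwise over all unordered pairs of focal branches; branches on
one root-to-tip path are excluded with a warning, since their changes are
not independent.

Significance uses expected counts under the fitted model.  For a branch
pair with lengths t1, t2 and parent-state distributions q1, q2:

    P_parallel(site)   = Σ_a q1(a) q2(a) Σ_{x≠a} P1[a,x] P2[a,x]
    P_convergent(site) = Σ_{a1≠a2} q1(a1) q2(a2) Σ_{x∉{a1,a2}} P1[a1,x] P2[a2,x]

computed per rate category and mixed with the site's category posterior.
Each q is the parent's posterior *excluding* the evidence of its own focal
subtree (the focal branch's message is divided out of the inclusive
posterior).  This exclusive form is what the Bernoulli factorisation
assumes: with the inclusive posterior the derived state is counted twice —
once inside q, once in P(a→x) — which inflates expectations and makes the
test anticonservative; simulation showed a ~10% excess that the exclusive
form removes.

The number of parallel (or convergent) sites is a sum of independent
Bernoulli variables; the p-value is the exact Poisson-binomial upper tail
(dynamic-programming convolution truncated at the observed count) for up to
10,000 sites, and a Poisson approximation with mean ΣP beyond that.  Two
discreteness adjustments are available: mid-p (default for calibration
reporting) and a seeded randomized tail, which is exactly U(0,1) under the
null.  Significance bands are starred as * p<0.05, ** p<0.01, *** p<0.001.

The formulation follows the classical expected-count test for
convergent/parallel sites; since no printed intermediate values exist to
check against, it is validated against a Monte-Carlo oracle (drawing
parent states from the same posteriors and derived states from P(t)) and
against closed-form Poisson/binomial tails.

## Annotation

TMHMM-style long-format topology files are parsed into per-protein interval
annotations ({TM, inside, outside}, 1-based, validated to tile the protein
exactly); candidate sites get the covering label.  Polarity uses the
standard four classes — nonpolar {G A V L I M F W P}, polar-neutral
{S T C Y N Q}, positive {K R H}, negative {D E} — and a change is reported
as the ordered class pair, or none within a class.  TMHMM itself is never
run, and 3D-structure mapping is out of scope.

## Synthetic data

Codon alignments are simulated *exactly* (Gillespie event-by-event along
each branch) so that the truth object carries every substitution with its
time, the true site class, and all node states; leaf sequences are
reproducible by replaying the event log.  Regimes: M0 (defaults κ=2,
ω=0.2 — a typical purifying mitochondrial gene) and branch-site Model A
(defaults p0=0.6, p1=0.2, ω0=0.2, ω2=4: 20% of sites episodically selected
on the foreground, a moderately widespread signal of the kind the test is
built to detect).  Codon frequencies default to uniform over sense codons.
One master seed drives named independent streams (per gene, per branch), so
edits that do not touch a stream leave other outputs unchanged.  Amino-acid
alignments for reconstruction/convergence studies use endpoint sampling —
only node states are needed there, not histories.

Planted parallel changes force k extra same-derived-state substitutions on
a branch pair.  Eligible sites must have (i) the same parent amino acid on
both branches, (ii) that amino acid conserved (≥70%) among leaves outside
the two focal subtrees, and (iii) a common derived amino acid one
nucleotide away from both parent codons and absent outside the focal
subtrees.  These conditions make the planted change a *recognisable*
parallel event — a change the reconstruction can in principle detect;
without them a planted change can be statistically indistinguishable from a
single ancestral change or from standing variation, which is a property of
the inference problem, not of the implementation.  Subtrees below the pair
are overwritten and their histories cleared so the event log still replays
exactly.

Fixture bundles (per-gene FASTA, tagged Newick, depth table, topology
table, truth JSON, manifest) model the study design: deep-sea taxa are
leaves chosen greedily for maximal path separation (independent invasions),
their terminal branches are set to 0.4 substitutions/codon (long isolated
lineages), and the edge above each attachment node is capped at 0.05 so
ancestors are inferable — emulating the dense shallow-water sampling of
real datasets.  Deep taxa receive maximum depths ≥ 1,000 m in the depth
table; the deep/shallow classifier treats the 1,000 m boundary as
inclusive (≥), with the threshold exposed as configuration.

What the simulations do *not* emulate: indels and alignment error,
base-composition heterogeneity across lineages, depth-dependent rates,
overlapping reading frames, and real mitochondrial codon usage (uniform π
by default).  Passing tests therefore demonstrate correctness of the
machinery and calibration under the model, not robustness to real-data
violations of it.

## Study conditions for the validation experiments

The simulation studies use fixed, documented conditions:

- **Six-taxon study tree** (`STUDY_TREE_6`): three cherries, tree length
  ≈ 1.9 substitutions/codon, with one long (0.5) terminal foreground
  branch — the deep-sea-lineage situation the branch-site test targets.
  Power and size of the LRT (500 codons; ω2 = 4 vs ω2 = 1) and one-ratio
  recovery (ω = 0.2) are measured here with 20–50 replicates.
- **Ten-taxon calibration tree**: two long (0.3) focal terminal branches in
  different clades, each attached to a node pinned by close relatives.
  Null p-value uniformity (200 replicates × 1,000 amino-acid sites,
  mtMAM+G α=0.8) and the observed-vs-expected count agreement are measured
  here.  The pinning matters: the expected-count test assumes confidently
  reconstructed ancestors, and with poorly pinned parents the MAP-based
  observed counts drift from the posterior-based expectations.
- **End-to-end fixture**: 10 taxa, 4 genes × 400 codons, one gene under
  foreground selection (ω2 = 4), k = 3 planted parallel changes in another.
  Problem sizes throughout were chosen so the full suite and the
  reproduction script each run in minutes on a single CPU.

## Numerical choices and degenerate inputs

- Convergence tolerance 1e-6 (relative) for all L-BFGS-B fits; lnL is
  therefore reproducible to ~|lnL|·1e-6 across restarts.
- Codon frequencies are floored at 1e-10 and renormalised before building
  generators; F3x4 uses a 0.5 pseudocount per nucleotide cell.
- P(t) rows are clipped at 0 and renormalised after eigendecomposition to
  absorb round-off.
- Identical sequences: branch lengths go to the lower bound and are
  reported as 0; one-ratio fits flag degeneracy instead.
- MAP ties: alphabetical amino-acid order, logged via a tie counter.
- The LRT statistic clamps at 0 when the alternative lands within
  optimizer tolerance below the null.

## Known limitations

- BEB (Bayes empirical Bayes) site identification is deliberately not
  implemented; NEB posteriors are known to be less robust at small sample
  sizes.
- Site-only models (M1a/M2a/M7/M8) and free-ratio models are out of scope.
- The convergence test treats the two parent-state posteriors as
  independent; their residual phylogenetic correlation is ignored (small
  for well-separated pairs, the only ones scanned).
- Joint (all-nodes) ancestral reconstruction is not provided.
- Overlapping reading frames (ATP8/ATP6) assign shared alignment columns to
  both genes.
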