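# Methods

`sfpevol` implements a quantitative evolutionary-proteomics analysis of
seminal-fluid proteins (SFPs) across primates with uni-male versus
multi-male mating systems.  The pipeline joins three strands of evidence
per gene: abundance differences between mating systems from peptide-level
relative isotope abundances (RIA), positive selection in coding sequences
from codon models, and correlated evolution between the lineage-specific
evolutionary rate (log dN/dS) and sexual characters on the phylogeny.
Because raw mass-spectrometry data of this kind are not generally
redistributable, the package carries a first-class synthetic-data generator
that reproduces the statistical structure every stage assumes, and the test
suite exercises the whole pipeline on it.

## Proteomic quantification (`quant.py`)

**Normalization.** Each MS run receives a factor equal to the geometric
mean of its spiked internal-standard peptides (horse-myoglobin- and
trypsin-like reserved protein ids) divided by a global reference; every RIA
in the run is divided by the factor.  Geometric means are computed in log
space; non-positive or missing RIAs are treated as missing, never as zero.
By default the reference is the geometric mean of the per-run standard
geometric means of the dataset at hand, which makes the single-run case an
identity and reproduces hand-computable factors (runs with standard
geometric means 6 and 24 get factors 0.5 and 2.0 against reference 12).
The reference can instead be pinned to an external calibration constant;
with a pinned reference, rescaling any single run by any c > 0 leaves all
of its normalized values bit-identical (the factor cancels c exactly), and
the per-run standard geometric mean equals the reference after
normalization.  With the data-derived default the reference itself moves by
c^(1/R) when one of R runs is rescaled, so only ratios are invariant; this
is an inherent property of self-calibrated references, not of the
implementation.  Runs with no detected standards are excluded and reported.

**QC filter.** Per biological sample and peptide, the technical-replicate
mean is retained iff at least two replicates are present and their CV is at
most 25% (CV = 100 x sample SD with n-1 denominator / mean, on the raw
scale — the standard clinical-proteomics convention).  Exclusions carry
machine-readable reasons (`single_replicate`, `cv_exceeds`).  A CV of
exactly 25% is retained.

**Rollup and classification.** Protein abundance per individual is the
arithmetic mean over its retained peptides, reported only for proteins with
at least three retained peptides.  Between-sample variability is classified
as conserved (CV < 25), high (CV > 75), or intermediate; both boundaries
fall in the intermediate class.  NSAF values are length-normalized spectral
counts renormalized to sum to one within a sample.

## Comparative statistics (`compare.py`)

Only exactly identical peptide sequences are compared across species
(modifications and ionization differences make RIAs of different peptides
incomparable; one residue difference excludes a peptide).  Group
comparisons use the Wilcoxon rank-sum test: exact enumeration of the null
(via scipy) when n + m <= 16 with no ties, otherwise the midrank normal
approximation with continuity correction; the two-sided p-value is
min(1, 2 x min of the one-sided p-values), and the one-sided pair assigns
direction to significant peptides.  Scans report raw p < alpha (default
0.05) with no multiple-testing correction, mirroring the candidate-table
semantics; Benjamini-Hochberg adjustment is available behind a flag.
Individuals are pooled within mating group across species, which is valid
in the synthetic study because species share a common null mean; real data
with species-level random effects would make this anti-conservative (a
known limitation of the pooled design).  Peptide concordance within a
protein is the squared Pearson correlation of log10 abundances across
shared samples (raw scale available), with pairs under three shared samples
or constant profiles reported as missing.

## Codon selection models (`selection.py`)

The substitution model is GY94: 61 sense codons (universal code),
single-nucleotide changes at rate proportional to the target frequency
pi_j, times kappa for transitions and omega for nonsynonymous changes.
Matrices are reversible, so P(t) comes from a symmetric eigendecomposition;
branch lengths are expected substitutions per codon site at the
mixture-mean rate.  Codon frequencies default to F3x4 estimated from the
alignment; uniform frequencies are used in simulation-based tests so the
generating and fitted frequencies agree.

Likelihoods use Felsenstein pruning over compressed site patterns with
per-node rescaling; gaps are missing states.  A per-class, per-branch omega
table lets one engine serve the site mixtures, the branch-site model, and
one-omega-per-branch fits.

**Fitting protocol.** M0 optimizes kappa, omega and a branch scale by
L-BFGS-B; when the input tree has no usable branch lengths they are
re-estimated by per-branch coordinate sweeps, otherwise the input tree's
relative lengths are trusted (the species tree is fixed genome-wide) and
only the gene-level scale is refit.  Richer models inherit kappa and
relative branch lengths and re-optimize one shared scale together with the
mixture parameters (M7/M8/M8a discretize the beta into K = 10
equal-probability classes at quantile midpoints).  Internally the shared
scale is parameterized on the unnormalized-generator time axis, which
reaches the same maximum likelihood while making each class's site
log-likelihood vector depend only on (omega, scale); cached vectors then
make forward-difference gradient steps cheap.  Mixture fits run from two
starts (a seeded/dedicated start plus a jittered one); in nested pairs the
alternative is seeded with the null optimum, so lnL(alt) >= lnL(null) holds
structurally.  Convergence uses relative ftol 1e-8 (delta-lnL resolution
about 1e-4, ample for LRTs read on a chi-squared scale).

**Tests.** LRT degrees of freedom: M1a-M2a and M7-M8 use 2, M8a-M8 uses 1.
Plain chi-squared is used rather than the 50:50 boundary mixture, which
makes M8a-M8 and the branch-site test conservative.  FDR control uses
Storey q-values with pi0 estimated on a lambda grid for at least 100
p-values and a pi0 = 1 (Benjamini-Hochberg) fallback otherwise.  The
branch-site test is standard model A with the multi-male lineages as
foreground: a tip branch is foreground iff its tip is multi-male, an
internal branch iff all its descendant tips are (parsimony-style rule);
the null fixes the foreground class at omega2 = 1.  Swapping the
foreground label provides the reversed control.

## Trait-rate correlation (`correlate.py`)

A two-stage, coevol-style analysis replaces joint substitution mapping.

**Stage one** estimates one omega per branch by maximum likelihood with
branch lengths and kappa fixed from M0, optimized by coordinate sweeps with
a weak Gaussian penalty on log omega centred at the gene's M0 estimate
(sd 2 log units) — a pseudocount that keeps branches without informative
substitutions finite.  Zero-length branches and substitution-free
alignments yield missing estimates.  Each branch gets an uncertainty weight
proportional to branch length times alignment length.

**Stage two** places a latent multivariate Brownian motion over
(log omega, characters) on the tree.  Characters are observed at the tips
(testis size, dimorphism and partner number log-transformed; the 0/1
mating type and the ordinal 1-4 coagulation rating untransformed; missing
entries stay latent).  Branch log omega is observed as the branch-average
of the latent rate coordinate — midpoint of the endpoints plus
Brownian-bridge averaging noise — with additional Gaussian noise whose
variance is s^2 divided by the branch weight.  A Gibbs sampler alternates
conditional-Gaussian node updates, a conjugate inverse-Wishart draw for the
covariance (prior: identity scale, df = dim + 2), and a conjugate
inverse-gamma draw for s^2 (floor 1e-4 to keep node conditionals well
scaled).  Marginal correlations between log omega and each character are
read off the covariance samples; pp = Pr(r > 0) is classified positive at
pp >= 0.975, negative at pp <= 0.025, else ns.  The sign convention for the
binary character: positive correlation means higher log omega on multi-male
lineages.  Library default chain: 20,000 iterations, 25% burn-in, thinning
10; the pipeline default uses 6,000/25%/5, which on 13-tip problems changes
pp by well under the 0.03 stability band (verified by the chain-doubling
test).  The identity-scale prior shrinks the correlation toward zero in
proportion to Psi0 relative to the increment scatter matrix; at a Brownian
variance of about 1 per unit branch length for log dN/dS — a realistic
magnitude for primate-depth trees and the value the calibration studies
use — the shrinkage is mild, keeping the null conservative at the
0.975/0.025 cutoffs without flattening genuine correlations.

## Synthetic data (`synthetic.py`)

The generator defines the study conditions:

* **Phylogeny** — a fixed 13-tip primate tree (apes, Old World monkeys,
  marmoset, mouse lemur) with uni/multi mating labels; branch lengths are
  plausible defaults in substitutions per codon (configuration, not
  inference), about 0.75 total tree length.
* **Quant tables** — five proteomic species (human and drill uni-male;
  rhesus and cynomolgus macaques and vervet multi-male), eight biological
  individuals for human and rhesus and two elsewhere, three technical
  replicates per sample.  Defaults: 100 proteins x 5 peptides, 40% of
  peptides identical across all species (the rest species-specific),
  biological CV 50%, technical CV 10% (lognormal, CV parameterizes the
  sigma of the log), run scale factors lognormal(0, 0.5), 5% missingness
  completely at random per (run, peptide), six standard peptides present in
  every run, and a 3-fold abundance shift (multi higher) for 10 designated
  responsive proteins — effect sizes in the range seen for copulatory-plug
  proteins.  Species share a common null mean, so the pooled mating-group
  scan is exactly calibrated; the generator does not model species-level
  random effects, peptide detectability, or non-random missingness, so
  passing tests speak to the statistics, not to instrument artefacts.
* **Codon alignments** — sampled under any of M0/M1a/M2a/M7/M8/M8a or the
  branch-site model by drawing a site class, a root codon from pi, and
  evolving along branches with the same rate scaling the fitter uses.  For
  the branch-site model, branch lengths are defined on the background rate
  scale, so a foreground class with omega2 > 1 genuinely adds
  substitutions on foreground lineages — the excess the LRT detects.
* **Characters** — multivariate Brownian motion over (log omega, latent
  characters); positive characters are exponentials of their latents, the
  coagulation rating is a quartile binning, and the binary mating type is a
  median split of its designated latent (recorded in the output metadata).
  Per-branch true log omega is the Brownian-bridge average.

All generators are deterministic given a seed; outputs round-trip through
the TSV/FASTA/newick writers bit-exactly (floats printed with 17
significant digits).

## Pipeline and integration (`pipeline.py`)

`run_full_pipeline` executes simulate -> normalize -> QC -> match ->
mating-system scan -> selection tests (M8a-M8 with q < 0.01; branch-site
with p < 0.01) -> trait-rate correlation -> integration, writing a TSV per
stage, a manifest with config, seeds and input hashes, and a summary with
recovery metrics against the planted truth.  A failing evolutionary fit
flags its gene and the scan continues.  The candidate table lists the union
of genes with any qualifying evidence: per-character pp (printed only when
it clears the 0.975/0.025 cutoffs, otherwise `ns`), an `x` for a
significant branch-site test, and an `x` for proteins with at least one
significant peptide in the abundance scan; per-category and overlap counts
are reported alongside the union.

## Problem sizes in the test suite and acceptance script

Simulation-based checks are sized for a desk-scale run while keeping their
binomial acceptance bands comfortably wide: pruning-vs-enumeration uses 50
random parameter draws on trees of up to 4 tips; M0 recovery uses 20
alignments (8 taxa, 500 codons); the M8a-M8 null calibration uses 30
alignments and the branch-site calibration 36 neutral alignments plus 12
power replicates (13 taxa, 300 codons; power simulated with half the sites
in the foreground-selected classes at omega2 = 4); the Brownian
calibration uses 50 null and 30 correlated datasets (13 tips, Brownian
variance 1 per unit branch length, chains of 3,000); the rank-sum checks
use 200 enumeration
cases and 1,000 null peptides; the end-to-end run plants 10 responsive
proteins among 100 and 5 positively selected genes among 8.  The
acceptance script recomputes the same quantities at somewhat smaller
replicate counts and prints them as JSON.

## Known limitations

* The branch-site and M8a-M8 tests use plain chi-squared df 1 at a boundary
  null, so their size is conservative by design.
* Stage-two correlation treats stage-one branch omegas as data; coevol's
  joint substitution mapping would propagate rate uncertainty more fully.
* The binary mating label enters the Brownian model as a 0/1 covariate,
  a deliberate simplification shared with the candidate-table semantics.
* The pooled mating-group scan ignores phylogenetic dependence between
  individuals of related species; on real data this inflates significance
  and is one reason the scan is reported as candidate evidence, not as a
  calibrated test of mating-system effect.
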