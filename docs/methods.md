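# Methods

`relict` analyses recurrent gene loss (pseudogenization) across a phylogeny
by combining four evidence streams — coding-sequence lesions, branch-specific
dN/dS, liver expression, and plasma enzyme activity — and then asking which
organismal phenotypes predict loss. This note documents the models, the
numerical choices, and what the synthetic data do and do not emulate.

## Codon substitution model and branch tests

The selection analysis uses a GY94-family codon model over the 61 sense
codons of the standard code. For branch class *c* the generator has

    q_ij = pi_j * kappa^[transition] * omega_c^[nonsynonymous]

for codon pairs differing at exactly one nucleotide, and 0 otherwise; rows
sum to zero and each class matrix is rescaled so the expected substitution
rate at stationarity is 1, so branch lengths are expected substitutions per
codon site. The model is time-reversible, which we exploit twice: transition
matrices come from a symmetric eigendecomposition (`P(t) = D^-1/2 V e^{wt}
V' D^1/2`), and the likelihood is invariant to root placement (checked by a
rerooting test).

Likelihoods use Felsenstein pruning over compressed site patterns with
per-pattern rescaling. Fitting jointly maximises kappa, the free omegas, and
all branch lengths with L-BFGS-B on log-transformed parameters. Gradients
with respect to branch lengths are analytic (a preorder pass reusing the
pruning partials; verified against finite differences); kappa/omega
derivatives use central differences, which is cheap because there are few of
them. Defaults: 3 optimisation starts (the first from the input tree's
branch lengths, kappa = 2, omega = 0.4; the rest jittered), relative
tolerance 1e-12, bounds keeping parameters positive. In the large replicated
experiments a single warm start is used, with the null model fitted first
and the alternative started from it — this also guarantees the nesting
inequality `logL_alt >= logL_null` numerically.

Codon frequencies are estimated from the data; F3x4 (position-specific
nucleotide frequencies, renormalised over sense codons) is the conventional
default, with F1x4, F61 and equal as options. Alignment columns containing a
gap or ambiguity in any species are excluded; premature stop codons in real
(pseudogene) input are masked as missing data for that species only, with a
warning, rather than discarding the whole column.

Nested branch partitions are compared with a likelihood-ratio test:
`2(logL_alt - logL_null)` floored at zero against a chi-square upper tail
with df equal to the difference in free parameters. Per-class constraints
support `free`, `fixed(value)` and `tied(other class)`, so both natural null
models — one shared omega, or the pooled group fixed to the background
estimate — can be expressed; the default report is the one-omega vs
two-omega comparison with df = 1.

## Lesion scanning

Coordinates are 1-based in reference numbering (the reference sequence's
ungapped positions), matching how critical residues are cited in the
literature (e.g. the human PON1 catalytic-calcium ligand N270). The scanner
reads query codons in the reference frame, so a premature stop is any
aligned stop triplet before the terminal reference codon, and synonymous
divergence elsewhere cannot change a call. Each maximal gap run (in query:
deletion; in reference: insertion) whose length is not a multiple of 3 is an
independent frameshift; two 1-nt gaps that jointly restore frame are still
two lesions — conservative, since no compensation rule is defensible without
transcript evidence. The critical-site screen compares each species' residue
at catalogued positions against the catalog residue; deletions are reported
with detail "deleted", untranslatable codons as "unresolved" (never counted
as substitutions). The shipped default catalog is the ten major PON1
active-site residues {Y71, I117, H134, H155, H184, R192, W202, F222, N270,
V304}. Splice-site checks require exon annotations and are not performed
without them.

## Expression statistics

Species means (not individuals) are the test units. Group contrasts use the
Mann–Whitney U test, two-sided, reporting both U (of the first group, with
midranks for ties) and the tie-corrected normal deviate Z. Exact p-values
come from the null permutation distribution when the sample is tie-free and
n1·n2 <= 400; otherwise the normal approximation is used, deliberately
without a continuity correction. Consequence: the exact and approximate
p-values can differ by up to ~0.04 at n around 8 (half the point mass of the
observed U); the gap shrinks with n and does not affect which comparisons
are significant at conventional levels. The antioxidant-panel screen runs
one two-sided test per gene with no multiplicity correction by default
(Benjamini–Hochberg available behind a flag), with direction taken from the
difference of group medians. Activity–expression correlation is OLS of
activity on natural-log TPM with a 0.01 pseudocount so zero-expression
pseudogenes remain usable. Kinetic slopes convert to enzyme units as
`U/mL = (dA/min ÷ (epsilon · path)) × (reaction/sample volume) × dilution`
with default molar extinction coefficients 1.31 (phenol), 5.56
(trichloropyridinol), 3 (IMHP) and 18 (p-nitrophenol) mM⁻¹cm⁻¹.

## Status classification

The classifier is deliberately rule-based and binary-with-exclusion. Rule
order: (1) any lesion or critical-site substitution → absent; (2) any plasma
activity > 0 or mean TPM >= 61.76 → present; (3) activity measured as zero
or TPM <= 41.3 → absent; (4) otherwise excluded, including lesion-free
DNA-only species. Lesions outrank expression because they are the only
irreversible evidence class. The present threshold is inclusive (>=) so the
boundary species sits on the functional side; TPM strictly between the two
thresholds with no other evidence is excluded rather than guessed. "Any
plasma activity" means any assayed substrate above 0 U/mL (configurable).
The thresholds are the observed liver expression of the lowest clearly
functional and highest clearly nonfunctional species in the Pon1 data; they
are data-derived constants, not fitted parameters.

## Phylogenetic logistic regression

Binary status is modelled as a two-state Markov switching process along the
tree. Each branch carries the equilibrium probability
`p = logistic(x_branch · beta)`, where `x_branch` is the covariate row of
the tip below a terminal branch and the mean over descendant tips for an
internal branch (the root uses the all-tip mean); the total switching rate
is the signal parameter alpha per unit branch length. Large alpha makes tips
independent Bernoulli(logistic(x_i beta)) draws — on a star tree the model
then reproduces ordinary logistic regression exactly, which is the oracle
test — while small alpha produces strong phylogenetic inertia. The simulator
and the estimator share this one parameterisation, so parameter-recovery
tests are internally consistent.

Fitting maximises the likelihood (2-state pruning) over (beta0, beta1,
log alpha) with L-BFGS-B from three starts; alpha is bounded (default
[1e-3, 1e3] on a tree internally rescaled to unit height — input branch
lengths are in millions of years and the rescaling only reparameterises
alpha; bound hits are flagged, not fatal). By default a Firth-style penalty
`0.5·log|X'WX|` (W the logistic information weights at the tip equilibria)
tames the separation that is routine at n = 9; plain ML is a flag away. The
predictor is standardised internally for optimisation and coefficients are
mapped back. Standard errors are Wald, from the numerical Hessian at the
optimum; AIC = 2k − 2·logL with k = 3 (intercept, slope, alpha) on the
unpenalised likelihood. Each trait is fitted in its own univariate model and
models are ranked by ascending AIC, with per-group extrema reported so the
"worst diving model vs best diet model" comparison is one line. Both
omega-6/(omega-3+omega-6) (bounded) and the raw omega-6:omega-3 ratio are
computed; the fraction form is the regression-facing default.

## Synthetic data: what it emulates, and what it does not

The generator produces (i) Yule trees (pure-birth, ultrametric, relabelled
sp01..spNN); (ii) codon alignments evolved under the branch-class model
above, with the root sequence drawn from the stationary codon distribution
so likelihood round-trips are exact; (iii) injected lesions — premature
stops, 1–2-nt frameshift deletions (never a multiple of 3; deletions rather
than insertions purely for simpler truth bookkeeping, detection is
identical), and critical-site substitutions — with an immutable truth
record; (iv) log-normal per-individual TPM around clade means (defaults put
terrestrial species near 400 TPM and aquatic near 8 TPM, inside the
observed 73–2,251 and 0.1–62 TPM ranges; log-normal is our choice, because
TPM is positive and right-skewed — no generative law is implied by the data);
and (v) binary traits from the same two-state switching process the
estimator assumes. One global seed expands into named substreams (tree,
alignment, lesions, expression, trait), so enabling a stage never perturbs
another stage's draws.

Deliberate simplifications: no read-level RNA-seq (TPM is drawn directly,
so mapping bias and length effects are absent); no alignment error (the
scanner sees the true alignment); no among-site rate variation or
non-stationarity in the codon model; lesion injection is independent of the
substitution process. Passing tests therefore demonstrate correctness of
the estimators under their own assumptions, not robustness to real-data
artefacts like misalignment or annotation error.

Truth-recovery exactness for the scanner is evaluated on an
identical-sequence backbone: on a diverged backbone, evolution itself
produces genuine critical-site substitutions that are correct calls but are
not in the injection record, so "exact set equality" would be ill-posed.
Stop and frameshift calls are additionally checked on diverged backbones,
where the 61-sense-codon simulator guarantees a clean negative control.

## Problem sizes used in the shipped experiments

Replicated experiments run at desk scale, chosen so each completes in
minutes on one core while keeping Monte-Carlo error well inside the asserted
tolerances: omega recovery and LRT power at 16 tips x 500 codons x 20
replicates; LRT type-I calibration at 6 tips x 150 codons x 200 replicates;
scanner exactness over 100 seeds; trait-model sign recovery at 50 tips x
100 replicates. The acceptance script (`scripts/acceptance.py`) re-runs the
same experiments at the sizes printed in its output.

## Known limitations

- The codon model has no among-site rate variation, no site- or
  branch-site selection classes, and assumes one stationary frequency
  vector; it matches the branch-model analysis it reimplements, nothing more.
- The branch covariate of the trait model (descendant-tip mean) is one of
  several defensible interpolations of unobserved ancestral covariates.
- The classifier's thresholds are constants derived from observed liver
  expression of Pon1 in aquatic vs terrestrial mammals; for other genes they
  should be re-derived.
- Exact Mann–Whitney p-values are only available for tie-free samples;
  ties always route to the tie-corrected normal approximation.
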