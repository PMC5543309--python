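# Methods

## Data model

All inference runs on a rooted chronogram (branch lengths in arbitrary time
units; no unit conversion is attempted) and a species × character matrix of
discrete states. Polytomies are accepted and treated as hard: the pruning
product and the Sankoff recursion simply run over all children. Root-to-tip
path spread is checked (`check_ultrametric`, relative tolerance 1e-6 by
default) but violations only warn, because posterior tree samples routinely
carry rounding noise. Zero-length terminal branches are allowed; zero-length
internal branches are collapsed only on request.

Missing (`?`) and inapplicable (`-`) cells are stored distinctly — their
fractions are reported separately — but both enter inference identically as
"no signal": an all-ones partial likelihood vector in the Mk machinery and a
zero cost vector in parsimony. This is mathematically the same as pruning
those tips from the tree for that character (the likelihood factorizes
through the absent subtree), without rebuilding trees per character.

## Mk models and the model zoo

A model is a constraint pattern over the ordered state pairs of a k-state
continuous-time Markov chain: equality classes of shared rates plus a set of
forced-zero transitions. Named patterns: `ER` (one rate), `SYM` (one rate
per unordered pair), `ARD` (all rates different), `ORD`/`ORDSYM`/`ORDER`
(ordered characters, non-adjacent transitions zero), `UNI01`/`UNI10`
(binary, one direction zero). Root priors: flat by default; `eq` variants
use the stationary distribution of the fitted Q; unidirectional models use
the point mass on their source state (the root state the model implies).
`EReq` is rejected because equilibrium equals flat there. For reducible
generators the "equilibrium" prior means the limiting distribution reached
from a uniform start (all mass on the absorbing class).

Transition probabilities are `exp(Qt)`. The per-branch matrices for a whole
tree are produced in one eigendecomposition of Q (k ≤ 4 in practice) with a
scaling-and-squaring fallback (`scipy.linalg.expm`) whenever the eigenvector
basis is ill-conditioned (condition number above 1e8). Partial likelihoods
are rescaled per node with accumulated log factors, so 800-tip trees pose no
underflow problem.

## Maximum likelihood and model choice

Rates are optimized in log space (bounds 1e-9 to 1e2 per rate) by L-BFGS-B
from five starts: one at the parsimony-informed scale (changes per unit of
total tree time) and the rest jittered around it with fixed seeds.
Non-convergence after the multistart budget flags the fit rather than
failing silently. Model choice is by AICc with Akaike weights; the sample
size n is the number of tips with observed states for that character — the
convention is exposed as an argument (`n_override`) because it is a genuine
knob, not a law. Candidate sets follow character kind: binary characters get
{ER, ARD, ARDeq, UNI01, UNI10}; ordered multistate characters add the ORD
family and its `eq` variants; unordered multistate get {ER, SYM, SYMeq, ARD,
ARDeq}.

Marginal ancestral probabilities come from the two-pass outside-inside
construction (equivalent to rerooting at each node), verified against
brute-force enumeration on small trees to 1e-10. Near-exact ties in the
modal state (|ΔP| < 1e-9) are reported as ties, never broken.

## Parsimony

Sankoff dynamic programming with unit (Fitch) costs by default for all
characters, including ordered ones — an |i−j| ordered-cost matrix is
available but off by default, since ordered parsimony is a stronger
assumption than the data usually warrant. MPR sets come from the down+up
pass: a state is in a node's set iff inside-cost plus outside-cost equals
the global minimum. A missing tip is reported as compatible with every
state. Nodes with more than one MPR state are reported equivocal.

## The reversible-jump sampler

The model space for a character with p free transition parameters is the set
of partitions of those parameters into unlabeled positive-rate classes plus
a distinguished zero class (any subset, possibly empty), excluding the
all-zero model. This convention is adopted as the definition because it is
the unique one reproducing both printed counts for the two-binary-trait
combined space (21,146 models over 8 parameters; 51 independent models over
4) — each count equals Bell(p+1) − 1, which the test suite cross-checks
against an independent Bell-number oracle. The prior over models is uniform
on that space: the ratio (21146−51)/51 used as prior odds in the Bayes
factor is then exactly the model-count ratio. Class rates have an
exponential prior with mean m; m has a uniform hyperprior on (0, 1].

Moves, with default mix 40% / ~40% / 10% / 5% / 5%:

* **Rate update** — multiplicative log-normal (σ = 0.6) on one class rate;
  Metropolis–Hastings with the exponential prior and the log-scale Jacobian.
* **Reassign** — move one uniformly chosen parameter to another existing
  class, a fresh singleton class (rate drawn from the exponential prior), or
  the zero class (disallowed only when it would create the all-zero model).
  The number of legal placements depends only on the partition of the other
  parameters, hence is identical in the forward and reverse directions, and
  the born/killed class rate's prior density cancels against its proposal
  density, so the acceptance probability is exactly min(1, likelihood
  ratio). This single move performs all class splitting and merging. It was
  chosen over separate split/merge moves deliberately: its Hastings ratio is
  exact by construction, which makes the prior-recovery property (below)
  hold mechanically instead of resting on Jacobian bookkeeping.
* **Tree switch** — propose a uniformly drawn tree from the posterior
  sample; accept on the likelihood ratio. This emulates per-generation tree
  sampling and integrates phylogenetic and dating uncertainty.
* **Hyperprior update** — fresh uniform draw of m; accepted on the rate
  prior ratio.
* **Model redraw** — independence proposal of a whole model from the
  uniform prior with all rates drawn from the rate prior; accepted on the
  likelihood ratio. Enabled when the space is enumerable (p ≤ 8); for larger
  spaces its weight folds into the reassign move.

A model under which the data are impossible (zero-rate classes blocking an
observed pattern) has likelihood zero and is simply rejected; only NaN
log-likelihoods abort the chain. Prior-only chains (every tip missing) skip
likelihood evaluation entirely, and the test suite verifies that they
recover the prior: uniform model-visit frequencies (chi-square), uniform
hyperprior mean (KS) and the class-rate marginal matching its
exponential-with-uniform-mean mixture, whose CDF is 1 − E₂(r) (KS). Those
checks thin the chain (samples every 10 generations for the model counts,
every 500 for the slowly-updating hyperparameters) so the nominal test
levels apply to near-independent draws.

Defaults mirror a long production run — 10M generations, sampling every
100, 1M burn-in — while every analysis here passes explicitly smaller
values; trace files are tab-delimited and Tracer-compatible, and burn-in
adequacy is ultimately the user's judgement on that trace. The root prior
inside Bayesian runs is flat by default (equilibrium by flag). Ancestral
states at focal nodes are recorded as marginal probability vectors by
default; drawn states are available (`marginalize_ancestral=False`).
Focal clades are defined by taxon sets; in trees where a set is not
monophyletic the MRCA is used anyway and the fraction of such samples is
reported. Chains are bit-for-bit reproducible given seed, settings and
inputs.

## Correlation tests

Two binary characters are combined into a 4-state chain over (00, 01, 10,
11), first trait the high bit, with the four dual transitions (both traits
changing at once) forced to zero — 8 free parameters. `SYMnodual` is defined
as forward/backward equality for each of the four allowed edges (4 free
parameters; still *dependent*, because each trait's rates differ across the
other trait's states); `UNCORRnodual` shares each trait transition across
the other trait's states (4 free parameters, independent). A rate-class
model is classified independent exactly when the two context-specific
copies of every trait transition share a class (or are both zero); the 51
independent models are in bijection with the 4-parameter partitions. A tip
missing one trait still carries partial signal via an indicator partial
vector over the consistent joint states.

Significance defaults — cumulative correlated Akaike weight > 0.5 (ML) and
BF_DI > 3 (Bayesian) — are configuration values, and both criteria are
always reported separately.

## Synthetic data

The generator exists to exercise every pipeline stage under known truth.
Yule trees are simulated forward (expected root age Σ_{j=2..n} 1/(jλ));
characters evolve by exact event-time (Gillespie) sampling so event logs
are available — e.g. to assert that "nodual" generators never produce dual
transitions; cells are masked independently at a target rate (default 27%,
with a share coded inapplicable) to mimic haphazardly distributed gaps in
exemplar-scored morphological matrices; pseudo-posterior tree sets jitter
node ages multiplicatively bottom-up (which preserves parent–child order
and exact ultrametricity) and apply a few NNI moves preferring short
internal edges, mimicking variation at weakly supported nodes.

What the generator does *not* emulate: phylogenetic signal shared across
characters beyond the tree itself, rate heterogeneity across lineages,
correlated missingness (inapplicability in real matrices is structured by
organ absence, not random), or topological uncertainty beyond local NNI
moves. Passing tests therefore demonstrate correctness of the machinery and
calibration under the models' own assumptions, not robustness to their
violation on real data.

The study-shaped benchmark (`study_shaped_dataset`, 792 species × 27
characters × ~27% missing) is used for load testing and the end-to-end
check; the analysis scripts default to a 120 × 12 replica with 50
pseudo-posterior trees, and the reconstruction stage uses 20k-generation
chains on 25 trees — sizes chosen so the full pipeline runs in a few
minutes while leaving every statistical property it demonstrates intact at
larger settings.

## Numerical and design choices

* Combined-state order fixed as (00, 01, 10, 11), trait A the high bit;
  recorded in `PAIR_STATE_LABELS` / `PAIR_PARAM_LABELS`.
* Credibility intervals are equal-tailed sample quantiles.
* ESS uses n / (1 + 2Σρ_k) with Geyer's initial-positive-sequence
  truncation; a zero-variance trace reports NaN (undefined) rather than a
  number; values below 200 are flagged.
* Rate classes are canonicalized by first occurrence, so model identity
  (and model-visit counting) is well defined.
* The confidence rule: 3 stars = all three methods name the same single
  state and the rjMCMC CI lower bound ≥ 0.75; 2 stars = same with CI ≥ 0.5;
  1 star = agreement with a weak CI, or exactly one soft method (equivocal
  MP set / ML tie) still containing the agreed state; 0 = any two
  single-state answers conflict or more than one method is soft. The
  thresholds are explicit configuration; scores are monotone in the CI
  lower bound, all else equal.

## Known limitations

* No hidden-rate (HMM-style) expansions, branch-heterogeneous rates, or
  correlation among more than two discrete characters.
* ML runs on a single summary tree (optionally replicated per tree); only
  the rjMCMC integrates over tree samples.
* The rjMCMC model prior is uniform over the enumerated space; alternative
  priors over class counts are not implemented.
* Marginal-likelihood estimation (stepping stone) and parallel tempering
  are out of scope; model support is measured by visit frequencies only.
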