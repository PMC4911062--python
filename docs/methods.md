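# Methods

## Languages

A language is an item×slot grid with a grammaticality label
(grammatical / ungrammatical / withheld) and a presentation count per cell.
Exactly one cell is withheld (the exception cell).  The word-order family
has three slots realized as the S-before-O orders S-O-V, S-V-O, V-S-O; the
contraction family has two slots realized as subject- vs object-position
contraction.  Slot→realization mappings are uniformly random bijections per
participant.  Surface forms (nouns, verb/modifier lexemes, the apostrophe
contraction orthography) are cosmetic: both learners operate on abstract
(item, slot) identities, so model results are invariant to the mapping and
the noun randomization.  The three shipped languages:

| language | items | slots | exception | trials (gram/ungram) |
|---|---|---|---|---|
| exp1 | V1–V4 | C1–C3 | V4×C2 | 96 (72/24) |
| exp2 | V1–V5 | C1–C3 | V5×C2 | 160 (120/40) |
| exp3 | M1–M4 | P1–P2 | M4×P2 | 128 (96/32) |

New languages are defined in a flat YAML config (family, items, slots,
cells[item][slot] = {label, freq}, nouns, lexicon); a config that is not
total, has a nonzero-frequency withheld cell, or more than one withheld
cell is rejected with the offending cell named.

## Sequence generation

Per-cell counts always equal the frequency matrix exactly; randomness only
affects ordering and noun pairing.  Word-order family: trials form blocks
containing each item once; blocks are grouped into 8-block cycles within
which each item works through a fixed quota of its slots
(frequency / number-of-cycles — 3/3/2 per verb for exp1).  When the number
of ungrammatical trials per cycle divides evenly over the blocks (exp1:
exactly 1 per block of 4, giving the 3:1 grammatical ratio), the per-block
count is enforced exactly; otherwise (exp2: 10 ungrammatical trials over 8
five-trial blocks) each item's ungrammatical trials land in randomly chosen
blocks of the cycle and only the per-cycle split is fixed.  Contraction
family: each modifier appears once per cycle in random order, with its
position/label sequence shuffled within fixed-quota chunks of 8.
Noun pairs are uniform over ordered pairs of distinct nouns, independent
across trials.  Infeasible frequency matrices (not divisible into the
block/cycle structure) raise an explicit error rather than silently
approximating.

## Strong-sampling learner

Generative model for the grammatical trials only:

    n_i | theta_i        ~ Multinomial(theta_i)          (counts of item i over slots)
    theta_i | alpha, beta ~ Dirichlet(alpha * beta)
    beta                  ~ Dirichlet(b),   b = 1 (uniform) by default
    alpha                 ~ Exponential(mean = 5)

Inference is exact-to-quadrature and fully deterministic: alpha is
marginalized over 50 log-spaced grid points on [0.01, 100] (weights =
exponential density × grid spacing) and beta over an interior simplex
lattice (resolution 512 for two slots, 48 for three — a few hundred
points).  Within each (alpha, beta) grid point the predictive is the
conjugate Dirichlet-multinomial rule (n_is + alpha·beta_s)/(n_i + alpha);
grid points are mixed by their normalized joint posterior weight.  Pinning
alpha and beta to single values recovers the closed-form predictive
exactly, which the test suite checks to 1e-9; against continuous
integration over beta on small problems the lattice agrees to well under
1e-3.  The predictive is monotone in observed counts and exchangeable in
trial order by construction (counts are sufficient).

The grammaticality *score* of a cell is its predictive probability divided
by the item's maximal slot probability — 1 for the modal slot, near 0 for
never-observed slots after heavy training.  This ratio-to-max
normalization is our choice for putting a distribution-estimating model on
the same [0, 1] grammaticality axis as the classifier below; any monotone
normalization preserves the qualitative contrast.  One consequence worth
noting: the shared base distribution gives the exception slot slightly
*more* mass than a slot that is ungrammatical for every item (0.008 vs
0.002 on exp1), because other items lend the exception slot base-level
support; both are far below the 0.5 midpoint.

Ungrammatical trials shown to strong-condition participants are excluded
from the model fit: the generative learner models the distribution of
grammatical utterances.

## Weak-sampling learner

Discriminative model over all labeled trials.  Features of a sentence:
intercept + indicators for its item, its slot, and its item×slot pair
(dimension 1 + I + S + I·S; exactly three non-intercept ones).  Labels:
grammatical = 1.  Priors: zero-mean Gaussians with one standard deviation
per feature family, each selected from the grid {0.25, 0.5, 1, 2, 4} by
maximizing the Laplace-approximated log marginal likelihood; the intercept
scale is fixed at 10.  For each scale combination the MAP is found by a
trust-region Newton method polished with explicit Newton steps to gradient
norm < 1e-10 (the objective is strictly convex); non-convergence raises
with diagnostics.  Cell-level (successes, trials) counts are the
sufficient statistic, so duplicating every trial cannot flip any cell's
predicted direction.  A pair feature that never occurs in training has
zero likelihood gradient, so its MAP coefficient is exactly the prior mode
0 — the formal reason the exception cell inherits the (grammatical-leaning)
item and slot main effects.  Predictions at exactly 0.5 are reported as
"undetermined", never rounded.

## Synthetic participants

All behavioral datasets are simulated, not measured; no human data ship
with the package.  Condition assignment is balanced.  Each
strong-condition participant's judgment probability for a cell is the
strong model's score; weak-condition, the weak model's probability.
Responses pass through a two-parameter noise model,
P(grammatical) = λ/2 + (1−λ)·sharpen(p, γ) with
sharpen(p, γ) = p^γ / (p^γ + (1−p)^γ): λ is a lapse rate (uniform
guessing; λ = 1 is pure guessing), γ a determinism exponent.  Defaults
λ = 0.1, γ = 1 — enough noise that accuracies are not at ceiling, while
condition differences remain detectable at 25 participants per condition.
The test schedule judges every cell twice plus two extra judgments of the
exception cell (26 judgments for exp1); productions are 4 per item,
sampled from the lapse-mixed *input* distribution in both conditions
(usage frequencies, unlike judgments, do not differ by condition);
completions are 2 forced choices per cell with contraction probability
0.5 × the condition's model grammaticality (0.5 being a neutral overall
contraction propensity).

What the simulator does **not** emulate: between-participant heterogeneity
(every simulated participant shares the condition's probabilities — real
judgment data show bimodal alternation patterns), learning trajectories,
item-level memory effects, and reaction times.  Passing tests therefore
show that the pipeline detects the model-level contrast under iid lapse
noise, not that it reproduces human statistic values.

## Statistics

* **Fractional-tally χ²** — for one cell, each participant contributes
  their response proportions (k/m, (m−k)/m) to their condition's 2×2 row;
  rows sum to participant counts.  Pearson's χ² (no continuity correction,
  no simulation-based p) on df = 1.  The fractional construction is a
  conservative repeated-measures correction, exact when a participant's
  repeated responses are fully dependent — the regime under which our
  calibration simulations hold the 5% type-I rate; with truly independent
  repetitions it is conservative by a factor of m.
* **Two-way ANOVA** — fixed effects of sentence cell × condition on
  participant-level judgment proportions; reports the condition main
  effect (numerator df 1) and the interaction (numerator df = cells − 1;
  11 for exp1-shaped designs), with residual MSE.  Zero residual variance
  is flagged rather than reported as a number.
* **Repeated-measures binomial GLM** — logit link on per-participant
  per-cell success counts, predictors condition (strong = 1),
  exception-cell indicator and their interaction; repeated measures
  handled by participant-cluster-robust covariance (no random effects —
  working independence with a sandwich correction).  Separation is
  detected (non-finite or |coefficient| > 15) and raised, with an optional
  L2-penalized fallback (`ridge > 0`, robust SEs then unavailable); the
  pipeline uses that fallback automatically at small samples and flags it
  in the output.

Calibration (checked in the test suite): the χ² and the GLM condition test
hold their nominal 5% level within ±2 points over 500–1000 null
simulations, and the GLM recovers known generating coefficients to within
0.05 at 200 participants over 500 replicates.

## Problem sizes and determinism

Model fits take well under a second per language (grid quadrature for the
strong learner; 125 convex fits for the weak learner's scale grid).
Simulation studies in the tests use 400–1000 replicates at the designs'
own sample sizes (25–200 participants per condition).  All randomness
flows from explicit seeds through numpy Generators, hierarchically split
per participant and phase; identical configs reproduce byte-identical
bundles.

## Known limitations

* The two learners are principled reconstructions of the model class
  described in the source literature, not transcriptions of specific
  published equations; the qualitative exception-cell contrast is robust
  to the open choices (hierarchy depth, grids, score normalization), all
  of which are exposed as parameters.
* The fractional χ² p-value is exact only under full response dependence
  (see above); sensitivity to that convention can be probed by changing
  the schedule to one judgment per cell.
* The block scheduler enforces exact per-block composition only when the
  totals allow it; for designs like exp2's five-item blocks the
  grammatical:ungrammatical ratio is exact per cycle, not per block.
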