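# Methods

## Affiliation networks and the exposure statistic

For each communication theme the package builds a two-mode (bipartite)
count matrix over the users who posted at least one message in that theme:
`counts[i, k]` is the number of user *i*'s theme messages carrying speech
act *k*. A multi-label message increments every act it carries; the column
set can be restricted to one of the two communication styles (push-in:
assertion, stance, declarative, directive, statement; interactive
turn-taking: question, expressive, emotion), and a user who posted in the
theme but never used an act from the chosen style keeps an all-zero row.

**Binarization.** A user is affiliated with an act when their count reaches
the network's median count, with two deliberate readings fixed as defaults:

* the median is taken over the *positive* cells of the network
  (zero cells mean the act was never expressed, and including them would
  drive most thresholds to zero and saturate every network);
* the comparison is `>=`, so ties at the median are affiliations, and a
  network where every user expresses every act exactly once stays
  non-empty.

Both choices are arguments (`median_base`, implicit `>=`), and each
theme × style network is binarized independently, since each is modeled
separately. The threshold is stored on the matrix and logged.

**Coaffiliation and exposure.** `C = A Aᵀ` over the binary matrix;
`D = diag(C)` is each user's affiliation degree. Affiliation exposure is
the coaffiliation-weighted mean of peers' engagement with the diagonal
excluded, `F_i = Σ_{j≠i} C_ij y_j / Σ_{j≠i} C_ij`. Users with an all-zero
off-diagonal row (isolates) have no defined weighted mean; they are
assigned exposure 0 and flagged, and they remain in regressions (their row
of `I − ρW` is an identity row, so they contribute ρ-free likelihood
terms). A `nan` policy is available for callers that prefer dropping them.

## The two-mode network autocorrelation model

    y = ρ W y + X β + γ D + ε,  ε ~ N(0, σ² I)

* `y` — posting frequency over the full analysis window (raw counts by
  default; `log1p` behind a flag, since no transform is assumed).
* `W` — row-normalized `C` with zero diagonal, so that `W y` equals the
  exposure vector entrywise for non-isolates. This is the reading under
  which the exposure statistic and the autocorrelation term are the same
  object; the raw-`C` alternative (which would make `Wy` a weighted sum
  rather than a mean) is available via passing `C` directly.
* `X` — intercept plus one binary column per persona axis: any medication
  use (oral / injectable / both → 1), pre-existing diagnosis (→ 1), and
  lifestyle changes (→ 1). Single-coefficient-per-axis encoding matches
  the one-row-per-axis reporting convention; users whose signature carries
  no information are retained and coded 0 rather than dropped, keeping the
  per-theme n equal to the network size.
* `D` — affiliation degree, included as a control against underestimating
  ρ through degree effects; passing `D=None` omits it (used by the guard
  test showing its omission shifts estimates).

**Estimation.** Profile (concentrated) likelihood. For fixed ρ,
`z = (I − ρW) y` is regressed on `[X, D]` by least squares, giving β̂(ρ),
γ̂(ρ) and σ̂²(ρ) = RSS/n in closed form; the profile

    ℓ_p(ρ) = −(n/2)(log 2πσ̂²(ρ) + 1) + Σ_i log|1 − ρλ_i|

is maximized by bounded scalar search (`scipy.optimize.minimize_scalar`,
`xatol = 1e−10`) on the open interval `(1/λ_min + δ, 1/λ_max − δ)`,
δ = 1e−6, spanned by the eigenvalues λ of `W`. Fitting is deterministic —
no randomness enters the optimizer. With ρ fixed at 0 the procedure *is*
ordinary least squares of `y` on `[X, D]`, which the tests assert to
1e−6.

**Spectrum.** `W` obtained by row-normalizing a symmetric `C` is
diagonally similar to the elementwise-symmetric `sqrt(W ∘ Wᵀ)`, so its
spectrum is real and is computed through the symmetric eigenproblem
(markedly better conditioned than general `eig`); isolate rows contribute
zero eigenvalues. `log|det(I − ρW)| = Σ log|1 − ρλ_i|` then costs O(n) per
ρ after one decomposition. The identity is verified against dense
`slogdet` on random 8×8 matrices over a ρ grid spanning the interior of
the admissible interval; within 2.5% of the interval endpoints the
determinant approaches zero and *both* routes lose precision, so no method
comparison is meaningful there and the model never evaluates there either.

**Uncertainty.** Standard errors come from the inverse of the numerically
differentiated (central differences, relative step 1e−5) observed
information of the full likelihood in (ρ, β, γ, σ²) at the optimum;
p-values are two-sided normal. Significance is reported with the footnote
convention a/b/c for p < .001/.01/.05.

**Simulation.** The forward model draws
`y = (I − ρW)⁻¹ (Xβ + γD + ε)` with seeded Gaussian noise; ρ at or beyond
an interval endpoint raises a singularity error.

## The synthetic community generator

The generator emulates the structure of the ADA type 2 diabetes support
community at the level of its published descriptive statistics; defaults
are the study conditions.

* **Scale**: 529 signature users; per-user message counts Poisson with
  mean 107.7 (≈ 57k messages); window 2014–2021 with yearly weights
  proportional to the published yearly message counts.
* **Themes**: default mode draws one theme per message from weights
  proportional to the published per-theme message counts; the `ada-like`
  preset instead uses per-theme Bernoulli inclusion at the published
  multi-label shares (e.g. social support on 99.9% of messages), with at
  least one theme guaranteed.
* **Speech acts**: each user has an interactive-style propensity drawn
  from a Beta distribution with mean 0.35; per message, acts are included
  by Bernoulli draws at the labeled-subset prevalences (assertion 0.563,
  statement 0.370, …; 0.15 for the three acts without a published
  prevalence), boosted for the message's style and damped (×0.3) across
  styles, with at least one act forced from the style.
* **Personas and signatures**: persona axes are sampled from the published
  distribution with each axis renormalized to sum to 1 (the printed counts
  sum to 531 over 529 users). Signatures are rendered from templates
  ("Diagnosed: March 2009. Meds: metformin 500 mg twice a day. Walking
  daily.") constructed so the extraction lexicons recover the sampled
  persona exactly; a `signature_noise` probability drops sentences to
  degrade recoverability on demand.
* **Recovery mode** bypasses message generation: the binary affiliation
  matrix is i.i.d. Bernoulli per (user, act) at density 0.25, C/W/D are
  derived by the pipeline operations, X is drawn from the persona
  marginals, and y from the forward model, so every parameter has exact
  ground truth. An all-isolate draw is retried up to 10 times, then
  raises. The default density matters: at density 0.25 a user holds ~2 of
  8 acts and the coaffiliation projection is heterogeneous, whereas as
  density grows the rank-k projection saturates (every off-diagonal of C
  approaches k/4), every row of W approaches the uniform average, and ρ
  loses identification — its SE grows by an order of magnitude. This
  saturation regime is a genuine property of dense two-mode projections,
  not an artifact of the estimator.
* **Seeding**: one global seed expands into independent substreams
  (personas, messages, noise) via `numpy.random.SeedSequence.spawn`.

**Experiment sizes.** The recovery study runs 100 replicates at n = 300,
ρ = 0.3, k = 8; the sign-pattern suite generates one network per
theme × style at the published per-theme user counts (529/505/471/360/
391/378) with ρ = +0.3 for interactive and −0.3 for push-in networks,
γ = 0.7, σ = 1, β = (5, −0.5, 0.5, 0.5). The ±0.3 magnitude is the
package's own choice of a clearly detectable but moderate autocorrelation
on the row-normalized scale (the published coefficients are on an
unstated weight scale and are not directly transferable); γ and β
magnitudes are loosely anchored to the published coefficient table.

## Persona extraction

Extraction is total and deterministic: lexicon hits over the lowercased
signature. Oral {metformin, glipizide}; injectable {novolog, lantus};
both → `both`; explicit no-medication phrases {"no meds",
"diet controlled", "no medications"} → `no_medications`, overridden by any
medication hit; lifestyle terms {low-carb(ohydrate), mediterranean,
treadmill, walking, diet} → `yes` ("diet controlled" is simultaneously
no-medication evidence and a lifestyle change). The diagnosis year is the
earliest 4-digit year in [1940, 2100] within 40 characters after a
diagnosis cue ({diagnosed, diagnosis, dx, since}); bare years without a
cue are ignored so dosages and glucose readings are never misread; the
cutoff (default 2018) splits newly diagnosed (≥) from pre-existing (<).
Since every rule is a global predicate, permuting sentences cannot change
the result.

## Descriptive tables

Percentages are rounded half-up to one decimal via `decimal.Decimal`
(matching printed-table convention, not banker's rounding), and every
published count/share pair used as an anchor recomputes exactly under this
rule. Yearly user counts intentionally sum to more than the unique-user
total (multi-year users are counted per active year). The theme table is
restricted to messages by persona users — the exposure-model subset —
mirroring how the per-theme dataset sizes were defined.

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline's operations are internally
consistent, that the estimator is unbiased and calibrated under the
model's own data-generating process, and that the qualitative
style-sign pattern is recoverable when it is truly present. They do not
validate the substantive claim on real forum data: the generator has no
reply-thread structure, no temporal tie dynamics, no text, independent
theme/act draws given style, and corpus-mode engagement is Poisson with
no built-in peer influence (so corpus-mode fits should find ρ ≈ 0, and in
nearly saturated networks ρ is weakly identified — visible as large SEs
in the demo pipeline). Cross-sectional affiliation data cannot separate
influence from selection.

## Numerical choices and degenerate inputs

* ρ search bounds offset by δ = 1e−6 from the spectral endpoints; scalar
  tolerance 1e−10; profile trace retained for convergence diagnostics.
* Observed-information Hessian steps: 1e−5 × max(|parameter|, 1).
* Rank-deficient `[X, D]` raises a design error naming the collinear
  columns (near-zero QR pivots).
* Empty theme, all-zero count matrix, and all-isolate recovery draws each
  raise typed errors rather than degenerate results.
* Exposure of an isolate: 0 (flagged), configurable to NaN.
* n must exceed the coefficient count + 1 for a fit.

## Known limitations

* SEs are plain observed-information; no sandwich/robust variants.
* The estimator assumes homoskedastic Gaussian errors; engagement counts
  are overdispersed in real communities (a log1p flag exists, but no count
  likelihood).
* BCT-based networks are constructible, but no BCT model fits are produced
  by default.
* One-mode projections beyond C (centralities, communities) and any
  Bayesian or spatial-error variant are out of scope.
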