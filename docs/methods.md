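# Methods

## Model and assumptions

The structural model is y_i = x_i'β + ε_i with kx exposures x and kz ≥ kx
instruments z satisfying E(z ε) = 0. The two samples are i.i.d. draws
from a common population and independent of each other, with finite
fourth moments, nonsingular instrument second moments Q_zz1, Q_zz2, and a
rank-kx cross moment E(z x') (strong identification). The sample-size
ratio n1/n2 converges to a positive constant α. Conditional
heteroskedasticity of both the reduced-form error u = ε + v'β and the
first-stage errors v is allowed throughout and is the reason the robust
variance exists: E(u² z z') = Ω_y1 and E(v v' ⊗ z z') = Ω_x2 need not
have the homoskedastic product form.

Common sampling from one population implies Π_x1 = Π_x2: the sample-2
first stage consistently predicts sample-1 exposures. That equality — not
equality of the instrument second moments — is what consistency of β̂
needs. The package therefore never pools Q̂_zz1 and Q̂_zz2, and the
sample-2 information enters the variance through Z₂'Z₂ only. The weaker
scenario E(z₁x₁') = c·E(z₂x₂'), E(z₁z₁') = c·E(z₂z₂') with c ≠ 1 leaves
Π_x1 = Π_x2 intact, so β̂ remains consistent and asymptotically normal;
a variance estimator that forces Q_zz1 = Q_zz2 (Inoue–Solon) does not
remain consistent, and the simulation studies below measure exactly that.

## Estimators and variance formulas

Point estimate: β̂ = (X̂₁'X̂₁)⁻¹X̂₁'y₁ with X̂₁ = Z₁Π̂_x2. The linking
matrix Ĉ = (X̂₁'X̂₁)⁻¹X̂₁'Z₁ satisfies ĈΠ̂_x2 = I_kx identically and
equals Π̂_x2⁻¹ when just identified.

Variance methods (all kx × kx, finite-sample scale):

* `robust` / `cluster`: Ĉ V̂ar(π̂_y1) Ĉ' + (β̂'⊗Ĉ) V̂ar(vec Π̂_x2) (β̂⊗Ĉ'),
  with stage sandwiches of the matching flavor.
* `homoskedastic`: σ̂ᵤ²(X̂₁'X̂₁)⁻¹ + (β̂'Σ̂_vβ̂)Ĉ(Z₂'Z₂)⁻¹Ĉ', where
  σ̂ᵤ² uses the reduced-form residuals and Σ̂_v the first-stage
  residuals, both with divisor n (no degrees-of-freedom correction: the
  justification is plim-based).
* `inoue_solon`: (σ̃ᵤ² + (n₁/n₂)β̂'Σ̂_vβ̂)(X̂₁'X̂₁)⁻¹ with σ̃ᵤ² from the
  structural residuals y₁ − X̂₁β̂. Offered only with homoskedastic stage
  inputs — it is derived under homoskedasticity, and accepting robust
  stage vcovs would misrepresent what it estimates; any other request
  errors.
* `scalar_delta`: (V̂ar(π̂_y1) + β̂²V̂ar(π̂_x2))/π̂_x2², valid for
  kx = kz = 1 only; the robust formula reduces to it algebraically there
  (asserted to 1e-10 in tests rather than shared as one code path).

Confidence intervals use normal critical values: the theory is asymptotic
and defines no finite-sample degrees of freedom.

Stage covariances: HC0 is the default robust flavor (the formulas are
plim-justified; no small-sample correction), with n/(n−kz) rescaling and
a G/(G−1) cluster factor available as explicit options. The cluster meat
is the literal sum over clusters of score-sum outer products. `vec`
stacks columns (column-major) package-wide; the per-observation score of
a multi-response stage is v ⊗ z (response-major), matching the
(I_kx ⊗ (Z'Z)⁻¹) bread structure.

## Generalized availability and the stacked covariance

When exposures are observed in sample 1 only, sample 2 only, or both,
each first-stage column comes from OLS on the corresponding row set
(pooled rows with equal weight for "both" — plain OLS on the stacked
sample). Stages sharing rows have correlated coefficients, so the
variance is (δ̂'⊗Ĉ) V̂ar(θ̂) (δ̂⊗Ĉ') with δ̂ = (1, −β̂')' and V̂ar(θ̂)
the joint sandwich of all stage coefficients: per underlying observation,
the scores of every equation using it are stacked (zeros elsewhere), the
meat sums stacked-score outer products (per cluster under the cluster
flavor), and the bread is block-diagonal (Z_e'Z_e)⁻¹. Zero cross-blocks
are a *consequence* of disjoint observation (or cluster) sets and are
additionally enforced exactly, never special-cased by availability
pattern. On a standard all-sample-2 design this expression collapses to
the robust formula above; the collapse is asserted at 1e-10.

## GMM and the Hansen test

The moment conditions are E[z₁(y₁ − z₁'Πβ)] = 0 (kz) and
E[(x₂ − Π'z₂) ⊗ z₂] = 0 (kz·kx). The criterion g'Wg is quadratic in β
given Π and in vec(Π) given β, so it is minimized by alternating exact
linear solves — deterministic, derivative-free, no step sizes —
initialized at (β̂_ts2sls, vec Π̂_x2), with convergence declared at
relative parameter change < 1e-10 (cap 500 iterations; the criterion is
asserted non-increasing each iteration). In just-identified designs the
initializer already solves the moments exactly.

Scaling convention: moment variances are expressed on the n₁ scale,
S = blockdiag(S₁, α̂·S₂) with α̂ = n₁/n₂, S₁ = n₁⁻¹Σ z₁z₁'û², S₂ =
n₂⁻¹Σ (v̂v̂')⊗(z₂z₂') (homoskedastic analogues in step 1, which makes the
step-1 criterion identical to the minimum-distance form in the
unrestricted stage estimates). Step 2 inverts the robust S at the step-1
residuals; block-diagonality across samples is imposed exactly, by
independence. J = n₁·g'S⁻¹g is then asymptotically χ²(kz − kx); the
convention is validated by the simulated size (≈ 4.9% at the nominal 5%
under the canonical design). The parameter covariance is the standard
GMM sandwich (G'WG)⁻¹G'WSWG(G'WG)⁻¹/n₁.

## Synthetic data

The generator draws z ~ N(0, Σ_z), first-stage errors and structural
error jointly normal with unit variances and correlation ρ between ε and
each v component (the endogeneity), x = Π'z + v, y = x'β + ε.
Heteroskedasticity multiplies each error by sqrt(exp(γ'z)) — always
positive, smooth, homoskedastic at γ = 0, strength set by ‖γ‖. The c
scenario scales sample-1 instruments by √c, which scales both instrument
second moments and cross moments by c while leaving Π common. An optional
cluster structure adds a shared within-cluster normal term
(equicorrelation ρ_c) to all errors. The two samples consume independent
child streams of one seed, so changing n₁ never perturbs sample 2.

Canonical study design (`default_test_spec`): kz = 3, Σ_z = I, one
exposure, β = 1, Π = (1, 0.8, 0.6)', ρ = 0.5, γ = (0.5, 0, 0) on both
errors, n₁ = n₂ = 2000. The population first-stage F is in the hundreds,
so variance and coverage results are not confounded by weak instruments.
The three-exposure layout (`general_availability_spec`) uses
β = (1, −0.5, 2) with a diagonally dominant Π and availability
x1: sample 1 only, x2: sample 2 only, x3: both.

What the generator does *not* emulate: non-normal errors, genetic-data
realism (discrete genotypes, allele frequencies, LD), survey weights, or
missingness. Passing tests show the estimators and variance formulas
behave as the sampling theory predicts under the assumed structure; they
do not certify behavior under violations of it (weak instruments,
pleiotropy, selection).

## Simulation study designs

* Robust-CI coverage: canonical heteroskedastic design, 1000
  replications, judged against the exact binomial 99% band around 0.95
  ([0.932, 0.968] at 1000 reps). Long-run coverage measures ≈ 0.945.
* Inoue–Solon inconsistency: c = 2, γ = 0 (homoskedasticity isolates the
  c mechanism), n₁ = n₂ = 5000 with 2000 replications. The asymptotic
  variance ratio V_IS/V is 0.8 under these parameters (expected IS
  coverage ≈ 0.92); n = 5000 is used because at n = 2000 the
  finite-sample variance of β̂ has not yet reached its asymptote and the
  comparison would sit on the band edge rather than measure the
  asymptotic property.
* Hansen J size: canonical design, 1000 replications, band
  [0.032, 0.068].
* Root-n rate: RMSE at n = 8000 vs n = 2000 over 500 replications each;
  the theoretical ratio is 0.5, asserted ≤ 0.55.
* Bootstrap cross-checks: two-sample pairs bootstrap (resampling each
  sample's rows independently), 2000 resamples at n = 5000, compared to
  the analytic variance within 15% relative error (Frobenius for the
  stacked stage covariance).

Per-replication seeds come from a counter construction
(SeedSequence(master, rep)), so studies are reproducible across processes
and any replication can be re-run alone. Replications raising singularity
or convergence errors are excluded and counted; a report warning fires
above 1% exclusions.

## Numerical choices and degenerate inputs

* Singularity: any Gram-matrix inversion checks the reciprocal condition
  number against 1e-12 and raises a named error — no silent
  pseudo-inverse.
* Missing values are rejected at load, never imputed: the i.i.d. sampling
  theory has no missingness mechanism.
* Instruments are matched across samples by column name, not position;
  silent positional misalignment is the most dangerous user error in
  two-sample designs.
* Partialling residuals carry no degrees-of-freedom correction, matching
  the divisor-n residual variances downstream; partialling is idempotent
  and equals the included-instrument route for the exposure coefficients
  (both tested).
* Weak instruments are reported (per-exposure first-stage Wald F) but
  never alter the estimator; no weak-IV-robust procedures are provided.
* JSON output rounds to 12 significant digits and validates against the
  shipped schemas.

## Known limitations

Two samples only; the outcome must live in sample 1. No
summary-statistic (per-variant beta/SE) input mode, no survey weights, no
HC2/HC3 or HAC covariances, no continuously-updated GMM, and no
many-weak-instrument corrections. The Inoue–Solon method is a comparison
estimator, deliberately restricted to homoskedastic inputs.
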