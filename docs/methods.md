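# Methods

## Model and assumptions

All computation happens at a single, implicit frequency ω. Source activity
is a zero-mean, stationary, circularly-symmetric complex Gaussian process
fully described by its Hermitian PSD spectral matrix `S_x` (p × p); sensor
noise is white, `S_e = σ² · ν · I_n`, with ν the largest eigenvalue of
`L Lᵀ` so that σ is dimensionless. Sensor data follow `Y = L X + E` with
i.i.d. columns. The estimand is the off-diagonal part of `S_x`: the entry
`γ_kl` carries interaction strength (magnitude) and lag (phase). No
multi-frequency spectra, tapering, autocorrelated noise, or non-Gaussian
sources are modeled.

The benchmark forward model is deliberately minimal: a 1-D current-source-
density segment under an 11-electrode array in an infinite homogeneous
isotropic conductor (conductivity 1), with the free-space monopole kernel
`V(x, y) = 1/(4π√(h² + (x−y)²))`. Nominal geometry: segment 4 mm with
0.2 mm source spacing (p = 21), array 4 mm with 0.4 mm pitch (n = 11),
height h = 0.5 mm. The kernel is analytic, so `L` is severely smoothing:
its singular values fall from 1 to ≈0.01 over r = 11 (after unit-spectral-
norm normalization, see below).

## Estimators

Three pipelines estimate `S_x` from the sensor sample spectral matrix
`Ŝ_y = Y Y†/(N−1)`, in the column-major vectorized space where
`Vec(A S Aᵀ) = (A⊗A)Vec(S)`:

* **E1 (source-based, source-space correction)** —
  `Vec(Ŝ₁⁽ᵏ⁾) = π₁⁽ᵏ⁾ (L♯ ⊗ L♯) Vec(Ŝ_y)` with the minimum-norm inverse
  `L♯ = Lᵀ(LLᵀ + λI)⁻¹`.
* **E2 (sensor-based, source-space correction)** —
  `Vec(Ŝ₂⁽ᵏ⁾) = π₂⁽ᵏ⁾ (L⊗L)♯ Vec(Ŝ_y)` with the matrix-space Tikhonov
  inverse at level λ².
* **E3 (sensor-based, sensor-space correction)** — the projector acts on
  `Vec(Ŝ_y)` before inversion and is folded into the inverse:
  `F₃⁽ᵏ⁾ = (L⊗L)ᵀ π₃⁽ᵏ⁾ [π₃⁽ᵏ⁾(L⊗L)(L⊗L)ᵀπ₃⁽ᵏ⁾ + λ²I]⁻¹ π₃⁽ᵏ⁾`, and
  `F₃⁽⁰⁾ = (L⊗L)♯` exactly.

The projector `π⁽ᵏ⁾ = I − U⁽ᵏ⁾(U⁽ᵏ⁾)ᵀ` removes the top-k left singular
directions of the leakage basis `B` — the p diagonal-index columns
(positions `1 + (i−1)(p+1)`) of the family's resolution operator (E1/E2) or
of `L⊗L` (E3). These columns are exactly `r_i ⊗ r_i` (squared point-spread
functions), all symmetric, so the removed subspace contains no
anti-symmetric component: the imaginary (lagged) part of any interaction
passes through every correction unchanged. This invariance is exact in
exact arithmetic and is held to ~1e−13 numerically (see below).

Both operator families diagonalize in the singular basis of `L`:
`R = Σ f_kl (v_k v_kᵀ)⊗(v_l v_lᵀ)` with
`f⁽¹⁾_kl = δ_k²δ_l²/((δ_k²+λ)(δ_l²+λ))` and
`f⁽²⁾_kl = δ_k²δ_l²/(δ_k²δ_l²+λ²)`; matching λ₂ = λ₁² makes the families
comparable, with the source-based coefficients never larger.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| λ (`log10_lambda`) | Tikhonov level, signal-space scale, dimensionless after normalization | −2 | the detection-power operating point; sweeps cover −8…1 |
| k (`rank`) | projection rank, 0…d | `"max"` | complete leakage suppression; k = 0 recovers the uncorrected estimator |
| γ | source coherence ∈ [0,1] | 0.3 | nominal benchmark interaction strength |
| φ | interaction lag | 0–90° | the quantity the statistics must be invariant to |
| σ | noise level in units of √ν | 0.01 (power study), 0–0.1 (sweeps) | nominal benchmark range |
| N | samples per spectral estimate | 100 | nominal benchmark value |
| n_reps | Monte-Carlo replicates | 1000 (library), 500 (acceptance studies) | the smaller value keeps full sweeps at seconds per lag with indistinguishable power estimates |
| α | significance level | 0.05 complex, 0.025 real/imag | splits the level over the two one-part tests |

## Numerical choices

* **Normalization.** `L` is scaled by 1/δ₁ by default so that δ₁ = 1 and
  λ is dimensionless; σ² is always expressed in units of the top eigenvalue
  of `LLᵀ` of the matrix actually used, so results are normalization-
  independent. Structural tests run both ways.
* **Inverses through singular systems.** `L♯`, `(L⊗L)♯`, and `F₃⁽ᵏ⁾` are
  built from SVDs (the Kronecker singular system `δ_kδ_l`, `u_k⊗u_l`,
  `v_k⊗v_l` for matrix space), never from explicit normal-equation
  inverses. For `F₃⁽ᵏ⁾` the projector is written as `π = WWᵀ` with `W` the
  exact orthonormal complement of the removed subspace and the SVD of
  `WᵀK` is filtered directly; the naive `inv(πKKᵀπ + λ²I)` loses ~6 digits
  of the lagged-part invariance at small λ through its artificial λ-level
  eigenvalues.
* **Numerical rank.** The leakage dimension d counts singular values of `B`
  above `max(s)·1e−10`; the benchmark yields d = 21 for every family at the
  operating λ.
* **Vectorization.** Column-major throughout; the diagonal-index positions
  are `i(p+1)` (0-based).
* **Hermitian symmetrization.** Estimates are averaged with their conjugate
  transpose defensively; for real `L` the adjustment is at rounding level
  (asserted < 1e−10 in tests) because real operators acting on Hermitian
  vectorizations preserve Hermitianity.
* **Sample spectral matrices.** Divisor N−1 per convention. For the
  known-zero-mean processes simulated here the exact expectation is
  `N/(N−1)·S`; Monte-Carlo recovery tests compare against that expectation.
* **PSD handling.** Spectral models are validated against an eigenvalue
  floor of −1e−10; matrix square roots clip negative eigenvalues at 0.
* **Confidence regions.** Real/imag statistics use percentile intervals at
  100·α/2 and 100·(1−α/2); the complex statistic uses the Gaussian ellipse
  from the replicate mean and (Re, Im) covariance at the χ²₂(1−α) radius,
  ridged by 1e−12·trace when near-singular. The distance from the origin to
  the ellipse is minimized on a 720-point boundary grid refined by bounded
  scalar minimization to 1e−6.
* **Detection power.** `(M+1)/(p(p−1)/2)` with strict-inequality counting
  of M, and 0 outright when the true pair itself is not significant —
  an interaction inside its own confidence region is undetected no matter
  its rank.
* **Bias.** Off-true mean amplitude over ordered pairs (diagonal excluded)
  against the amplitude on the relaxed 3×3 true neighborhood; the maximum
  over the neighborhood is the default (translation-robust), the mean is
  available. λ is grid-searched (−8…0 in 0.5 steps) per estimator.
* **Suppression angle.** `α = arcsin(√Q)` so that suppression 1−Q = cos²α
  decreases monotonically in α.
* **Seeding.** All studies derive per-cell generators from one root
  `SeedSequence` with positional spawn keys, so results are independent of
  execution order and reproducible bit-for-bit.

## Design decisions where the design was open

* **Traveling-wave coherence.** The K-source wave uses amplitudes √γ with
  unit diagonal so that the pairwise coherence among members is exactly γ
  (a literal amplitude of γ would give coherence γ², inconsistent with
  sweeping γ as "the shared coherence" to 1).
* **λ scale correspondence.** One user-facing λ on the signal-space scale;
  matrix-space operators use λ² internally (the filter-coefficient
  correspondence). A raw-λ override exists for sweeps on either scale.
* **Two-point geometry.** The closed-form leakage/interaction norms and
  the leakage ≥ interaction inequality are stated for Kronecker-square
  (source-based) resolution structure, where they are exact; the
  sensor-based family's coefficients are not separable and its diagonal
  basis columns are not exact tensor squares.
* **Extended sources.** The leakage-to-interaction ratio of a homogeneous
  m-point patch is reported by the compact approximation `σ²/((m−1)γ²)`;
  against the exact two-term construction with a shared point spread it is
  accurate to ~10–20% for coherences near 1 and degrades for small γ.

## What the synthetic benchmark shows — and does not

The generator emulates exactly the conditions the estimators are designed
for: a known, noiseless-geometry forward model; Gaussian, stationary,
single-frequency activity; white uncorrelated sensor noise; at most a few
point sources or one evenly-spaced network. Passing tests therefore
establish the *algebraic* claims (leakage confinement, lagged-part
invariance, estimator equivalences, suppression behavior) and the
*statistical* claims under the model (lag-invariant power 1 of the
corrected complex statistic at p = 21, n = 11, N = 100, σ = 0.01).

They do not establish performance under forward-model misspecification
(wrong sensor positions, conduction, or source orientations), correlated or
non-Gaussian noise, dense source configurations, or realistic 3-D head
geometries; nor do they address data-driven selection of λ or of the
projection rank k, both of which are left to the user (the
`suppression-curves` study is the built-in diagnostic for the λ trade-off:
stronger regularization suppresses leakage *and* progressively eats the
real part of true interactions, with lag-90° interactions the only ones
never harmed). Dense materialization of the p²×p² operators caps the
practical problem size (a guard refuses p > 200); large-p iterative
implementations are out of scope.
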