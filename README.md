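# leakfree

Lag-invariant, leakage-corrected estimation of source-space interaction
(cross-spectral) matrices for linearly-mixed, spatially-extended systems.

## The problem

Many measurement setups observe a linear mixture of hidden sources:
electric potentials over a sheet of neural tissue (LFP/ECoG/EEG), magnetic
flux outside the head (MEG), or any sensor array governed by

```
y(t, ω) = L x(t, ω) + e(t, ω),
```

with `x` the p source amplitudes at one frequency ω, `y` the n sensor
samples (n < p), `L` the forward matrix, and `e` white sensor noise with
spectral matrix `S_e = σ² I`. Interactions between sources k and l are the
off-diagonal entries `γ_kl` of the source spectral matrix
`S_x = ⟨x x†⟩`: |γ_kl| is the coupling strength, arg γ_kl the lag.

Reconstructing `S_x` through a regularized inverse — the minimum-norm
operator `L♯ = Lᵀ(LLᵀ + λI)⁻¹`, or its matrix-space analogue
`(L⊗L)♯` — suffers from *signal leakage*: incomplete unmixing makes source
*power* masquerade as connectivity, so pair-wise tests light up around every
active source whether or not it interacts with anything. The common
workaround — keeping only the imaginary part of `γ̂_kl` — is immune to
leakage but blind to interactions with small lags.

## The method

In the vectorized space of spectral matrices, the expectation of any of the
linear estimators splits into three terms (column-major `Vec`):

```
Vec(⟨Ŝ⟩) = R Vec(S_x⁺)  +  R Vec(S_x⁻)  +  F Vec(S_e)
            (leakage)      (interaction)    (projected noise)
```

where `S_x⁺`/`S_x⁻` are the diagonal/off-diagonal parts of `S_x`, and
`R`, `F` are the resolution and inverse operators of the chosen family
(source-based: `R₁ = (L♯L)⊗(L♯L)`, `F₁ = L♯⊗L♯`; sensor-based:
`F₂ = (L⊗L)♯`, `R₂ = F₂(L⊗L)`). The leakage term is confined to the span of
the p diagonal-index columns of `R` (or of `L⊗L` in sensor space) — the
*leakage subspace*. Projecting off its top-k left singular directions,
`π⁽ᵏ⁾ = I − U⁽ᵏ⁾(U⁽ᵏ⁾)ᵀ`, removes leakage while **provably leaving the
anti-symmetric (imaginary, lagged) part of every interaction untouched**.
Three corrected estimators are provided:

| family | estimate | correction applied in |
|--------|-----------------------------|--------------|
| `E1`   | source-based `L♯ Ŝ_y (L♯)ᵀ` | source space |
| `E2`   | sensor-based `(L⊗L)♯ Vec(Ŝ_y)` | source space |
| `E3`   | sensor-based | sensor space (folded into the inversion) |

With the correction at full rank, the complex statistic `γ̂_kl` becomes a
*lag-invariant* detector: its Monte-Carlo detection power on the benchmark
is 1 at every lag from 0° to 90°, where the raw real/imaginary statistics
each fail on half the range.

The package ships a self-contained benchmark: a 4 mm current-source-density
segment (21 grid points, 0.2 mm spacing) observed by 11 electrodes
(0.4 mm pitch) at height 0.5 mm in an infinite homogeneous conductor, with
monopole potentials `V(x,y) = 1/(4π √(h² + (x−y)²))`, two unit-power sources
at ±1 mm with coherence γ and lag φ, and circularly-symmetric complex
Gaussian sampling.

## Worked example

```python
import numpy as np
from leakfree import (default_benchmark, InteractionSpec, two_source_spectrum,
                      sample_activity, SourceInteractionModel)

fm = default_benchmark()                      # 11 electrodes x 21 sources
spec = InteractionSpec.two_source(fm, gamma=0.3, phi_deg=60.0)
spectral = two_source_spectrum(fm, spec, sigma=0.01)
samples = sample_activity(spectral, fm, N=200, seed=42)

results = SourceInteractionModel(samples, fm, family="E1",
                                 log10_lambda=-2.0, rank="max").fit()
print(results.summary(n_pairs=3))

tp = (fm.source_index(-1.0), fm.source_index(1.0))
power = results.detection_power(spectral, tp, kind="complex",
                                N=100, n_reps=500, seed=1)
print(f"detection power (complex statistic): {power}")
```

prints

```
Leakage-corrected source-space spectral estimate
================================================
estimator family:      E1
log10(lambda):         -2
projection rank k:     21 (leakage dimension d = 21)
grid / sensors:        p = 21, n = 11
Hermitian defect:      5.58e-17

strongest 3 interactions (|value|, lag):
  (-1.0 mm, +1.0 mm)  |g| = 0.0111  lag =   72.80 deg
  (-1.0 mm, +1.2 mm)  |g| = 0.0102  lag =   72.98 deg
  (-1.2 mm, +1.0 mm)  |g| = 0.0101  lag =   72.98 deg

detection power (complex statistic): 1.0
```

The strongest reconstructed interaction sits exactly at the simulated pair
(−1 mm, +1 mm); its magnitude is attenuated by the inverse operator's
filtering (the estimate is biased but localized), and the recovered lag is
within a few degrees of the inverse-filtered truth. The complex statistic
ranks the true pair above all 210 candidate pairs at every lag — detection
power 1.

A command-line interface mirrors the library
(`leakfree simulate | operators | estimate | suppression-curves |
bias-curves | power-curves | network-demo | sensitivity-map`); every
subcommand emits delimited text plus a JSON manifest that replays the run
bit-for-bit.

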