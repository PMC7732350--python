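"""Source spectral models and the complex Gaussian sampler.

Everything lives at a single (implicit) frequency: a source configuration is
a Hermitian positive semi-definite spectral matrix ``S_x`` (p x p), sensor
noise is white with spectral matrix ``S_e = sigma^2 * noise_unit * I`` where
``noise_unit`` is the largest eigenvalue of ``L L^T``, and time-frequency
samples are i.i.d. circularly-symmetric complex Gaussian vectors with those
covariances. The sample spectral matrix ``Z Z^dagger / (N - 1)`` is the
unbiased workhorse estimator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientSamplesError, PSDViolationError
from .forward import ForwardModel

__all__ = [
    "InteractionSpec",
    "NetworkSpec",
    "SpectralModel",
    "SampleSet",
    "two_source_spectrum",
    "traveling_wave_spectrum",
    "sample_activity",
    "sample_spectral_matrix",
]

#: Eigenvalue floor below which a spectral matrix is rejected as non-PSD.
PSD_FLOOR = -1e-10


@dataclass(frozen=True)
class InteractionSpec:
    """Pairwise interactions between point sources.

    ``active_pairs`` lists ``(k, l, gamma, phi_deg)`` with grid indices
    ``k < l``, coherence ``0 <= gamma <= 1`` and lag ``phi`` in degrees.
    ``source_powers`` maps grid index -> variance sigma_i^2 (default 1 for
    every index that appears in a pair).
    """

    active_pairs: tuple = ()
    source_powers: dict = field(default_factory=dict)

    @classmethod
    def two_source(cls, model: ForwardModel, gamma: float, phi_deg: float,
                   positions_mm=(-1.0, 1.0), powers=(1.0, 1.0)) -> "InteractionSpec":
        k, l = (model.source_index(x) for x in positions_mm)
        return cls(
            active_pairs=((k, l, gamma, phi_deg),),
            source_powers={k: powers[0], l: powers[1]},
        )

    def active_indices(self) -> list:
        idx = set(self.source_powers)
        for k, l, *_ in self.active_pairs:
            idx.update((k, l))
        return sorted(idx)


@dataclass(frozen=True)
class NetworkSpec:
    """Traveling-wave network of K coherent sources.

    Phases ``phi_n = 2 pi (n - 1) / K`` advance left to right, modeling a wave
    whose wavelength is the distance between the first and last source. Unit
    diagonal; every off-diagonal coherence among members equals ``gamma``.
    """

    K: int
    gamma: float
    locations: tuple | None = None  # grid indices, evenly spaced, left->right

    def resolve_locations(self, model: ForwardModel) -> np.ndarray:
        if self.K < 2:
            raise PSDViolationError(f"network needs K >= 2 sources (got {self.K})")
        if self.locations is not None:
            loc = np.asarray(self.locations, dtype=int)
        else:
            p = model.p
            gap = (p - 1) // (self.K - 1)
            if gap < 1:
                raise PSDViolationError(f"K = {self.K} sources do not fit a {p}-point grid")
            start = (p - 1 - gap * (self.K - 1)) // 2
            loc = start + gap * np.arange(self.K)
        if loc.size != self.K or np.any(np.diff(loc) <= 0):
            raise PSDViolationError("network locations must be K strictly increasing indices")
        if np.unique(np.diff(loc)).size != 1:
            raise PSDViolationError("network locations must be evenly spaced")
        if loc[0] < 0 or loc[-1] >= model.p:
            raise PSDViolationError("network locations fall outside the source grid")
        return loc

    @property
    def phases(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.K) / self.K


@dataclass(frozen=True)
class SpectralModel:
    """Source spectral matrix S_x plus white sensor noise at level sigma.

    ``sigma`` is expressed in units of ``sqrt(noise_unit)`` of the forward
    model, i.e. ``S_e = sigma^2 * noise_unit * I_n``.
    """

    S_x: np.ndarray
    sigma: float
    noise_unit: float
    n_sensors: int

    def __post_init__(self):
        S = np.asarray(self.S_x)
        if not np.allclose(S, S.conj().T, atol=1e-12):
            raise PSDViolationError("S_x is not Hermitian")
        w = np.linalg.eigvalsh(S)
        if w.min(initial=0.0) < PSD_FLOOR * max(1.0, w.max(initial=0.0)):
            raise PSDViolationError(f"S_x has negative eigenvalue {w.min():.3e}")

    @property
    def S_e(self) -> np.ndarray:
        return self.sigma ** 2 * self.noise_unit * np.eye(self.n_sensors)

    @property
    def p(self) -> int:
        return self.S_x.shape[0]


def _spectral_model(model: ForwardModel, S_x: np.ndarray, sigma: float) -> SpectralModel:
    return SpectralModel(S_x=S_x, sigma=float(sigma), noise_unit=model.noise_unit,
                         n_sensors=model.n)


def two_source_spectrum(
    model: ForwardModel, spec: InteractionSpec, sigma: float = 0.0
) -> SpectralModel:
    """S_x for point sources with prescribed pairwise coherences.

    For the canonical two-source case the active 2 x 2 block is

        [[s_k^2,                g s_k s_l e^{+i phi}],
         [g s_k s_l e^{-i phi}, s_l^2              ]].
    """
    S = np.zeros((model.p, model.p), dtype=complex)
    for i in spec.active_indices():
        S[i, i] = spec.source_powers.get(i, 1.0)
    for k, l, gamma, phi_deg in spec.active_pairs:
        if not 0.0 <= gamma <= 1.0:
            raise PSDViolationError(f"coherence must be in [0, 1] (got {gamma})")
        amp = gamma * np.sqrt(S[k, k].real * S[l, l].real)
        phase = np.exp(1j * np.deg2rad(phi_deg))
        S[k, l] = amp * phase
        S[l, k] = amp * np.conj(phase)
    return _spectral_model(model, S, sigma)


def traveling_wave_spectrum(
    model: ForwardModel, spec: NetworkSpec, sigma: float = 0.0
) -> SpectralModel:
    """Traveling-wave S_x: unit diagonal, coherence gamma among members.

    Built from the rank-1 structure ``v v^dagger`` with amplitudes
    ``sqrt(gamma) e^{i phi_n}`` plus ``(1 - gamma)`` residual power on the
    diagonal, so off-diagonal entries among members are exactly
    ``gamma e^{i(phi_n - phi_m)}``.
    """
    if not 0.0 <= spec.gamma <= 1.0:
        raise PSDViolationError(f"coherence must be in [0, 1] (got {spec.gamma})")
    loc = spec.resolve_locations(model)
    v = np.sqrt(spec.gamma) * np.exp(1j * spec.phases)
    block = np.outer(v, v.conj())
    np.fill_diagonal(block, 1.0)
    S = np.zeros((model.p, model.p), dtype=complex)
    S[np.ix_(loc, loc)] = block
    return _spectral_model(model, S, sigma)


def _psd_sqrt(S: np.ndarray) -> np.ndarray:
    w, Q = np.linalg.eigh(np.asarray(S, dtype=complex))
    scale = max(1.0, w.max(initial=0.0))
    if w.min(initial=0.0) < PSD_FLOOR * scale:
        raise PSDViolationError(f"matrix has negative eigenvalue {w.min():.3e}")
    return (Q * np.sqrt(np.clip(w, 0.0, None))) @ Q.conj().T


@dataclass(frozen=True)
class SampleSet:
    """One draw of N time-frequency samples: Y = L X + E exactly."""

    X: np.ndarray
    E: np.ndarray
    Y: np.ndarray
    N: int
    seed: object


def _circular_gaussian(rng: np.random.Generator, shape) -> np.ndarray:
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)


def sample_activity(
    spectral: SpectralModel, model: ForwardModel, N: int, seed
) -> SampleSet:
    """Draw N i.i.d. circular complex Gaussian samples of sources and noise.

    ``X = S_x^{1/2} Z`` with ``Z`` standard circular complex Gaussian, so
    ``<X X^dagger> = S_x``; the same for the noise. Identical seeds reproduce
    identical samples bit-for-bit.
    """
    if N < 2:
        raise InsufficientSamplesError(f"need N >= 2 samples (got {N})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = _psd_sqrt(spectral.S_x)
    X = A @ _circular_gaussian(rng, (model.p, N))
    E = spectral.sigma * np.sqrt(spectral.noise_unit) * _circular_gaussian(rng, (model.n, N))
    Y = model.L @ X + E
    return SampleSet(X=X, E=E, Y=Y, N=N, seed=seed)


def sample_spectral_matrix(Z: np.ndarray) -> np.ndarray:
    """Sample spectral matrix ``Z Z^dagger / (N - 1)``, exactly Hermitian."""
    Z = np.asarray(Z)
    N = Z.shape[1]
    if N < 2:
        raise InsufficientSamplesError(f"need at least 2 samples (got {N})")
    S = Z @ Z.conj().T / (N - 1)
    return (S + S.conj().T) / 2.0
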