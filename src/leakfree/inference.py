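"""Monte-Carlo test statistics, confidence regions, sensitivity, and power.

For every ordered source pair (k, l) the test statistic is the (k, l) entry
of a (corrected) source-space spectral estimate, used against the null
H0: gamma_kl = 0. Its sampling distribution is approximated by simulating
replicates of the sensor data under the generative model. The *sensitivity*
of a statistic is the Euclidean distance from 0 to its 100(1-alpha)%
confidence region — a percentile interval for the real/imaginary statistics,
a Gaussian-approximation ellipse in the complex plane for the complex
statistic — and is 0 when the null value lies inside the region.

Detection power ranks the true pair among all p(p-1)/2 ordered pairs:
(M + 1) / (p(p-1)/2) with M the number of pairs of strictly lower
sensitivity, and 0 outright when the true pair itself is not significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import ConfigurationError, UnstableRegionError
from .forward import ForwardModel
from .leakage import EstimatorSpec
from .spectra import SpectralModel, _circular_gaussian, _psd_sqrt

__all__ = [
    "TestStatisticReplicates",
    "ConfidenceRegion",
    "SensitivityResult",
    "replicate_statistics",
    "confidence_region",
    "sensitivity",
    "sensitivity_matrix",
    "detection_power",
]

#: Per-kind significance-level convention: the complex statistic is one test,
#: its real/imaginary parts are two, so alpha is split.
DEFAULT_ALPHA = {"complex": 0.05, "real": 0.025, "imag": 0.025}

MIN_REPLICATES = 20


@dataclass(frozen=True)
class TestStatisticReplicates:
    """Replicated corrected spectral estimates (n_reps x p x p complex)."""

    estimates: np.ndarray
    N: int
    seed: object
    family: str
    k: int

    @property
    def n_reps(self) -> int:
        return self.estimates.shape[0]

    def pair(self, i: int, j: int) -> np.ndarray:
        """Complex replicate values of the statistic at pair (i, j)."""
        return self.estimates[:, i, j]


def replicate_statistics(
    spectral: SpectralModel,
    model: ForwardModel,
    spec: EstimatorSpec,
    N: int,
    n_reps: int,
    seed,
    chunk: int = 256,
) -> TestStatisticReplicates:
    """Simulate n_reps independent corrected spectral estimates.

    Each replicate draws N circular complex Gaussian samples of sources and
    sensor noise, forms the sensor sample spectral matrix, and applies the
    corrected inverse operator. Replicates are generated in fixed-size chunks
    so results are reproducible bit-for-bit for a given seed regardless of
    platform vectorization.
    """
    if N < 2 or n_reps < 2:
        raise ConfigurationError("need N >= 2 samples and n_reps >= 2 replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p, n = model.p, model.n
    A = _psd_sqrt(spectral.S_x)
    noise_scale = spectral.sigma * np.sqrt(spectral.noise_unit)
    F = spec.F  # p^2 x n^2, real
    out = np.empty((n_reps, p, p), dtype=complex)
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        Z = _circular_gaussian(rng, (m, p, N))
        E = noise_scale * _circular_gaussian(rng, (m, n, N))
        Y = model.L @ (A @ Z) + E
        S_y = Y @ Y.conj().transpose(0, 2, 1) / (N - 1)
        vecs = S_y.transpose(0, 2, 1).reshape(m, n * n)  # row-wise column-major Vec
        est = vecs @ F.T
        est = est.reshape(m, p, p).transpose(0, 2, 1)  # un-Vec (column-major)
        out[done:done + m] = (est + est.conj().transpose(0, 2, 1)) / 2.0
        done += m
    return TestStatisticReplicates(estimates=out, N=N, seed=seed,
                                   family=spec.family, k=spec.k)


@dataclass(frozen=True)
class ConfidenceRegion:
    kind: str
    alpha: float
    lo: float | None = None
    hi: float | None = None
    center: np.ndarray | None = None
    shape: np.ndarray | None = None  # 2x2 covariance of (Re, Im)
    radius_sq: float | None = None  # chi^2_2 quantile


def confidence_region(values: np.ndarray, kind: str, alpha: float) -> ConfidenceRegion:
    """Confidence region of one pair's statistic from its replicates.

    real/imag: percentile interval [100*alpha/2, 100*(1 - alpha/2)].
    complex: ellipse from the sample mean and covariance of (Re, Im) at the
    chi^2_2(1 - alpha) radius; a near-singular covariance is ridged by
    1e-12 * trace on the diagonal.
    """
    if not 0.0 < alpha < 0.5:
        raise ConfigurationError(f"alpha must be in (0, 0.5) (got {alpha})")
    values = np.asarray(values)
    if values.size < MIN_REPLICATES:
        raise UnstableRegionError(
            f"need at least {MIN_REPLICATES} replicates (got {values.size})"
        )
    if kind in ("real", "imag"):
        x = values.real if kind == "real" else values.imag
        lo, hi = np.percentile(x, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return ConfidenceRegion(kind=kind, alpha=alpha, lo=float(lo), hi=float(hi))
    if kind != "complex":
        raise ConfigurationError(f"kind must be real, imag or complex (got {kind!r})")
    pts = np.column_stack([values.real, values.imag])
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    tr = np.trace(cov)
    w = np.linalg.eigvalsh(cov)
    if tr == 0 or w[0] < 1e-12 * tr:
        cov = cov + 1e-12 * max(tr, np.finfo(float).tiny) * np.eye(2)
    return ConfidenceRegion(
        kind="complex", alpha=alpha, center=center, shape=cov,
        radius_sq=float(stats.chi2.ppf(1 - alpha, df=2)),
    )


def _ellipse_distance(region: ConfidenceRegion, tol: float = 1e-6) -> float:
    """Euclidean distance from the origin to the confidence ellipse (0 if the
    origin lies inside), found numerically on the boundary parametrization."""
    m, cov, q = region.center, region.shape, region.radius_sq
    covinv = np.linalg.inv(cov)
    if m @ covinv @ m <= q:
        return 0.0
    C = np.linalg.cholesky(cov) * np.sqrt(q)

    def dist(theta):
        z = m + C @ np.array([np.cos(theta), np.sin(theta)])
        return np.hypot(*z)

    thetas = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    bz = m[:, None] + C @ np.vstack([np.cos(thetas), np.sin(thetas)])
    i0 = int(np.argmin(np.hypot(bz[0], bz[1])))
    span = 2 * np.pi / 720
    res = optimize.minimize_scalar(
        dist, bounds=(thetas[i0] - span, thetas[i0] + span), method="bounded",
        options={"xatol": tol * 1e-3},
    )
    return float(min(res.fun, np.hypot(bz[0], bz[1]).min()))


def sensitivity(values: np.ndarray, kind: str, alpha: float) -> float:
    """Distance from the null value 0 to the confidence region (0 if inside)."""
    region = confidence_region(values, kind, alpha)
    if kind in ("real", "imag"):
        if region.lo <= 0.0 <= region.hi:
            return 0.0
        return float(min(abs(region.lo), abs(region.hi)))
    return _ellipse_distance(region)


@dataclass(frozen=True)
class SensitivityResult:
    """Per-pair sensitivity matrix with the true pair and, later, power."""

    matrix: np.ndarray
    kind: str
    alpha: float
    true_pair: tuple | None
    n_reps: int
    N: int

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


def sensitivity_matrix(
    spectral: SpectralModel,
    model: ForwardModel,
    spec: EstimatorSpec,
    kind: str,
    N: int,
    n_reps: int,
    seed,
    alpha: float | None = None,
    true_pair=None,
    replicates: TestStatisticReplicates | None = None,
) -> SensitivityResult:
    """Sensitivity of one statistic kind at every ordered pair k < l.

    ``replicates`` may be supplied to reuse one simulation across the three
    statistic kinds (they share the same complex replicate values).
    """
    if alpha is None:
        alpha = DEFAULT_ALPHA[kind]
    if replicates is None:
        replicates = replicate_statistics(spectral, model, spec, N, n_reps, seed)
    p = model.p
    S = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            S[i, j] = S[j, i] = sensitivity(replicates.pair(i, j), kind, alpha)
    return SensitivityResult(matrix=S, kind=kind, alpha=alpha,
                             true_pair=tuple(true_pair) if true_pair is not None else None,
                             n_reps=replicates.n_reps, N=replicates.N)


def detection_power(result: SensitivityResult, true_pair=None) -> float:
    """Rank-based detection power of the true pair.

    0 when the true pair's sensitivity is 0 (H0 inside its own confidence
    region); otherwise (M + 1) / (p(p-1)/2) with M the number of ordered
    pairs of strictly lower sensitivity (ties not counted).
    """
    pair = true_pair if true_pair is not None else result.true_pair
    if pair is None:
        raise ConfigurationError("true pair not set")
    k0, l0 = pair
    s_true = result.matrix[k0, l0]
    if s_true == 0.0:
        return 0.0
    p = result.p
    iu, ju = np.triu_indices(p, k=1)
    s_all = result.matrix[iu, ju]
    M = int(np.sum(s_all < s_true))
    return float((M + 1) / (p * (p - 1) / 2))
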