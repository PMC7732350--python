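"""Leakage subspaces, rank-k correction projections, and corrected estimators.

The expected value of any vectorized source-space spectral estimate splits
into three terms (column-major Vec throughout):

    Vec(<S_hat>) = R Vec(S_x+) + R Vec(S_x-) + F Vec(S_e)

where ``S_x+``/``S_x-`` are the diagonal/off-diagonal parts of the source
spectral matrix. The first term — the *leakage term* — depends on source
powers only and is confined to the span of the diagonal-index columns of the
resolution operator (the *leakage subspace*). Projecting off the top-k left
singular directions of that column set suppresses leakage while leaving the
anti-symmetric (imaginary, lagged) part of the interactions untouched.

Three corrected estimator pipelines are provided:

* ``E1`` — source-based estimate, correction in source-space,
* ``E2`` — sensor-based estimate, correction in source-space,
* ``E3`` — sensor-based estimate, correction in sensor-space (the projector
  is built from the diagonal-index columns of ``L (x) L`` and folded into the
  Tikhonov inversion itself).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError, PSDViolationError
from .forward import ForwardModel
from .operators import (
    RegularizationSetting,
    as_regularization,
    diag_vec_indices,
    minimum_norm_inverse,
    unvec,
    vec,
    vectorized_operators,
)
from .spectra import SampleSet, SpectralModel, sample_spectral_matrix

__all__ = [
    "LeakageProjector",
    "EstimatorSpec",
    "ExpectationDecomposition",
    "leakage_basis",
    "set_rank",
    "build_estimator",
    "estimate_interactions",
    "decompose_expectation",
    "two_point_source_norms",
    "extended_source_ratio",
]

#: Relative singular-value cutoff defining the numerical dimension of the
#: leakage subspace.
RANK_RTOL = 1e-10

_FAMILY_SPACE = {1: "source", 2: "source", 3: "sensor"}


@dataclass(frozen=True)
class LeakageProjector:
    """Leakage-subspace basis B with its SVD and a rank-k projection.

    For families 1-2, B holds the diagonal-index columns of the resolution
    operator R_j (p^2 x p); for family 3 it holds the diagonal-index columns
    of L (x) L (n^2 x p). ``d`` is the numerical rank of B;
    ``pi_k = I - U_k U_k^T`` projects off the leading k left singular
    directions (k = 0 gives the identity, k = d nullifies the subspace).
    """

    family: int
    B: np.ndarray
    U: np.ndarray  # full orthonormal basis; first d columns span the subspace
    svals: np.ndarray
    d: int
    k: int | None = None
    pi_k: np.ndarray | None = None

    @property
    def space(self) -> str:
        return _FAMILY_SPACE[self.family]

    def complement(self) -> np.ndarray:
        """Orthonormal basis of the orthogonal complement of the removed
        rank-k subspace (columns k..dim of the full left singular basis)."""
        if self.k is None:
            raise ConfigurationError("projection rank not set")
        return self.U[:, self.k:]


def leakage_basis(model: ForwardModel, reg, family: int) -> LeakageProjector:
    """Build the leakage-subspace basis for one estimator family (rank unset).

    Families 1 and 2 depend on the regularization level through R_j; family 3
    uses ``L (x) L`` and is lambda-independent.
    """
    reg = as_regularization(reg)
    idx = diag_vec_indices(model.p)
    if family == 1:
        B = vectorized_operators(model, reg, "source_based").R[:, idx]
    elif family == 2:
        B = vectorized_operators(model, reg, "sensor_based").R[:, idx]
    elif family == 3:
        B = np.kron(model.L, model.L)[:, idx]
    else:
        raise ConfigurationError(f"family must be 1, 2 or 3 (got {family})")
    U, s, _ = np.linalg.svd(B, full_matrices=True)
    d = int(np.sum(s > s[0] * RANK_RTOL)) if s.size else 0
    return LeakageProjector(family=family, B=B, U=U, svals=s, d=d)


def set_rank(projector: LeakageProjector, k) -> LeakageProjector:
    """Materialize ``pi_k = I - U_k U_k^T`` for 0 <= k <= d ('max' = d)."""
    if k == "max":
        k = projector.d
    k = int(k)
    if not 0 <= k <= projector.d:
        raise ConfigurationError(
            f"projection rank k = {k} outside [0, d = {projector.d}]"
        )
    dim = projector.B.shape[0]
    Uk = projector.U[:, :k]
    pi = np.eye(dim) - Uk @ Uk.T
    return replace(projector, k=k, pi_k=pi)


@dataclass(frozen=True)
class EstimatorSpec:
    """A fully materialized corrected estimator.

    ``F`` and ``R`` are the corrected inverse/resolution operators
    (``F0``/``R0`` are the uncorrected, k = 0 versions of the same family);
    both act on column-major vectorizations. ``reg`` carries the signal-space
    lambda; sensor-based/matrix-space operators internally use its square.
    """

    family: str  # "E1" | "E2" | "E3"
    reg: RegularizationSetting
    k: int
    projector: LeakageProjector
    F: np.ndarray
    R: np.ndarray
    F0: np.ndarray
    R0: np.ndarray

    @property
    def rank(self) -> int:
        return self.k


_FAMILY_NUM = {"E1": 1, "E2": 2, "E3": 3}


def build_estimator(model: ForwardModel, family: str, reg, k) -> EstimatorSpec:
    """Materialize one of the three corrected estimators at rank k.

    E1: F^(k) = pi_k (L# (x) L#),      R^(k) = pi_k ((L# L) (x) (L# L))
    E2: F^(k) = pi_k (L (x) L)#,       R^(k) = pi_k F2 (L (x) L)
    E3: F^(k) = K^T pi_k [pi_k K K^T pi_k + lam^2 I]^{-1} pi_k,  R^(k) = F^(k) K
        with K = L (x) L and the sensor-space projector pi_k.
    """
    reg = as_regularization(reg)
    if family not in _FAMILY_NUM:
        raise ConfigurationError(f"family must be one of E1, E2, E3 (got {family!r})")
    fam = _FAMILY_NUM[family]
    proj = set_rank(leakage_basis(model, reg, fam), k)
    if family in ("E1", "E2"):
        kind = "source_based" if family == "E1" else "sensor_based"
        pair = vectorized_operators(model, reg, kind)
        F = proj.pi_k @ pair.F
        R = proj.pi_k @ pair.R
        return EstimatorSpec(family=family, reg=reg, k=proj.k, projector=proj,
                             F=F, R=R, F0=pair.F, R0=pair.R)
    # E3: fold the sensor-space projector into the matrix-space inversion,
    #   F^(k) = K^T pi [pi K K^T pi + lam^2 I]^{-1} pi.
    # Writing pi = W W^T with W the exact orthonormal complement of the
    # removed subspace, this equals W-restricted Tikhonov inversion of
    # K_pi = W^T K, computed through the SVD of K_pi (no normal equations),
    # which keeps the lagged-part invariance exact to rounding even for
    # severely under-regularized settings.
    K = np.kron(model.L, model.L)
    lam2 = reg.matrix_lam
    W = proj.complement()
    P, s, Qt = np.linalg.svd(W.T @ K, full_matrices=False)
    keep = s > (s[0] * max(K.shape) * np.finfo(float).eps if s.size else 0)
    P, s, Qt = P[:, keep], s[keep], Qt[keep]
    gains = s / (s ** 2 + lam2)
    F = (Qt.T * gains) @ P.T @ W.T
    R = F @ K
    pair0 = vectorized_operators(model, reg, "sensor_based")
    return EstimatorSpec(family=family, reg=reg, k=proj.k, projector=proj,
                         F=F, R=R, F0=pair0.F, R0=pair0.R)


def estimate_interactions(data, spec: EstimatorSpec, model: ForwardModel,
                          return_defect: bool = False):
    """Corrected source-space spectral estimate from sensor data.

    ``data`` is a :class:`SampleSet`, an n x N matrix of complex sensor
    samples, or an n x n Hermitian sample spectral matrix. The result is
    defensively symmetrized (Hermitian average); with ``return_defect=True``
    the maximum absolute symmetrization adjustment is returned as well — for
    real forward matrices and the column-major convention it is at rounding
    level.
    """
    if isinstance(data, SampleSet):
        S_y = sample_spectral_matrix(data.Y)
    else:
        data = np.asarray(data)
        if data.shape[0] != model.n:
            raise ConfigurationError(
                f"data has {data.shape[0]} rows, expected n = {model.n}"
            )
        S_y = data if data.shape[1] == model.n else sample_spectral_matrix(data)
    if S_y.shape != (model.n, model.n):
        raise ConfigurationError(f"sensor spectral matrix has shape {S_y.shape}")
    est = unvec(spec.F @ vec(S_y), model.p)
    sym = (est + est.conj().T) / 2.0
    if return_defect:
        return sym, float(np.max(np.abs(est - sym)))
    return sym


@dataclass(frozen=True)
class ExpectationDecomposition:
    """Leakage / interaction / noise terms of the estimator expectation."""

    leakage: np.ndarray      # p x p complex
    interaction: np.ndarray  # p x p complex
    noise: np.ndarray        # p x p complex

    @property
    def total(self) -> np.ndarray:
        return self.leakage + self.interaction + self.noise


def decompose_expectation(
    spectral: SpectralModel, spec: EstimatorSpec, model: ForwardModel
) -> ExpectationDecomposition:
    """Split Vec(<S_hat>) = R Vec(S_x+) + R Vec(S_x-) + F Vec(S_e).

    The source-noise cross term of the finite-sample identity has zero
    expectation (sources and noise are uncorrelated) and is dropped here.
    """
    S = spectral.S_x
    S_plus = np.diag(np.diag(S))
    S_minus = S - S_plus
    p = model.p
    leak = unvec(spec.R @ vec(S_plus), p)
    inter = unvec(spec.R @ vec(S_minus), p)
    noise = unvec(spec.F @ vec(spectral.S_e), p)
    return ExpectationDecomposition(leakage=leak, interaction=inter, noise=noise)


def two_point_source_norms(model: ForwardModel, reg, k_src: int, l_src: int,
                           powers=(1.0, 1.0), gamma: float = 0.0,
                           family: int = 1):
    """Closed-form norms of the leakage and interaction terms of two point
    sources, using the point-spread functions r_i of the resolution matrix.

    leakage term:      s_k^2 r_k (x) r_k + s_l^2 r_l (x) r_l
    interaction term:  gamma (r_k (x) r_l + r_l (x) r_k)

    Positive semi-definiteness requires gamma^2 <= s_k^2 s_l^2, under which
    the leakage norm always dominates the interaction norm. The ``family``
    argument selects the lambda scale of the underlying inverse (1: lam,
    2: matrix-space lam^2 mapped back to an effective signal-space level);
    the Kronecker-square geometry itself is that of the source-based family.
    """
    reg = as_regularization(reg)
    sk2, sl2 = (float(x) for x in powers)
    if gamma ** 2 > sk2 * sl2 + 1e-15:
        raise PSDViolationError(
            f"gamma^2 = {gamma**2:.3g} exceeds s_k^2 s_l^2 = {sk2 * sl2:.3g}"
        )
    if family not in (1, 2):
        raise ConfigurationError("two-point norms are defined for families 1 and 2")
    R = minimum_norm_inverse(model, reg).R
    rk, rl = R[:, k_src], R[:, l_src]
    nk2, nl2 = rk @ rk, rl @ rl
    cross = rk @ rl
    leakage_sq = sk2 ** 2 * nk2 ** 2 + sl2 ** 2 * nl2 ** 2 + 2 * sk2 * sl2 * cross ** 2
    interaction_sq = 2 * gamma ** 2 * (cross ** 2 + nk2 * nl2)
    return float(np.sqrt(leakage_sq)), float(np.sqrt(interaction_sq))


def extended_source_ratio(sigma2: float, gamma: float, m: int) -> float:
    """Approximate leakage-to-interaction strength ratio of a homogeneous
    extended source covering m grid points: sigma^2 / ((m - 1) gamma^2).

    Valid when the point-spread functions across the patch are nearly equal;
    grows small for large m, where leakage is negligible relative to
    intra-source connectivity.
    """
    if m < 2:
        raise ConfigurationError(f"extended source needs m >= 2 locations (got {m})")
    if gamma <= 0:
        raise ConfigurationError(f"within-source coherence must be > 0 (got {gamma})")
    return float(sigma2) / ((m - 1) * float(gamma) ** 2)
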