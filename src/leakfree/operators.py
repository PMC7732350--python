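"""Minimum-norm inversion and the vectorized (Kronecker) operator families.

Two routes from an observed sensor spectral matrix to a source-space spectral
matrix exist for a linear forward model ``y = L x + e``:

* *source-based*: invert the signal first. The Tikhonov inverse
  ``L# = L^T (L L^T + lam I)^{-1}`` acts on the data, so in the vectorized
  space of spectral matrices the inverse operator is ``F1 = L# (x) L#`` and
  the resolution operator is ``R1 = (L# L) (x) (L# L)``.
* *sensor-based*: invert in matrix space. With ``K = L (x) L`` the inverse is
  ``F2 = K^T (K K^T + lam2 I)^{-1}`` and ``R2 = F2 K``.

Both families diagonalize in the singular basis of ``L``: if
``L = U diag(D) V^T`` then ``Rj = sum_{k,l} f_kl (v_k v_k^T) (x) (v_l v_l^T)``
with filter coefficients ``f_kl^(1) = d_k^2 d_l^2 / ((d_k^2+lam)(d_l^2+lam))``
and ``f_kl^(2) = d_k^2 d_l^2 / (d_k^2 d_l^2 + lam2)``. Matching
``lam2 = lam^2`` makes the two families directly comparable; the source-based
coefficients are then never larger (stronger damping).

All vectorizations are column-major, so ``Vec(A S A^T) = (A (x) A) Vec(S)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, RankDeficiencyError, SizeCapError
from .forward import ForwardModel

__all__ = [
    "RegularizationSetting",
    "LinearInverse",
    "VectorizedOperatorPair",
    "FilterCoefficients",
    "vec",
    "unvec",
    "diag_vec_indices",
    "minimum_norm_inverse",
    "vectorized_operators",
    "filter_coefficients",
    "spectral_representation_check",
]

#: Refuse dense p^2 x p^2 materialization above this many source points.
DENSE_SIZE_CAP = 200


def vec(S: np.ndarray) -> np.ndarray:
    """Column-major vectorization."""
    return np.asarray(S).ravel(order="F")


def unvec(v: np.ndarray, p: int, q: int | None = None) -> np.ndarray:
    """Inverse of :func:`vec` for a p x q matrix."""
    q = p if q is None else q
    return np.asarray(v).reshape((p, q), order="F")


def diag_vec_indices(p: int) -> np.ndarray:
    """Positions of the diagonal entries (i, i) inside a column-major Vec.

    These are the 1 + (i-1)(p+1) positions in 1-based counting, i.e.
    ``i * (p + 1)`` for 0-based ``i``.
    """
    return np.arange(p) * (p + 1)


@dataclass(frozen=True)
class RegularizationSetting:
    """Regularization level with its scale convention.

    ``lam`` lives on the signal-space scale (that of ``L#``). Matrix-space
    operators (the sensor-based family) use ``lam**2``, the natural
    correspondence between the two filter families. Set ``raw=True`` to use
    ``lam`` verbatim on both scales (for sweeps on the matrix-space scale).
    """

    lam: float
    raw: bool = False

    def __post_init__(self):
        if self.lam < 0:
            raise ConfigurationError(f"lambda must be >= 0 (got {self.lam})")

    @classmethod
    def from_log10(cls, log10_lambda: float, raw: bool = False) -> "RegularizationSetting":
        return cls(lam=10.0 ** log10_lambda, raw=raw)

    @classmethod
    def zero(cls) -> "RegularizationSetting":
        return cls(lam=0.0)

    @property
    def signal_lam(self) -> float:
        return self.lam

    @property
    def matrix_lam(self) -> float:
        return self.lam if self.raw else self.lam ** 2


def as_regularization(reg) -> RegularizationSetting:
    if isinstance(reg, RegularizationSetting):
        return reg
    return RegularizationSetting(lam=float(reg))


@dataclass(frozen=True)
class LinearInverse:
    """Tikhonov inverse ``L#`` with its resolution matrix ``R = L# L``."""

    L_sharp: np.ndarray
    lam: float
    R: np.ndarray


def minimum_norm_inverse(model: ForwardModel, reg) -> LinearInverse:
    """Minimum-norm (Tikhonov) inverse ``L# = L^T (L L^T + lam I)^{-1}``.

    Computed through the singular system, ``L# = V diag(d/(d^2+lam)) U^T``,
    which is algebraically identical and numerically stable down to very
    small lam. For ``lam = 0`` on a full-row-rank ``L`` this is the
    Moore-Penrose pseudoinverse; a rank-deficient ``L`` with ``lam = 0``
    raises :class:`RankDeficiencyError`.
    """
    reg = as_regularization(reg)
    lam = reg.signal_lam
    if lam == 0 and not model.full_row_rank:
        raise RankDeficiencyError(
            f"L L^T is singular (rank {model.r} < n = {model.n}); lambda = 0 not allowed"
        )
    gains = model.D / (model.D ** 2 + lam)
    L_sharp = (model.V * gains) @ model.U.T
    return LinearInverse(L_sharp=L_sharp, lam=lam, R=L_sharp @ model.L)


@dataclass(frozen=True)
class VectorizedOperatorPair:
    """Inverse operator F (p^2 x n^2) and resolution operator R (p^2 x p^2)."""

    kind: str  # "source_based" | "sensor_based"
    F: np.ndarray
    R: np.ndarray
    lam: float  # on the family's own scale


def _check_size(model: ForwardModel, cap: int) -> None:
    if model.p > cap:
        raise SizeCapError(
            f"p = {model.p} exceeds the dense materialization cap ({cap}); "
            "the p^2 x p^2 operators would be too large"
        )


def vectorized_operators(
    model: ForwardModel, reg, kind: str, size_cap: int = DENSE_SIZE_CAP
) -> VectorizedOperatorPair:
    """Materialize the vectorized inverse/resolution pair for one family.

    source_based:  F = L# (x) L#,                R = (L# L) (x) (L# L)
    sensor_based:  F = K^T (K K^T + lam^2 I)^-1, R = F K,   K = L (x) L

    The sensor-based pair is built in the Kronecker singular basis of K
    (singular values ``d_k d_l``, singular vectors ``u_k (x) u_l`` and
    ``v_k (x) v_l``), avoiding the explicit n^2 x n^2 inversion.
    """
    reg = as_regularization(reg)
    _check_size(model, size_cap)
    if kind == "source_based":
        inv = minimum_norm_inverse(model, reg)
        F = np.kron(inv.L_sharp, inv.L_sharp)
        R = np.kron(inv.R, inv.R)
        return VectorizedOperatorPair(kind=kind, F=F, R=R, lam=reg.signal_lam)
    if kind == "sensor_based":
        lam2 = reg.matrix_lam
        d = np.multiply.outer(model.D, model.D).ravel()  # r^2 singular values of K
        if lam2 == 0 and not model.full_row_rank:
            raise RankDeficiencyError(
                f"K K^T is singular (rank {model.r**2} < n^2); lambda = 0 not allowed"
            )
        UK = np.kron(model.U, model.U)  # n^2 x r^2
        VK = np.kron(model.V, model.V)  # p^2 x r^2
        gains = d / (d ** 2 + lam2)
        F = (VK * gains) @ UK.T
        R = (VK * (gains * d)) @ VK.T
        return VectorizedOperatorPair(kind=kind, F=F, R=R, lam=lam2)
    raise ConfigurationError(f"unknown operator kind {kind!r}")


@dataclass(frozen=True)
class FilterCoefficients:
    """Filter matrix f[k, l] over singular-value index pairs, entries in [0, 1]."""

    family: int
    matrix: np.ndarray

    @property
    def gains(self) -> np.ndarray:
        return np.diag(self.matrix)


def filter_coefficients(model: ForwardModel, reg, family: int) -> FilterCoefficients:
    """Filter coefficients of the two estimator families.

    family 1: f_kl = d_k^2 d_l^2 / ((d_k^2 + lam)(d_l^2 + lam))
    family 2: f_kl = d_k^2 d_l^2 / (d_k^2 d_l^2 + lam^2)
    """
    reg = as_regularization(reg)
    d2 = model.D ** 2
    num = np.multiply.outer(d2, d2)
    if family == 1:
        den = np.multiply.outer(d2 + reg.signal_lam, d2 + reg.signal_lam)
    elif family == 2:
        den = num + reg.matrix_lam
    else:
        raise ConfigurationError(f"family must be 1 or 2 (got {family})")
    return FilterCoefficients(family=family, matrix=num / den)


def spectral_representation_check(
    pair: VectorizedOperatorPair, coeffs: FilterCoefficients, model: ForwardModel
) -> float:
    """Max |R - sum_{k,l} f_kl (v_k v_k^T) (x) (v_l v_l^T)|.

    Verifies that the materialized resolution operator matches its singular
    expansion through the filter coefficients. The pair and coefficients must
    come from matched families/lambda scales.
    """
    expected = {1: "source_based", 2: "sensor_based"}[coeffs.family]
    if pair.kind != expected:
        raise ConfigurationError(
            f"operator kind {pair.kind!r} does not match filter family {coeffs.family}"
        )
    VK = np.kron(model.V, model.V)  # columns are v_k (x) v_l = vec of (v_l v_k^T)...
    # (v_k v_k^T) (x) (v_l v_l^T) = (v_k (x) v_l)(v_k (x) v_l)^T, so the whole
    # sum is VK diag(vec f) VK^T with f laid out to match kron column order.
    f = coeffs.matrix  # f[k, l]
    weights = f.ravel(order="C")  # kron(V, V) column k*r + l carries v_k (x) v_l
    rebuilt = (VK * weights) @ VK.T
    return float(np.max(np.abs(pair.R - rebuilt)))
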