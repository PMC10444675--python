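"""Core model components shared by the BRM and the DDRM.

The Beta Response Model (BRM) treats a single bounded response as a proportion
splitting the scale into two parts; its shape parameters carry an IRT
structure (person location ``theta``, item difficulty ``delta``, item
precision ``tau``, global scaling ``alpha``).  The Dirichlet Dual Response
Model (DDRM) extends this to interval responses from a dual-range slider: the
interval splits the unit scale into three proportions modeled by a Dirichlet
distribution whose shapes additionally involve a person expansion tendency
``eta`` and an item expansion parameter ``gamma``.

This module provides the raw-scale rescaling transforms, the link functions
mapping IRT parameters to beta/Dirichlet shapes, the interval log-likelihood,
and small container types used across the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

logger = logging.getLogger(__name__)

#: Hard clip on the exponent inside the link functions.  exp(30) ~ 1e13 keeps
#: all downstream gamma-function evaluations finite in double precision.
EXP_CLIP = 30.0


# ---------------------------------------------------------------------------
# Container types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SingleResponse:
    """A single-range-slider response: raw integer and its (0,1) transform."""

    x_raw: int
    x: float


@dataclass(frozen=True)
class IntervalResponse:
    """A dual-range-slider response.

    Attributes
    ----------
    yl_raw, yu_raw
        Raw slider positions on the 0-100 scale, ``yl_raw <= yu_raw``.
    yl, yu
        Transformed bounds, ``0 < yl < yu < 1`` strictly (even for
        zero-width raw intervals).
    y
        The simplex vector ``(yl, yu - yl, 1 - yu)``: proportions left of,
        inside, and right of the interval.
    """

    yl_raw: int
    yu_raw: int
    yl: float
    yu: float
    y: tuple[float, float, float]


@dataclass(frozen=True)
class PersonParams:
    """Latent person parameters: location ``theta`` and expansion ``eta``."""

    theta: float
    eta: float = 0.0


@dataclass(frozen=True)
class ItemParams:
    """Item parameters: difficulty ``delta``, expansion ``gamma``, precision ``tau >= 0``."""

    delta: float
    gamma: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be nonnegative, got {self.tau}")


@dataclass(frozen=True)
class ScalingParams:
    """Positive scaling parameters: BRM ``alpha``; DDRM ``alpha_lambda``, ``alpha_epsilon``."""

    alpha: float = 0.5
    alpha_lambda: float = 0.5
    alpha_epsilon: float = 0.5

    def __post_init__(self) -> None:
        if min(self.alpha, self.alpha_lambda, self.alpha_epsilon) <= 0:
            raise ValueError("scaling parameters must be positive")


@dataclass(frozen=True)
class BetaShape:
    """Beta shape parameters (m, n) produced by the BRM link function."""

    m: float
    n: float


@dataclass(frozen=True)
class DirichletShape:
    """Dirichlet shape parameters (a, e, d) produced by the DDRM link function.

    ``a`` drives agreement (left proportion), ``e`` expansion (interval
    width), ``d`` disagreement (right proportion).
    """

    a: float
    e: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.e, self.d) <= 0:
            raise ValueError("Dirichlet shape parameters must be positive")

    @property
    def total(self) -> float:
        return self.a + self.e + self.d


@dataclass(frozen=True)
class LatentGammaValues:
    """Latent gamma-distributed interpolation values behind one interval response.

    The response simplex is ``(v_a, v_e, v_d) / (v_a + v_e + v_d)``; the
    common scale ``s`` cancels in the normalisation, so it only matters to the
    sampling construction, never to inference.
    """

    v_a: float
    v_e: float
    v_d: float
    s: float = 1.0


# ---------------------------------------------------------------------------
# Response-scale transforms
# ---------------------------------------------------------------------------


def _check_raw(value, name: str) -> np.ndarray:
    arr = np.asarray(value)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError(f"{name} must be integer-valued, got {value!r}")
        arr = arr.astype(np.int64)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError(f"{name} must lie in [0, 100], got {value!r}")
    return arr


def rescale_rs1(x_raw):
    """Map a raw 0-100 single response to the open unit interval.

    Uses ``x = (x_raw + 1) / 102`` so that the endpoints 0 and 100 map
    strictly inside (0, 1), keeping the beta log-likelihood finite.

    Accepts a scalar (returns :class:`SingleResponse`) or an array
    (returns the transformed array).
    """
    arr = _check_raw(x_raw, "x_raw")
    x = (arr + 1.0) / 102.0
    if arr.ndim == 0:
        return SingleResponse(x_raw=int(arr), x=float(x))
    return x


def rs1_to_raw(x) -> np.ndarray:
    """Inverse of :func:`rescale_rs1` for exactly-transformed values."""
    return np.rint(np.asarray(x) * 102.0 - 1.0).astype(np.int64)


def rescale_rs2(yl_raw, yu_raw):
    """Map raw 0-100 interval bounds to strictly ordered interior bounds.

    Uses ``yl = (yl_raw + 1) / 103`` and ``yu = (yu_raw + 2) / 103`` so that
    ``0 < yl < yu < 1`` holds even when the two sliders coincide
    (a zero-width raw interval keeps a width of 1/103 after transform).

    Accepts scalars (returns :class:`IntervalResponse`) or arrays
    (returns ``(yl, yu)`` arrays).
    """
    l_arr = _check_raw(yl_raw, "yl_raw")
    u_arr = _check_raw(yu_raw, "yu_raw")
    if np.any(l_arr > u_arr):
        raise ValueError("yl_raw must not exceed yu_raw")
    yl = (l_arr + 1.0) / 103.0
    yu = (u_arr + 2.0) / 103.0
    if l_arr.ndim == 0:
        ylf, yuf = float(yl), float(yu)
        return IntervalResponse(
            yl_raw=int(l_arr),
            yu_raw=int(u_arr),
            yl=ylf,
            yu=yuf,
            y=(ylf, yuf - ylf, 1.0 - yuf),
        )
    return yl, yu


def rs2_to_raw(yl, yu) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`rescale_rs2` for exactly-transformed values."""
    l_raw = np.rint(np.asarray(yl) * 103.0 - 1.0).astype(np.int64)
    u_raw = np.rint(np.asarray(yu) * 103.0 - 2.0).astype(np.int64)
    return l_raw, u_raw


def simplex_from_bounds(yl, yu) -> np.ndarray:
    """Stack transformed interval bounds into simplex proportions.

    Returns an array with last axis (left, width, right); each row sums
    to one.
    """
    yl = np.asarray(yl, dtype=float)
    yu = np.asarray(yu, dtype=float)
    return np.stack([yl, yu - yl, 1.0 - yu], axis=-1)


# ---------------------------------------------------------------------------
# Link functions
# ---------------------------------------------------------------------------


def _clipped_exp(exponent, label: str):
    exponent = np.asarray(exponent, dtype=float)
    if np.any(np.abs(exponent) > EXP_CLIP):
        logger.warning("clipping %s link exponent beyond |%.0f|", label, EXP_CLIP)
        exponent = np.clip(exponent, -EXP_CLIP, EXP_CLIP)
    return np.exp(exponent)


def beta_shape(theta, delta, tau, alpha=0.5):
    """BRM link: (theta, delta, tau, alpha) -> beta shapes (m, n).

    ``m = exp[alpha (theta - delta) + tau]`` and
    ``n = exp[-alpha (theta - delta) + tau]``; hence ``m n = exp(2 tau)``
    identically, and the difference theta - delta pushes m and n away from 1
    in opposite directions, moving the beta mode up or down the scale.
    """
    lin = np.asarray(alpha, dtype=float) * (np.asarray(theta, dtype=float) - delta)
    m = _clipped_exp(lin + tau, "beta")
    n = _clipped_exp(-lin + tau, "beta")
    if np.ndim(m) == 0:
        return BetaShape(m=float(m), n=float(n))
    return m, n


def dirichlet_shape(theta, delta, eta, gamma, tau, alpha_lambda=0.5, alpha_epsilon=0.5):
    """DDRM link: IRT parameters -> Dirichlet shapes (a, e, d).

    ``a = exp[alpha_lambda (theta - delta) + tau]``,
    ``e = exp[alpha_epsilon (eta + gamma) + tau]``,
    ``d = exp[-alpha_lambda (theta - delta) + tau]``.

    The location contrast theta - delta moves the interval along the scale
    (a and d in tandem, opposite signs); the expansion sum eta + gamma widens
    it; tau scales all three shapes up, tightening the response distribution
    without changing its mean.
    """
    loc = np.asarray(alpha_lambda, dtype=float) * (np.asarray(theta, dtype=float) - delta)
    exp_ = np.asarray(alpha_epsilon, dtype=float) * (np.asarray(eta, dtype=float) + gamma)
    a = _clipped_exp(loc + tau, "dirichlet")
    e = _clipped_exp(exp_ + tau, "dirichlet")
    d = _clipped_exp(-loc + tau, "dirichlet")
    if np.ndim(a) == 0 and np.ndim(e) == 0:
        return DirichletShape(a=float(a), e=float(e), d=float(d))
    return np.broadcast_arrays(a, e, d)


# ---------------------------------------------------------------------------
# Likelihood evaluation
# ---------------------------------------------------------------------------


def _shape_triplet(shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(shape, DirichletShape):
        return np.asarray(shape.a), np.asarray(shape.e), np.asarray(shape.d)
    a, e, d = shape
    return np.asarray(a, dtype=float), np.asarray(e, dtype=float), np.asarray(d, dtype=float)


def dirichlet_logpdf(y, shape) -> np.ndarray:
    """Log-density of the interval response simplex under Dirichlet shapes.

    Parameters
    ----------
    y
        Simplex vector(s) with last axis of length 3; all components must be
        strictly positive (interior of the simplex).
    shape
        A :class:`DirichletShape` or a triplet of arrays (a, e, d).

    Raises
    ------
    ValueError
        If any simplex component is at the boundary.  Boundary responses are
        a raw-data artefact; apply :func:`rescale_rs2` instead of nudging.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != 3:
        raise ValueError("y must have three components on the last axis")
    if np.any(y <= 0.0):
        raise ValueError(
            "simplex components must be strictly positive; raw boundary "
            "responses should be mapped inward with rescale_rs2"
        )
    if not np.allclose(y.sum(axis=-1), 1.0, atol=1e-8):
        raise ValueError("y components must sum to one")
    a, e, d = _shape_triplet(shape)
    total = a + e + d
    lognorm = special.gammaln(total) - special.gammaln(a) - special.gammaln(e) - special.gammaln(d)
    out = (
        lognorm
        + (a - 1.0) * np.log(y[..., 0])
        + (e - 1.0) * np.log(y[..., 1])
        + (d - 1.0) * np.log(y[..., 2])
    )
    return out if out.ndim else float(out)


def beta_logpdf(x, shape) -> np.ndarray:
    """Log-density of a transformed single response under beta shapes (m, n)."""
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError(
            "responses must be strictly inside (0,1); raw boundary responses "
            "should be mapped inward with rescale_rs1"
        )
    if isinstance(shape, BetaShape):
        m, n = np.asarray(shape.m), np.asarray(shape.n)
    else:
        m, n = (np.asarray(v, dtype=float) for v in shape)
    out = (
        special.gammaln(m + n)
        - special.gammaln(m)
        - special.gammaln(n)
        + (m - 1.0) * np.log(x)
        + (n - 1.0) * np.log1p(-x)
    )
    return out if out.ndim else float(out)


def expected_interval(shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected (lower bound, width, midpoint location) of an interval response.

    The Dirichlet mean gives E[left] = a/S, E[width] = e/S, E[right] = d/S
    with S = a + e + d; the expected midpoint is E[left] + E[width]/2.
    When a = d the expected midpoint is exactly 0.5 for any e.
    """
    a, e, d = _shape_triplet(shape)
    total = a + e + d
    lower = a / total
    width = e / total
    location = lower + width / 2.0
    if np.ndim(lower) == 0:
        return float(lower), float(width), float(location)
    return lower, width, location
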