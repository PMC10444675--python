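"""Analytic item information for the DDRM person parameters.

The expected Fisher information for the person location ``theta`` and the
person expansion ``eta`` has closed form in digamma/trigamma functions,
because the expectation of the data-dependent score terms vanishes at the
true parameters and only the trigamma curvature terms survive.

Notation: for Dirichlet shapes (a, e, d) with total S = a + e + d, the
derivative of the per-shape score with respect to each shape is

    zeta_a_a = psi'(S) - psi'(a)      (< 0, trigamma strictly decreasing)
    zeta_d_d = psi'(S) - psi'(d)      (< 0)
    zeta_a_d = zeta_d_a = psi'(S)

The data-dependent scores themselves (``zeta_a``, ``zeta_d``) involve
log-responses and are only needed by the Monte-Carlo cross-check in the
test-suite, not by the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .model_core import DirichletShape, dirichlet_shape


@dataclass(frozen=True)
class ZetaTerms:
    """Data-free shape-derivative terms entering the information functions."""

    zeta_a_a: float
    zeta_d_d: float
    zeta_a_d: float
    zeta_d_a: float


@dataclass(frozen=True)
class ItemInformation:
    """Fisher information carried by one item about (theta, eta)."""

    i_theta: float
    i_eta: float


def zeta_derivative_terms(shape) -> ZetaTerms:
    """Trigamma derivative terms for a Dirichlet shape triplet."""
    try:
        a, e, d = shape.a, shape.e, shape.d
    except AttributeError:
        a, e, d = shape
    total_tri = special.polygamma(1, np.asarray(a) + e + d)
    return ZetaTerms(
        zeta_a_a=total_tri - special.polygamma(1, a),
        zeta_d_d=total_tri - special.polygamma(1, d),
        zeta_a_d=total_tri,
        zeta_d_a=total_tri,
    )


def _info_theta_from_shapes(a, e, d, alpha_lambda):
    tri_s = special.polygamma(1, a + e + d)
    tri_a = special.polygamma(1, a)
    tri_d = special.polygamma(1, d)
    al = alpha_lambda
    # - [ zeta_a_a * al * a - zeta_d_a * al * d ] * al * a
    # - [ zeta_a_d * al * a - zeta_d_d * al * d ] * (-al) * d
    first = ((tri_s - tri_a) * al * a - tri_s * al * d) * al * a
    second = (tri_s * al * a - (tri_s - tri_d) * al * d) * (-al) * d
    return -(first + second)


def _info_eta_from_shapes(a, e, d, alpha_epsilon):
    tri = special.polygamma(1, a + e + d) - special.polygamma(1, e)
    return -tri * alpha_epsilon**2 * e**2


def item_information_theta(person, item, scaling) -> float:
    """Expected Fisher information about the person location theta.

    Symmetric in the sign of theta - delta (exchanging a and d), unimodal at
    low expansion and tending to a bimodal U-shape as eta + gamma grows.
    """
    a, e, d = _shapes(person, item, scaling)
    out = _info_theta_from_shapes(a, e, d, scaling.alpha_lambda)
    return float(out) if np.ndim(out) == 0 else out


def item_information_eta(person, item, scaling) -> float:
    """Expected Fisher information about the person expansion eta.

    Always positive, monotonically increasing in eta + gamma, and raised by
    moving the location contrast theta - delta away from zero (which
    increases the Dirichlet total and hence the distribution's precision).
    """
    a, e, d = _shapes(person, item, scaling)
    out = _info_eta_from_shapes(a, e, d, scaling.alpha_epsilon)
    return float(out) if np.ndim(out) == 0 else out


def item_information(person, item, scaling) -> ItemInformation:
    return ItemInformation(
        i_theta=item_information_theta(person, item, scaling),
        i_eta=item_information_eta(person, item, scaling),
    )


def _shapes(person, item, scaling):
    shape = dirichlet_shape(
        person.theta,
        item.delta,
        person.eta,
        item.gamma,
        item.tau,
        scaling.alpha_lambda,
        scaling.alpha_epsilon,
    )
    if isinstance(shape, DirichletShape):
        return shape.a, shape.e, shape.d
    return shape


def information_curves(
    location_grid,
    expansion_grid,
    tau_levels,
    alpha_lambda: float = 0.5,
    alpha_epsilon: float = 0.5,
) -> pd.DataFrame:
    """Tabulate both information functions over latent-contrast grids.

    Parameters
    ----------
    location_grid
        Values of the location contrast theta - delta.
    expansion_grid
        Values of the expansion sum eta + gamma.
    tau_levels
        Item precision levels, one curve family per level.

    Returns
    -------
    DataFrame with columns location, expansion, tau, i_theta, i_eta —
    one row per grid point, ready for plotting.
    """
    loc = np.asarray(location_grid, dtype=float)
    exp_ = np.asarray(expansion_grid, dtype=float)
    taus = np.atleast_1d(np.asarray(tau_levels, dtype=float))
    ll, ee, tt = np.meshgrid(loc, exp_, taus, indexing="ij")
    a = np.exp(alpha_lambda * ll + tt)
    e = np.exp(alpha_epsilon * ee + tt)
    d = np.exp(-alpha_lambda * ll + tt)
    return pd.DataFrame(
        {
            "location": ll.ravel(),
            "expansion": ee.ravel(),
            "tau": tt.ravel(),
            "i_theta": _info_theta_from_shapes(a, e, d, alpha_lambda).ravel(),
            "i_eta": _info_eta_from_shapes(a, e, d, alpha_epsilon).ravel(),
        }
    )
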