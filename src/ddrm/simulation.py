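"""Synthetic data generation for the BRM and DDRM.

Reproduces the recovery-study generating process: person parameters
``theta_i, eta_i ~ N(0,1)``; item location and expansion parameters drawn
from the fixed candidate grid spanning [-2, 2] with step ``4/J``; precision
``tau_j ~ U(0, 2)``; scaling parameters fixed at 0.5.  Interval responses are
drawn from the Dirichlet implied by the DDRM link function, single responses
from the beta implied by the BRM link.

A gamma-interpolation sampler mirrors the latent response mechanism (three
gamma variates with a common scale, normalised to the simplex) and serves as
an independent distributional oracle for the direct Dirichlet sampler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import beta_shape, dirichlet_shape

#: (I, J) cells of the full recovery-study design: four test lengths crossed
#: with three sample sizes.
FULL_DESIGN_CONDITIONS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in (100, 250, 500) for j in (10, 15, 20, 30)
)


@dataclass
class StudyDesign:
    """Generating parameters for one simulated dataset."""

    n_persons: int
    n_items: int
    theta: np.ndarray
    eta: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    tau: np.ndarray
    alpha_lambda: float = 0.5
    alpha_epsilon: float = 0.5
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_persons": self.n_persons,
            "n_items": self.n_items,
            "theta": self.theta.tolist(),
            "eta": self.eta.tolist(),
            "delta": self.delta.tolist(),
            "gamma": self.gamma.tolist(),
            "tau": self.tau.tolist(),
            "alpha_lambda": self.alpha_lambda,
            "alpha_epsilon": self.alpha_epsilon,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        return cls(
            n_persons=d["n_persons"],
            n_items=d["n_items"],
            theta=np.asarray(d["theta"]),
            eta=np.asarray(d["eta"]),
            delta=np.asarray(d["delta"]),
            gamma=np.asarray(d["gamma"]),
            tau=np.asarray(d["tau"]),
            alpha_lambda=d["alpha_lambda"],
            alpha_epsilon=d["alpha_epsilon"],
            seed=d.get("seed"),
        )


@dataclass
class SimulatedDataset:
    """One complete person x item table of interval responses plus its design."""

    responses: pd.DataFrame
    design: StudyDesign
    seed: int | None = None

    def write(self, path: str | Path) -> None:
        """Write the response table as CSV with a JSON design sidecar."""
        path = Path(path)
        self.responses.to_csv(path, index=False)
        sidecar = {"design": self.design.to_dict(), "response_seed": self.seed}
        path.with_suffix(".design.json").write_text(json.dumps(sidecar, indent=1))


def item_candidate_grid(n_items: int) -> np.ndarray:
    """The fixed candidate values for delta and gamma: [-2, 2] in steps of 4/J."""
    return np.linspace(-2.0, 2.0, n_items + 1)


def generate_design(
    n_persons: int,
    n_items: int,
    seed: int | np.random.Generator | None = None,
    alpha_lambda: float = 0.5,
    alpha_epsilon: float = 0.5,
) -> StudyDesign:
    """Draw one study design.

    Person parameters are independent standard normal.  Item location and
    expansion parameters are assigned by drawing a random permutation of the
    (J+1)-value candidate grid independently for delta and gamma and keeping
    the first J values, which keeps the item spread balanced across the grid.
    Precisions are uniform on [0, 2].
    """
    if n_persons < 2 or n_items < 2:
        raise ValueError("need at least 2 persons and 2 items")
    rng = np.random.default_rng(seed)
    grid = item_candidate_grid(n_items)
    return StudyDesign(
        n_persons=n_persons,
        n_items=n_items,
        theta=rng.standard_normal(n_persons),
        eta=rng.standard_normal(n_persons),
        delta=rng.permutation(grid)[:n_items],
        gamma=rng.permutation(grid)[:n_items],
        tau=rng.uniform(0.0, 2.0, n_items),
        alpha_lambda=alpha_lambda,
        alpha_epsilon=alpha_epsilon,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def design_shapes(design: StudyDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dirichlet shape arrays (a, e, d), each of shape (I, J), for a design."""
    return dirichlet_shape(
        design.theta[:, None],
        design.delta[None, :],
        design.eta[:, None],
        design.gamma[None, :],
        design.tau[None, :],
        design.alpha_lambda,
        design.alpha_epsilon,
    )


def sample_rs2(
    design: StudyDesign,
    seed: int | np.random.Generator | None = None,
    discretize: bool = False,
) -> SimulatedDataset:
    """Draw one interval response per person x item from the DDRM Dirichlet.

    Responses stay on the continuous (0, 1) scale; with ``discretize=True``
    they are additionally mapped back to the 0-100 integer grid by inverting
    the rescale transforms and rounding (for exercising I/O paths).
    """
    rng = np.random.default_rng(seed)
    a, e, d = design_shapes(design)
    gammas = rng.standard_gamma(np.stack([a, e, d], axis=-1))
    y = gammas / gammas.sum(axis=-1, keepdims=True)
    # gamma draws with very small shapes can underflow to exactly zero;
    # keep responses strictly interior to the simplex
    y = np.clip(y, 1e-10, None)
    y /= y.sum(axis=-1, keepdims=True)
    yl = y[..., 0]
    yu = y[..., 0] + y[..., 1]
    i_idx, j_idx = np.meshgrid(
        np.arange(design.n_persons), np.arange(design.n_items), indexing="ij"
    )
    table = pd.DataFrame(
        {
            "person": i_idx.ravel(),
            "item": j_idx.ravel(),
            "yl": yl.ravel(),
            "yu": yu.ravel(),
        }
    )
    if discretize:
        l_raw = np.clip(np.rint(table["yl"] * 103.0 - 1.0), 0, 100).astype(int)
        u_raw = np.clip(np.rint(table["yu"] * 103.0 - 2.0), 0, 100).astype(int)
        u_raw = np.maximum(l_raw, u_raw)
        table["yl_raw"] = l_raw
        table["yu_raw"] = u_raw
    return SimulatedDataset(
        responses=table,
        design=design,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def sample_rs1(
    theta,
    delta,
    tau,
    alpha: float = 0.5,
    n: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` single responses from the BRM beta distribution."""
    rng = np.random.default_rng(seed)
    m, n_shape = np.broadcast_arrays(*np.atleast_1d(*_beta_mn(theta, delta, tau, alpha)))
    return rng.beta(m, n_shape, size=(n,) + m.shape).squeeze()


def _beta_mn(theta, delta, tau, alpha):
    shape = beta_shape(theta, delta, tau, alpha)
    try:
        return np.asarray(shape.m), np.asarray(shape.n)
    except AttributeError:
        return shape


def sample_rs1_table(
    design: StudyDesign,
    alpha: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """One BRM response per person x item using the design's theta/delta/tau."""
    rng = np.random.default_rng(seed)
    lin = alpha * (design.theta[:, None] - design.delta[None, :])
    m = np.exp(lin + design.tau[None, :])
    n = np.exp(-lin + design.tau[None, :])
    x = rng.beta(m, n)
    i_idx, j_idx = np.meshgrid(
        np.arange(design.n_persons), np.arange(design.n_items), indexing="ij"
    )
    return pd.DataFrame(
        {"person": i_idx.ravel(), "item": j_idx.ravel(), "x": x.ravel()}
    )


def sample_rs2_via_gamma(
    shape,
    s: float = 1.0,
    n: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sample interval simplexes through the latent gamma interpolation.

    Three gamma variates with shapes (a, e, d) and a *common* scale ``s`` are
    normalised to the simplex; the scale cancels, so the result is Dir(a,e,d)
    for any s > 0.  This mirrors the assumed response mechanism and is used
    as an independent check of the direct Dirichlet sampler.
    """
    if s <= 0:
        raise ValueError("gamma scale s must be positive")
    rng = np.random.default_rng(seed)
    try:
        a, e, d = shape.a, shape.e, shape.d
    except AttributeError:
        a, e, d = shape
    v = rng.gamma(shape=np.array([a, e, d]), scale=s, size=(n, 3))
    return v / v.sum(axis=1, keepdims=True)


def generate_dataset(
    n_persons: int,
    n_items: int,
    seed: int | None = None,
    alpha_lambda: float = 0.5,
    alpha_epsilon: float = 0.5,
    discretize: bool = False,
) -> SimulatedDataset:
    """Convenience wrapper: design + responses from one master seed.

    The master seed is split into independent substreams for the design and
    the response draw, so datasets with the same seed are fully reproducible.
    """
    ss = np.random.SeedSequence(seed)
    design_rng, response_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    design = generate_design(
        n_persons, n_items, design_rng, alpha_lambda, alpha_epsilon
    )
    design.seed = seed
    ds = sample_rs2(design, response_rng, discretize=discretize)
    ds.seed = seed
    return ds
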