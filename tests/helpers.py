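"""Independent oracles shared by the unit and acceptance tests."""

import numpy as np

from ddrm import dirichlet_logpdf, dirichlet_shape


def mc_fisher_information(
    which: str,
    theta: float,
    delta: float,
    eta: float,
    gamma: float,
    tau: float,
    alpha_lambda: float = 0.5,
    alpha_epsilon: float = 0.5,
    n: int = 100_000,
    h: float = 1e-3,
    seed: int = 0,
) -> tuple[float, float]:
    """Brute-force Fisher information for theta or eta.

    Estimates -E[d^2 log L / d param^2] by central second differences of the
    log-likelihood at responses sampled from the true model.  Returns the
    estimate and its Monte-Carlo standard error.  Independent of the analytic
    closed forms: it only uses the link function and the Dirichlet density.
    """

    def shapes(th, et):
        s = dirichlet_shape(th, delta, et, gamma, tau, alpha_lambda, alpha_epsilon)
        return (s.a, s.e, s.d)

    rng = np.random.default_rng(seed)
    y = rng.dirichlet(shapes(theta, eta), size=n)
    if which == "theta":
        lo = dirichlet_logpdf(y, shapes(theta - h, eta))
        mid = dirichlet_logpdf(y, shapes(theta, eta))
        hi = dirichlet_logpdf(y, shapes(theta + h, eta))
    elif which == "eta":
        lo = dirichlet_logpdf(y, shapes(theta, eta - h))
        mid = dirichlet_logpdf(y, shapes(theta, eta))
        hi = dirichlet_logpdf(y, shapes(theta, eta + h))
    else:
        raise ValueError(which)
    second = (hi - 2 * mid + lo) / h**2
    return float(-second.mean()), float(second.std(ddof=1) / np.sqrt(n))
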