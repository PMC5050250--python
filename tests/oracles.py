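"""Independent numerical oracles used by the test suite.

Everything here is deliberately written against the mathematical definitions
(quadrature, grids, brute-force simulation) rather than the package's own
closed forms, so agreement is evidence and not tautology.
"""

import numpy as np
from scipy import integrate, stats


def quad_binomial_log_evidence(y: int, f: int, a: float = 1.0) -> float:
    """log ∫ p^y (1−p)^f · Beta(a,a)-prior dp by adaptive quadrature."""
    val, _ = integrate.quad(
        lambda p: p**y * (1 - p) ** f * stats.beta.pdf(p, a, a), 0.0, 1.0,
        limit=200,
    )
    return float(np.log(val))


def grid_log_odds_median(a1, b1, a2, b2, n_grid: int = 4001) -> float:
    """Median of logit(p1) − logit(p2), p_i ~ Beta(a_i, b_i), via the CDF
    identity P(D ≤ d) = ∫ f1(x) F2(x − d) dx on the logit scale and bisection."""

    def cdf_diff(d):
        def f(x):
            p = 1 / (1 + np.exp(-x))
            # logit-normal style change of variables: density of X = logit(p1)
            fx = stats.beta.pdf(p, a1, b1) * p * (1 - p)
            # D = X − Y ≤ d  ⟺  Y ≥ x − d
            q = 1 / (1 + np.exp(-(x - d)))
            return fx * (1 - stats.beta.cdf(q, a2, b2))

        val, _ = integrate.quad(f, -30, 30, limit=400)
        return val

    lo, hi = -10.0, 10.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if cdf_diff(mid) < 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def jzs_bf10_grid(t: float, n1: int, n2: int, r: float, n_grid: int = 200_001) -> float:
    """Two-sided JZS BF10 by dense-grid integration of the g-mixture form.

    δ | g ~ N(0, g), g ~ InvGamma(1/2, r²/2) (so δ is Cauchy(0, r) marginally);
    integrating δ and σ² analytically leaves a 1-D integral over g.
    """
    df = n1 + n2 - 2
    neff = n1 * n2 / (n1 + n2)
    u = np.linspace(1e-9, 1 - 1e-9, n_grid)
    g = u / (1 - u)
    jac = 1.0 / (1 - u) ** 2
    m1 = (1 + neff * g) ** -0.5 * (1 + t**2 / ((1 + neff * g) * df)) ** (
        -(df + 1) / 2
    )
    prior = stats.invgamma.pdf(g, 0.5, scale=r**2 / 2)
    num = np.trapezoid(m1 * prior * jac, u)
    den = (1 + t**2 / df) ** (-(df + 1) / 2)
    return float(num / den)


def two_look_stop_rate(
    n_first: int, n_second: int, alpha: float, n_sims: int, seed: int
) -> float:
    """Brute-force two-look optional stopping (two-sample, δ = 0), written
    independently with its own RNG stream."""
    rng = np.random.default_rng(seed)
    hits = 0
    x = rng.standard_normal((n_sims, n_second))
    y = rng.standard_normal((n_sims, n_second))
    for look in (n_first, n_second):
        xs, ys = x[:, :look], y[:, :look]
        sp2 = (xs.var(axis=1, ddof=1) + ys.var(axis=1, ddof=1)) / 2
        t = (xs.mean(axis=1) - ys.mean(axis=1)) / np.sqrt(sp2 * 2 / look)
        p = 2 * stats.t.sf(np.abs(t), 2 * look - 2)
        if look == n_first:
            first_sig = p < alpha
        else:
            hits = np.mean(first_sig | (p < alpha))
    return float(hits)


def selected_abs_effect(n_per_group: int, alpha: float, n_sims: int, seed: int) -> float:
    """E[|d| given |t| > critical] for null two-sample data, by brute force."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_sims, n_per_group))
    y = rng.standard_normal((n_sims, n_per_group))
    sp2 = (x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2
    d = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2)
    t = d * np.sqrt(n_per_group / 2)
    p = 2 * stats.t.sf(np.abs(t), 2 * n_per_group - 2)
    return float(np.abs(d[p < alpha]).mean())


def folded_null_effect_mean(n_per_group: int, n_sims: int, seed: int) -> float:
    """E[|d|] for null two-sample data (the HARKed mean), by brute force."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_sims, n_per_group))
    y = rng.standard_normal((n_sims, n_per_group))
    sp2 = (x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2
    d = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2)
    return float(np.abs(d).mean())
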