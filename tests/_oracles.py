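"""Independent oracles used by the tests.

These deliberately avoid the package's own computational paths: category
probabilities come from explicit tree-path enumeration, likelihood
maximisation from a coarse grid plus Nelder-Mead polish on the probability
scale, and noncentral chi-square power from its Poisson-mixture series.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, stats


def path_probabilities(dP: float, b: float, g: float, dA: float, k: int) -> dict[str, float]:
    """Category probabilities by enumerating every tree path."""
    u = 1.0 / k
    cp_paths = [
        ([dP], "cp_suspect"),
        ([1 - dP, b], "cp_suspect"),
        ([1 - dP, 1 - b, g, u], "cp_suspect"),
        ([1 - dP, 1 - b, g, 1 - u], "cp_filler"),
        ([1 - dP, 1 - b, 1 - g], "cp_reject"),
    ]
    ca_paths = [
        ([dA], "ca_reject"),
        ([1 - dA, b], "ca_suspect"),
        ([1 - dA, 1 - b, g, u], "ca_suspect"),
        ([1 - dA, 1 - b, g, 1 - u], "ca_filler"),
        ([1 - dA, 1 - b, 1 - g], "ca_reject"),
    ]
    out = {c: 0.0 for c in (
        "cp_suspect", "cp_filler", "cp_reject", "ca_suspect", "ca_filler", "ca_reject")}
    for edges, category in cp_paths + ca_paths:
        out[category] += float(np.prod(edges))
    return out


def _loglik(theta_by_condition: list[tuple[float, float, float, float]],
            counts: np.ndarray, k: int = 6) -> float:
    ll = 0.0
    for theta, n in zip(theta_by_condition, counts):
        probs = path_probabilities(*theta, k)
        order = ("cp_suspect", "cp_filler", "cp_reject",
                 "ca_suspect", "ca_filler", "ca_reject")
        p = np.array([probs[c] for c in order])
        ll += float(np.sum(n * np.log(np.clip(p, 1e-300, None))))
    return ll


def brute_force_g_squared(counts: np.ndarray, slot_map, n_free: int,
                          k: int = 6, grid_points: int = 9) -> float:
    """Maximise the product-multinomial likelihood by grid search plus
    Nelder-Mead polish; return G².

    ``counts`` has shape (C, 6); ``slot_map`` maps a free vector to the list
    of per-condition (dP, b, g, dA) tuples.
    """
    grid = np.linspace(0.02, 0.98, grid_points)
    best_theta, best_ll = None, -np.inf
    for combo in itertools.product(grid, repeat=n_free):
        ll = _loglik(slot_map(np.array(combo)), counts, k)
        if ll > best_ll:
            best_ll, best_theta = ll, np.array(combo)

    def neg(theta):
        theta = np.clip(theta, 1e-9, 1 - 1e-9)
        return -_loglik(slot_map(theta), counts, k)

    res = optimize.minimize(neg, best_theta, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    ll_hat = -res.fun
    tree_totals = np.repeat(counts.reshape(len(counts), 2, 3).sum(axis=2), 3, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_sat = np.where(tree_totals > 0, counts / np.where(tree_totals > 0, tree_totals, 1), 0.0)
        ll_sat = float(np.sum(np.where(counts > 0, counts * np.log(np.where(p_sat > 0, p_sat, 1)), 0.0)))
    return 2.0 * (ll_sat - ll_hat)


def noncentral_chi2_sf_series(x: float, df: int, lam: float, terms: int = 2000) -> float:
    """Upper tail of the noncentral chi-square as a Poisson mixture of
    central chi-square tails."""
    j = np.arange(terms)
    weights = stats.poisson.pmf(j, lam / 2.0)
    return float(np.sum(weights * stats.chi2.sf(x, df + 2 * j)))


def min_detectable_w_bisect(alpha: float, power: float, n_total: int, df: int) -> float:
    """Invert the noncentral chi-square power function by bisection."""
    crit = stats.chi2.ppf(1 - alpha, df)
    lo, hi = 0.0, 1.0
    while noncentral_chi2_sf_series(crit, df, hi) < power:
        hi *= 2
    for _ in range(200):
        mid = (lo + hi) / 2
        if noncentral_chi2_sf_series(crit, df, mid) < power:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt((lo + hi) / 2 / n_total))
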