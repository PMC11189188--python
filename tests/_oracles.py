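"""Independent brute-force oracles used to validate the marginalized
likelihood and the Jaccard index."""

import numpy as np
from scipy.stats import binom, poisson


def enum_loglik(y, psi, lam, phi, K):
    """Direct probability sum over the inclusion indicator a and latent
    abundance M (no log-space tricks): the enumeration oracle."""
    y = np.asarray(y, int)
    phi = np.broadcast_to(np.asarray(phi, float), y.shape)
    total = 0.0
    for a in (0, 1):
        pa = psi if a else 1.0 - psi
        if pa == 0.0:
            continue
        for m in range(K + 1):
            pm = poisson.pmf(m, a * lam)
            pb = np.prod([binom.pmf(yv, m, pv) for yv, pv in zip(y, phi)])
            total += pa * pm * pb
    return np.log(total) if total > 0 else -np.inf


def plain_nmixture_loglik(y, lam, phi, K):
    """Non-inflated N-mixture marginal (psi = 1) by direct summation."""
    return enum_loglik(y, 1.0, lam, phi, K)


def allzero_closed_form(psi, lam, phi):
    """(1 - psi) + psi * exp(-lam * (1 - prod_v (1 - phi_v)))."""
    q = np.prod(1.0 - np.asarray(phi, float))
    return (1.0 - psi) + psi * np.exp(-lam * (1.0 - q))


def jaccard_sets(z_i, z_j):
    """Set-based Jaccard oracle."""
    a = {k for k, v in enumerate(z_i) if v}
    b = {k for k, v in enumerate(z_j) if v}
    if not a | b:
        return float("nan")
    return len(a & b) / len(a | b)


def random_small_instance(rng):
    """One randomized small likelihood instance (lam <= 3, V <= 3, y <= 4)."""
    V = rng.integers(1, 4)
    y = rng.integers(0, 5, V)
    psi = rng.uniform(0.05, 0.95)
    lam = rng.uniform(0.1, 3.0)
    phi = rng.uniform(0.05, 0.95, V)
    return y, psi, lam, phi
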