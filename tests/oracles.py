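"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own likelihood code paths: the
beta-binomial pmf comes from scipy.stats.betabinom in the (n, a, b)
parameterisation, and maximisation is a dense two-stage grid search.
"""

import numpy as np
from scipy import stats


def bb_loglik_ref(X, N, mu, rho):
    """Beta-binomial log-likelihood via scipy's betabinom (a, b) pmf."""
    t = (1.0 - rho) / rho
    return float(stats.betabinom.logpmf(X, N, mu * t, (1.0 - mu) * t).sum())


def binom_loglik_ref(X, N, p):
    return float(stats.binom.logpmf(X, N, p).sum())


def grid_max_bb(X, N, n_coarse=160, n_fine=160):
    """Dense (mu, rho) grid search for the beta-binomial maximum, refined
    once around the coarse argmax.  Includes a near-zero rho column so the
    binomial limit participates.

    Returns (mu, rho, loglik).
    """
    X = np.asarray(X, dtype=float)
    N = np.asarray(N, dtype=float)

    def evaluate(mus, rhos):
        mu_g, rho_g = np.meshgrid(mus, rhos, indexing="ij")
        t = (1.0 - rho_g) / rho_g
        a = (mu_g * t)[..., None]
        b = ((1.0 - mu_g) * t)[..., None]
        ll = stats.betabinom.logpmf(X, N, a, b).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        return float(mus[i]), float(rhos[j]), float(ll[i, j])

    # rho floor 1e-6: below that scipy's betabinom logpmf (alpha, beta ~ 1e8)
    # loses more precision than the 1e-4 comparison tolerance
    mus = np.linspace(1e-4, 1.0 - 1e-4, n_coarse)
    rhos = np.concatenate([[1e-6, 1e-5, 1e-4], np.linspace(1e-3, 0.995, n_coarse)])
    mu0, rho0, _ = evaluate(mus, rhos)

    mu_lo, mu_hi = max(mu0 - 0.02, 1e-6), min(mu0 + 0.02, 1.0 - 1e-6)
    rho_lo, rho_hi = max(rho0 / 4.0, 1e-6), min(rho0 * 4.0 + 1e-3, 0.999)
    mus_f = np.linspace(mu_lo, mu_hi, n_fine)
    rhos_f = np.geomspace(rho_lo, rho_hi, n_fine)
    mu1, rho1, ll1 = evaluate(mus_f, rhos_f)

    # one more zoom for curvature-limited accuracy
    mus_z = np.linspace(max(mu1 - 0.002, 1e-6), min(mu1 + 0.002, 1 - 1e-6), n_fine)
    rhos_z = np.geomspace(max(rho1 * 0.7, 1e-6), min(rho1 * 1.4 + 1e-5, 0.999), n_fine)
    mu2, rho2, ll2 = evaluate(mus_z, rhos_z)
    if ll2 < ll1:
        mu2, rho2, ll2 = mu1, rho1, ll1

    # rho = 0 boundary: the exact binomial limit over the mu grid
    ll_bin = stats.binom.logpmf(X, N, mus[:, None]).sum(axis=1)
    k = int(np.argmax(ll_bin))
    p_hat = X.sum() / N.sum()
    if 0.0 < p_hat < 1.0:
        ll_bin_hat = float(stats.binom.logpmf(X, N, p_hat).sum())
        if ll_bin_hat > ll_bin[k]:
            mus = np.append(mus, p_hat)
            ll_bin = np.append(ll_bin, ll_bin_hat)
            k = len(mus) - 1
    if ll_bin[k] > ll2:
        return float(mus[k]), 0.0, float(ll_bin[k])
    return mu2, rho2, ll2


def bh_ref(p):
    """Textbook step-up BH adjustment."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj
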