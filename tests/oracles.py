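"""Brute-force numerical oracles kept independent of the library code paths."""

import numpy as np
from scipy.linalg import cholesky
from scipy.special import expit


def gp_exact_3d(K, y, ks=None, kss=None, n_nodes=60):
    """Exact (to quadrature accuracy) marginal likelihood and predictive
    probability of a 3-point logistic GP, by tensor Gauss-Hermite integration
    over the latent prior.

    Returns (log_marginal, predictive_prob) — the latter is None unless ``ks``
    and ``kss`` are given.
    """
    assert K.shape == (3, 3)
    nodes, wts = np.polynomial.hermite_e.hermegauss(n_nodes)
    wts = wts / wts.sum()
    L = cholesky(K, lower=True)
    Kinv = np.linalg.inv(K)

    if ks is not None:
        mu_coef = ks @ Kinv
        var_star = float(kss - ks @ Kinv @ ks)
        n1, w1 = np.polynomial.hermite_e.hermegauss(40)
        w1 = w1 / w1.sum()

    z_total = 0.0
    p_total = 0.0
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            f = L @ np.vstack([np.full(n_nodes, a), np.full(n_nodes, b), nodes])
            lik = expit(y[:, None] * f).prod(axis=0)
            z_total += wts[i] * wts[j] * (wts * lik).sum()
            if ks is not None:
                mu_star = mu_coef @ f
                zz = mu_star[None, :] + np.sqrt(max(var_star, 0.0)) * n1[:, None]
                inner = (w1[:, None] * expit(zz)).sum(axis=0)
                p_total += wts[i] * wts[j] * (wts * lik * inner).sum()

    lml = float(np.log(z_total))
    prob = float(p_total / z_total) if ks is not None else None
    return lml, prob
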