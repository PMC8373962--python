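"""Independent reference implementations used as test oracles."""

import math

import numpy as np


def naive_ward(X):
    """O(n^3) agglomeration by Ward's criterion, from first principles.

    Clusters are merged by explicit minimization of the increase in total
    within-cluster sum of squares, computed from cluster means and sizes
    (no Lance-Williams recursion).  Ties break on the lexicographically
    smallest (left, right) node-id pair.  Returns a list of
    (node_a, node_b, delta_ss, new_size) with scipy node numbering.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                ma, mb = X[clusters[a]].mean(0), X[clusters[b]].mean(0)
                na, nb = len(clusters[a]), len(clusters[b])
                delta = na * nb / (na + nb) * float(((ma - mb) ** 2).sum())
                if best is None or delta < best[0] - 1e-12:
                    best = (delta, a, b)
        delta, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = members
        merges.append((a, b, delta, len(members)))
        next_id += 1
    return merges


def pearson_textbook(x, y):
    """Pearson r and two-tailed p by the direct formulas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
    t = r * math.sqrt((n - 2) / (1 - r**2))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), n - 2)
    return r, float(p)


def split_rhat_reference(chains):
    """Split-R-hat written out longhand (Gelman-Rubin with split chains)."""
    chains = np.asarray(chains, dtype=float)
    m_half = chains.shape[1] // 2
    halves = [c[:m_half] for c in chains] + [c[m_half : 2 * m_half] for c in chains]
    halves = np.array(halves)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    grand = chain_means.mean()
    B = n / (m - 1) * ((chain_means - grand) ** 2).sum()
    W = np.mean([np.var(h, ddof=1) for h in halves])
    var_plus = (n - 1) / n * W + B / n
    return math.sqrt(var_plus / W)


def marginal_loglik_quadrature(P, sigma, X, mu, omega, lam, tau, n_nodes=80):
    """Log-likelihood by Gauss-Hermite integration over the latent
    per-observation source realizations y_k = S_jk + C_jk."""
    from numpy.polynomial.hermite_e import hermegauss

    nodes, weights = hermegauss(n_nodes)
    weights = weights / weights.sum()
    X = np.atleast_2d(X)
    n, J = X.shape
    K = mu.shape[1]
    total = 0.0
    for i in range(n):
        for j in range(J):
            centers = mu[j] + lam[j]
            spreads = np.sqrt(omega[j] ** 2 + tau[j] ** 2)
            # integrate over K latent values on a tensor grid
            grids = np.meshgrid(*[centers[k] + spreads[k] * nodes for k in range(K)],
                                indexing="ij")
            wgrids = np.meshgrid(*[weights for _ in range(K)], indexing="ij")
            w = np.ones_like(wgrids[0])
            for wg in wgrids:
                w = w * wg
            mix = sum(P[k] * grids[k] for k in range(K))
            dens = (
                np.exp(-0.5 * ((X[i, j] - mix) / sigma[j]) ** 2)
                / (sigma[j] * math.sqrt(2 * math.pi))
            )
            total += math.log(float((w * dens).sum()))
    return total


def grid_posterior_p1(X, mu, omega, sigma_scale, n_p=1200, n_s=400, s_max=None):
    """Normalized posterior CDF of P1 for a two-source, one-tracer mixing
    model, by direct grid evaluation of prior x likelihood over (P1, sigma).

    Returns (p1_grid, cdf).
    """
    X = np.asarray(X, dtype=float).ravel()
    if s_max is None:
        s_max = 4.0 * max(X.std(), 1.0)
    p1 = (np.arange(n_p) + 0.5) / n_p
    sig = (np.arange(n_s) + 0.5) / n_s * s_max
    P1, S = np.meshgrid(p1, sig, indexing="ij")
    mean = P1 * mu[0, 0] + (1 - P1) * mu[0, 1]
    var = P1**2 * omega[0, 0] ** 2 + (1 - P1) ** 2 * omega[0, 1] ** 2 + S**2
    loglik = np.zeros_like(P1)
    for x in X:
        loglik += -0.5 * ((x - mean) ** 2 / var + np.log(2 * np.pi * var))
    logprior = -0.5 * S**2 / sigma_scale**2
    logpost = loglik + logprior
    logpost -= logpost.max()
    marg = np.exp(logpost).sum(axis=1)
    marg /= marg.sum()
    return p1, np.cumsum(marg)
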