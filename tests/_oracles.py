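"""Independent reference implementations used to verify the fast code paths.

These deliberately avoid the factorised transition updates of the package
kernels: the dense oracle multiplies explicit H^2 x H^2 transition matrices,
and the enumeration oracle literally sums over every hidden state path.
"""

import itertools

import numpy as np

from sireimpute.hmm import emission_table


def dense_hmm_posteriors(panel, obs, theta, error_rate):
    """Forward-backward over ordered haplotype pairs with dense matrices.

    Returns (M, 3) genotype posteriors at sites with obs < 0, NaN elsewhere.
    """
    H, M = panel.shape
    emis = emission_table(error_rate)
    S = H * H

    def site_emission(m):
        e = np.empty(S)
        for j in range(H):
            for k in range(H):
                d = panel[j, m] + panel[k, m]
                e[j * H + k] = emis[d, obs[m]] if obs[m] >= 0 else 1.0
        return e

    def transition(th):
        T1 = (1.0 - th) * np.eye(H) + th / H * np.ones((H, H))
        return np.kron(T1, T1)

    fs = np.empty((M, S))
    f = np.full(S, 1.0 / S) * site_emission(0)
    f /= f.sum()
    fs[0] = f
    for m in range(1, M):
        f = (f @ transition(theta[m - 1])) * site_emission(m)
        f /= f.sum()
        fs[m] = f
    bs = np.empty((M, S))
    b = np.ones(S)
    bs[M - 1] = b
    for m in range(M - 2, -1, -1):
        b = transition(theta[m]) @ (site_emission(m + 1) * b)
        b /= b.sum()
        bs[m] = b

    post = np.full((M, 3), np.nan)
    for m in range(M):
        if obs[m] >= 0:
            continue
        w = fs[m] * bs[m]
        p = np.zeros(3)
        for j in range(H):
            for k in range(H):
                p[panel[j, m] + panel[k, m]] += w[j * H + k]
        post[m] = p / p.sum()
    return post


def enumerate_hmm_posteriors(panel, obs, theta, error_rate):
    """Genotype posteriors by literal summation over all state paths."""
    H, M = panel.shape
    emis = emission_table(error_rate)
    states = list(itertools.product(range(H), repeat=2))

    def trans(th, a, b):
        return (1.0 - th) * (a == b) + th / H

    post = np.full((M, 3), np.nan)
    weights = {}
    total = 0.0
    for path in itertools.product(states, repeat=M):
        p = 1.0 / (H * H)
        for m, (j, k) in enumerate(path):
            if m > 0:
                pj, pk = path[m - 1]
                p *= trans(theta[m - 1], pj, j) * trans(theta[m - 1], pk, k)
            d = panel[j, m] + panel[k, m]
            p *= emis[d, obs[m]] if obs[m] >= 0 else 1.0
        weights[path] = p
        total += p
    for m in range(M):
        if obs[m] >= 0:
            continue
        acc = np.zeros(3)
        for path, p in weights.items():
            j, k = path[m]
            acc[panel[j, m] + panel[k, m]] += p
        post[m] = acc / total
    return post
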