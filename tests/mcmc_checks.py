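"""Shared Monte-Carlo agreement statistic for Gibbs-vs-closed-form checks.

For a chain targeting a known Gaussian posterior, whiten the draws by the
exact posterior Cholesky factor, scale each whitened coordinate's mean
error by its ESS-based MC standard error, and return the sum of squared
z-scores together with the coordinate count.  Under exact sampling the sum
behaves like a chi-square with one df per coordinate, so a 3-SD acceptance
band is  total < K + 3 * sqrt(2K)  over K coordinates.
"""

import warnings

import numpy as np
from scipy.linalg import solve_triangular

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az


def whitened_chi2(draws, ref_mean, post_cov):
    draws = np.asarray(draws, dtype=float)
    L = np.linalg.cholesky(post_cov)
    Wd = solve_triangular(L, (draws - ref_mean).T, lower=True).T
    k = Wd.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = np.array([az.ess(np.ascontiguousarray(Wd[:, j]))
                        for j in range(k)])
    se = Wd.std(axis=0, ddof=1) / np.sqrt(ess)
    z = Wd.mean(axis=0) / se
    return float(np.sum(z ** 2)), k
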