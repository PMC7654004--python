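"""Whole-genome Bayesian regression: Bayesian Ridge Regression and Bayes C-pi.

Both models regress the pre-adjusted phenotype on standardized SNP dosages,

    y* = 1 mu + sum_j z_j a_j + e,     e ~ N(0, I sigma2_e),

and differ only in the prior on marker effects.  BRR assigns every marker an
independent N(0, sigma2_a) prior with one shared variance; Bayes C-pi mixes
a point mass at zero (probability pi) with N(0, sigma2_a) (probability
1 - pi), treats pi as unknown with a Uniform(0, 1) prior, and carries a
per-marker inclusion indicator delta_j.  Both variances get scaled
inverse-chi-square hyperpriors; the intercept gets a flat prior.

Sampling is single-site Gibbs with running-residual bookkeeping, compiled
with numba (the sweep is inherently sequential).  Chains are bit-reproducible
for a fixed seed.  Default chain settings: 30,000 iterations, 20,000 burn-in,
thinning 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .genotypes import GenotypeMatrix

__all__ = ["McmcConfig", "PriorSpec", "PosteriorSummary", "standardize",
           "default_marker_scale", "fit_brr", "fit_bayes_cpi", "predict_gebv",
           "BayesianRidge", "BayesC"]


@dataclass
class McmcConfig:
    n_iter: int = 30_000
    burn_in: int = 20_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PriorSpec:
    """Hyperprior settings for the marker-effect and residual variances.

    ``S2_a`` / ``S2_e`` / ``sigma_s2_tilde`` left as None are resolved from
    the data at fit time: S2_a by the default-scale rule
    S2_a = sigma_tilde_a2 (v_a - 2)/v_a with
    sigma_tilde_a2 = sigma_s2_tilde / ((1 - pi) * sum_j p_j (1 - p_j))
    (denominator m for standardized markers when no allele frequencies are
    supplied), sigma_s2_tilde as half the sample variance of y*, and S2_e so
    the prior mode equals half the sample variance of y*.
    """

    v_a: float = 4.2
    S2_a: float | None = None
    v_e: float = 4.2
    S2_e: float | None = None
    pi_prior: str | float = "uniform"   # "uniform" or a fixed value in [0, 1)
    sigma_s2_tilde: float | None = None
    het_factor_2: bool = False          # use 2*sum p(1-p) in the denominator

    def __post_init__(self):
        if self.S2_a is None and self.v_a <= 2:
            raise ValueError("default-scale rule needs v_a > 2")
        for name in ("S2_a", "S2_e", "sigma_s2_tilde"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if not isinstance(self.pi_prior, str):
            if not 0 <= float(self.pi_prior) < 1:
                raise ValueError("fixed pi must be in [0, 1)")


@dataclass
class PosteriorSummary:
    """Posterior means and retained draws from one Gibbs chain."""

    mu_mean: float
    effect_means: np.ndarray
    inclusion_probs: np.ndarray | None
    pi_samples: np.ndarray | None
    variance_samples: dict
    mu_samples: np.ndarray
    effect_draws: np.ndarray
    retained_draw_count: int
    transform: tuple | None = None
    model: str = "BRR"

    def predict(self, Gnew, transform=None) -> np.ndarray:
        return predict_gebv(Gnew, transform or self.transform, self)

    def save(self, outdir, marker_names=None) -> None:
        """Write posterior means and retained draws as CSV files."""
        import pandas as pd
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        m = len(self.effect_means)
        names = (marker_names if marker_names is not None
                 else [f"m{j + 1}" for j in range(m)])
        eff = pd.DataFrame({"marker": names, "effect_mean": self.effect_means})
        if self.inclusion_probs is not None:
            eff["inclusion_prob"] = self.inclusion_probs
        eff.to_csv(out / "effects.csv", index=False)
        draws = pd.DataFrame({"mu": self.mu_samples,
                              **{k: v for k, v in self.variance_samples.items()}})
        if self.pi_samples is not None:
            draws["pi"] = self.pi_samples
        draws.to_csv(out / "draws.csv", index=False)

    def summary(self) -> str:
        va = self.variance_samples
        lines = [
            f"{self.model} posterior summary",
            "=" * 40,
            f"retained draws      {self.retained_draw_count:>10d}",
            f"mu                  {self.mu_mean:>10.3f}",
            f"E[sigma2_a | y]     {np.mean(va['sigma2_a']):>10.4f}",
            f"E[sigma2_e | y]     {np.mean(va['sigma2_e']):>10.4f}",
        ]
        if self.pi_samples is not None:
            lines.append(f"E[pi | y]           {np.mean(self.pi_samples):>10.4f}")
            lines.append(f"markers in model    {np.sum(self.inclusion_probs > 0.5):>10d}"
                         " (posterior inclusion > 0.5)")
        lines.append("=" * 40)
        return "\n".join(lines)


# ----------------------------------------------------------------------
# standardization and prior scale


def standardize(G):
    """Center and scale marker columns to mean 0, variance 1 (sample SD).

    Accepts a GenotypeMatrix or a plain matrix; missing entries must have
    been imputed first.  Returns (Zstd, means, sds); apply the same means
    and sds to new individuals before prediction.
    """
    M = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    if np.isnan(M).any():
        raise ValueError("missing entries present: impute before standardizing")
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = int(np.flatnonzero(sds == 0)[0])
        raise ValueError(
            f"zero-variance column {bad}: remove monomorphic markers in QC")
    return (M - means) / sds, means, sds


def default_marker_scale(prior: PriorSpec, pi: float, allele_freqs=None,
                         m: int | None = None):
    """Prior scale S2_a from the variance explained by all markers.

    sigma_tilde_a2 = sigma_s2_tilde / ((1 - pi) * D) with
    D = sum_j p_j (1 - p_j) when allele frequencies are given (doubled when
    ``het_factor_2``), else D = m for standardized markers; then
    S2_a = sigma_tilde_a2 * (v_a - 2) / v_a.
    """
    if pi >= 1:
        raise ValueError("pi must be < 1 for the default-scale rule")
    if prior.v_a <= 2:
        raise ValueError("default-scale rule needs v_a > 2")
    if prior.sigma_s2_tilde is None:
        raise ValueError("sigma_s2_tilde must be set to resolve the scale")
    if allele_freqs is not None:
        p = np.asarray(allele_freqs, dtype=float)
        D = float(np.sum(p * (1 - p)))
        if prior.het_factor_2:
            D *= 2.0
    else:
        if m is None:
            raise ValueError("need allele_freqs or a marker count m")
        D = float(m)
    if D <= 0:
        raise ValueError("sum of p(1-p) must be positive")
    sigma_tilde_a2 = prior.sigma_s2_tilde / ((1.0 - pi) * D)
    return sigma_tilde_a2 * (prior.v_a - 2.0) / prior.v_a


# ----------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _brr_kernel(y, Z, n_iter, burn_in, thin, v_a, S2_a, v_e, S2_e,
                sample_variances, sigma2_a0, sigma2_e0, mu0, a0, seed):
    n, m = Z.shape
    np.random.seed(seed)
    mu = mu0
    a = a0.copy()
    sigma2_a = sigma2_a0
    sigma2_e = sigma2_e0
    r = y - mu - Z @ a
    zz = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zz[j] = s
    n_keep = (n_iter - burn_in) // thin
    mu_out = np.empty(n_keep)
    a_out = np.empty((n_keep, m))
    s2a_out = np.empty(n_keep)
    s2e_out = np.empty(n_keep)
    kept = 0
    bad_iter = -1
    for it in range(n_iter):
        # intercept (flat prior)
        rbar = 0.0
        for i in range(n):
            rbar += r[i]
        rbar /= n
        mu_new = np.random.normal(rbar + mu, np.sqrt(sigma2_e / n))
        shift = mu - mu_new
        for i in range(n):
            r[i] += shift
        mu = mu_new
        # marker effects, single site
        lam = sigma2_e / sigma2_a
        for j in range(m):
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * r[i]
            rhs += zz[j] * a[j]
            cj = zz[j] + lam
            mean = rhs / cj
            a_new = np.random.normal(mean, np.sqrt(sigma2_e / cj))
            diff = a[j] - a_new
            if diff != 0.0:
                for i in range(n):
                    r[i] += Z[i, j] * diff
            a[j] = a_new
        if sample_variances:
            ss_a = v_a * S2_a
            for j in range(m):
                ss_a += a[j] * a[j]
            sigma2_a = ss_a / np.random.chisquare(v_a + m)
            ss_e = v_e * S2_e
            for i in range(n):
                ss_e += r[i] * r[i]
            sigma2_e = ss_e / np.random.chisquare(v_e + n)
        if not (np.isfinite(mu) and np.isfinite(sigma2_e) and np.isfinite(sigma2_a)):
            bad_iter = it
            break
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            mu_out[kept] = mu
            for j in range(m):
                a_out[kept, j] = a[j]
            s2a_out[kept] = sigma2_a
            s2e_out[kept] = sigma2_e
            kept += 1
    return mu_out, a_out, s2a_out, s2e_out, bad_iter, mu, a, sigma2_a, sigma2_e


@njit(cache=True)
def _cpi_kernel(y, Z, n_iter, burn_in, thin, v_a, S2_a, v_e, S2_e,
                pi0, pi_fixed, sigma2_a0, sigma2_e0, seed):
    n, m = Z.shape
    np.random.seed(seed)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    a = np.zeros(m)
    delta = np.ones(m)
    pi = pi0
    sigma2_a = sigma2_a0
    sigma2_e = sigma2_e0
    r = y - mu - Z @ a
    zz = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zz[j] = s
    n_keep = (n_iter - burn_in) // thin
    mu_out = np.empty(n_keep)
    a_out = np.empty((n_keep, m))
    s2a_out = np.empty(n_keep)
    s2e_out = np.empty(n_keep)
    pi_out = np.empty(n_keep)
    delta_sum = np.zeros(m)
    kept = 0
    bad_iter = -1
    empty_model_iters = 0
    for it in range(n_iter):
        rbar = 0.0
        for i in range(n):
            rbar += r[i]
        rbar /= n
        mu_new = np.random.normal(rbar + mu, np.sqrt(sigma2_e / n))
        shift = mu - mu_new
        for i in range(n):
            r[i] += shift
        mu = mu_new
        m_in = 0
        for j in range(m):
            # rhs on the residual with marker j removed
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * r[i]
            rhs += zz[j] * a[j]
            u = zz[j]
            denom = sigma2_a * u + sigma2_e
            log_bf = 0.5 * (np.log(sigma2_e) - np.log(denom)) \
                + 0.5 * rhs * rhs * sigma2_a / (sigma2_e * denom)
            if pi <= 0.0:
                include = True
            elif pi >= 1.0:
                include = False
            else:
                t = np.log(1.0 - pi) - np.log(pi) + log_bf
                if t > 35.0:
                    include = True
                elif t < -35.0:
                    include = False
                else:
                    include = np.random.random() < 1.0 / (1.0 + np.exp(-t))
            if include:
                cj = u + sigma2_e / sigma2_a
                a_new = np.random.normal(rhs / cj, np.sqrt(sigma2_e / cj))
                delta[j] = 1.0
                m_in += 1
            else:
                a_new = 0.0
                delta[j] = 0.0
            diff = a[j] - a_new
            if diff != 0.0:
                for i in range(n):
                    r[i] += Z[i, j] * diff
            a[j] = a_new
        if m_in == 0:
            empty_model_iters += 1
        if not pi_fixed:
            pi = np.random.beta(m - m_in + 1.0, m_in + 1.0)
        ss_a = v_a * S2_a
        for j in range(m):
            ss_a += a[j] * a[j]
        sigma2_a = ss_a / np.random.chisquare(v_a + m_in)
        ss_e = v_e * S2_e
        for i in range(n):
            ss_e += r[i] * r[i]
        sigma2_e = ss_e / np.random.chisquare(v_e + n)
        if not (np.isfinite(mu) and np.isfinite(sigma2_e) and np.isfinite(sigma2_a)):
            bad_iter = it
            break
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            mu_out[kept] = mu
            for j in range(m):
                a_out[kept, j] = a[j]
                delta_sum[j] += delta[j]
            s2a_out[kept] = sigma2_a
            s2e_out[kept] = sigma2_e
            pi_out[kept] = pi
            kept += 1
    return (mu_out, a_out, s2a_out, s2e_out, pi_out, delta_sum, kept,
            bad_iter, empty_model_iters)


# ----------------------------------------------------------------------
# model objects


def _resolve_priors(y, m, prior: PriorSpec, pi_for_scale, allele_freqs):
    vary = float(np.var(y, ddof=1))
    prior = PriorSpec(**{**prior.__dict__})
    if prior.sigma_s2_tilde is None:
        prior.sigma_s2_tilde = 0.5 * vary
    if prior.S2_a is None:
        prior.S2_a = default_marker_scale(prior, pi_for_scale, allele_freqs, m=m)
    if prior.S2_e is None:
        # prior mode v S2 / (v + 2) set to half the sample variance of y*
        prior.S2_e = 0.5 * vary * (prior.v_e + 2.0) / prior.v_e
    return prior


class _WholeGenomeRegression:
    """Shared plumbing for the two Gibbs-sampled marker models."""

    def __init__(self, y, Z, allele_freqs=None, transform=None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.Z = np.asfortranarray(np.asarray(Z, dtype=float))
        if self.Z.shape[0] != len(self.y):
            raise ValueError("y and Z row counts disagree")
        self.allele_freqs = allele_freqs
        self.transform = transform

    @classmethod
    def from_genotypes(cls, y, G: GenotypeMatrix):
        Zstd, means, sds = standardize(G)
        return cls(y, Zstd, allele_freqs=G.allele_freqs, transform=(means, sds))


class BayesianRidge(_WholeGenomeRegression):
    """BRR: shared-variance Gaussian prior on every marker effect."""

    def fit(self, mcmc: McmcConfig = McmcConfig(), prior: PriorSpec = PriorSpec(),
            sample_variances=True, sigma2_a=None, sigma2_e=None) -> PosteriorSummary:
        """Run the Gibbs chain.

        ``sample_variances=False`` freezes (sigma2_a, sigma2_e) at the
        supplied values — the conjugate setting whose posterior mean equals
        the closed-form ridge solution.
        """
        n, m = self.Z.shape
        prior = _resolve_priors(self.y, m, prior, 0.0, self.allele_freqs)
        s2a0 = sigma2_a if sigma2_a is not None else prior.sigma_s2_tilde / m
        s2e0 = sigma2_e if sigma2_e is not None else 0.5 * float(np.var(self.y, ddof=1))
        mu_out, a_out, s2a_out, s2e_out, bad, *_ = _brr_kernel(
            self.y, self.Z, mcmc.n_iter, mcmc.burn_in, mcmc.thin,
            prior.v_a, prior.S2_a, prior.v_e, prior.S2_e,
            sample_variances, s2a0, s2e0, float(np.mean(self.y)),
            np.zeros(m), mcmc.seed % 2**32)
        if bad >= 0:
            raise FloatingPointError(f"NaN in Gibbs state at iteration {bad}")
        return PosteriorSummary(
            mu_mean=float(np.mean(mu_out)), effect_means=a_out.mean(axis=0),
            inclusion_probs=None, pi_samples=None,
            variance_samples={"sigma2_a": s2a_out, "sigma2_e": s2e_out},
            mu_samples=mu_out, effect_draws=a_out,
            retained_draw_count=len(mu_out), transform=self.transform,
            model="BRR")


class BayesC(_WholeGenomeRegression):
    """Bayes C-pi: point-mass/Gaussian mixture prior, pi unknown."""

    def fit(self, mcmc: McmcConfig = McmcConfig(),
            prior: PriorSpec = PriorSpec()) -> PosteriorSummary:
        import logging
        n, m = self.Z.shape
        if isinstance(prior.pi_prior, str):
            pi0, pi_fixed = 0.5, False
        else:
            pi0, pi_fixed = float(prior.pi_prior), True
        prior = _resolve_priors(self.y, m, prior, pi0, self.allele_freqs)
        s2a0 = prior.sigma_s2_tilde / max((1 - pi0) * m, 1.0)
        s2e0 = 0.5 * float(np.var(self.y, ddof=1))
        (mu_out, a_out, s2a_out, s2e_out, pi_out, delta_sum, kept, bad,
         empty_iters) = _cpi_kernel(
            self.y, self.Z, mcmc.n_iter, mcmc.burn_in, mcmc.thin,
            prior.v_a, prior.S2_a, prior.v_e, prior.S2_e,
            pi0, pi_fixed, s2a0, s2e0, mcmc.seed % 2**32)
        if bad >= 0:
            raise FloatingPointError(f"NaN in Gibbs state at iteration {bad}")
        if empty_iters > mcmc.n_iter / 2:
            logging.getLogger(__name__).warning(
                "all markers excluded in %d/%d iterations: prior scale may be "
                "misspecified", empty_iters, mcmc.n_iter)
        return PosteriorSummary(
            mu_mean=float(np.mean(mu_out)), effect_means=a_out.mean(axis=0),
            inclusion_probs=delta_sum / max(kept, 1), pi_samples=pi_out,
            variance_samples={"sigma2_a": s2a_out, "sigma2_e": s2e_out},
            mu_samples=mu_out, effect_draws=a_out,
            retained_draw_count=kept, transform=self.transform,
            model="BayesCpi")


def fit_brr(y_star, Zstd, mcmc: McmcConfig = McmcConfig(),
            prior: PriorSpec = PriorSpec(), **kw) -> PosteriorSummary:
    """Functional wrapper around :class:`BayesianRidge`."""
    return BayesianRidge(y_star, Zstd, allele_freqs=kw.pop("allele_freqs", None),
                         transform=kw.pop("transform", None)).fit(
        mcmc=mcmc, prior=prior, **kw)


def fit_bayes_cpi(y_star, Zstd, mcmc: McmcConfig = McmcConfig(),
                  prior: PriorSpec = PriorSpec(), **kw) -> PosteriorSummary:
    """Functional wrapper around :class:`BayesC`."""
    return BayesC(y_star, Zstd, allele_freqs=kw.pop("allele_freqs", None),
                  transform=kw.pop("transform", None)).fit(mcmc=mcmc, prior=prior)


def predict_gebv(Gnew, transform, posterior: PosteriorSummary) -> np.ndarray:
    """Genomic breeding values mu + Z_new a for new individuals.

    Z_new is standardized with the TRAINING means/sds carried in
    ``transform``; genotypes must be imputed and in training marker order.
    """
    M = Gnew.dosages if isinstance(Gnew, GenotypeMatrix) else np.asarray(Gnew, dtype=float)
    if transform is None:
        raise ValueError("need the training (means, sds) transform")
    means, sds = transform
    if M.shape[1] != len(posterior.effect_means) or M.shape[1] != len(means):
        raise ValueError("marker count mismatch with the training panel")
    if np.isnan(M).any():
        raise ValueError("missing genotypes: impute before prediction")
    Znew = (M - means) / sds
    return posterior.mu_mean + Znew @ posterior.effect_means
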