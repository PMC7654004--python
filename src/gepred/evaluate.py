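"""Forward-prediction experimental design and comparison metrics.

The validation scheme mirrors routine breeding practice: marker effects are
estimated on older generations and validated on the newest ones.  The data
split is chronological — the newest generations form the test set, the
next-newest generation is a tuning set (used only for neural-net early
stopping and architecture selection), and everything older trains the
models.  Training-set learning curves come from a ladder of nested random
sub-samples (each larger subset contains every smaller one), and Bayesian
models are optionally refitted "with tuning" (WT) — tuning set merged into
the training subset — to offset the extra data the net sees.

Metrics: Pearson prediction correlation, mean square error of prediction
(MSEP), relative gain RG = (r1 - r2)/r2 * 100, predictive bias (OLS slope
of observed on predicted; 1 = unbiased, > 1 means deflated/under-dispersed
predictions), Spearman rank correlation between methods, and percent
agreement of the top-ranked selection candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import BayesC, BayesianRidge, McmcConfig, PriorSpec, predict_gebv
from .nnet import MLPRegressor, SearchSpace, TrainConfig

__all__ = ["SplitPlan", "SubsampleLadder", "EvaluationReport",
           "chronological_split", "nested_subsamples", "prediction_correlation",
           "msep", "relative_gain", "predictive_bias", "spearman_between",
           "topk_agreement", "run_comparison"]

log = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    train_ids: np.ndarray
    tune_ids: np.ndarray
    test_ids: np.ndarray
    generation_map: dict

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.tune_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/tune/test sets must be disjoint")
        gm = self.generation_map
        if self.train_ids.size and self.tune_ids.size:
            if max(gm[i] for i in self.train_ids) >= min(gm[i] for i in self.tune_ids):
                raise ValueError("training generations must precede tuning")
        if self.tune_ids.size and self.test_ids.size:
            if max(gm[i] for i in self.tune_ids) >= min(gm[i] for i in self.test_ids):
                raise ValueError("tuning generations must precede testing")


@dataclass
class SubsampleLadder:
    fractions: tuple
    subsets: list

    def __post_init__(self):
        for small, big in zip(self.subsets, self.subsets[1:]):
            if not set(small) <= set(big):
                raise ValueError("subsets must be nested")


DEFAULT_FRACTIONS = (1, 3, 5, 7, 10, 15, 20, 30, 40, 50, 60, 70, 80, 90, 100)


def chronological_split(records: pd.DataFrame, n_test_generations: int = 2,
                        tune_generations: int = 1) -> SplitPlan:
    """Split ids by generation label: newest -> test, next -> tune, rest -> train.

    ``records`` needs columns ``id`` and ``generation`` (sortable labels).
    """
    gens = np.sort(records["generation"].unique())
    need = n_test_generations + tune_generations + 1
    if len(gens) < need:
        raise ValueError(f"need at least {need} distinct generations, "
                         f"got {len(gens)}")
    test_gens = set(gens[-n_test_generations:])
    tune_gens = set(gens[-(n_test_generations + tune_generations):-n_test_generations])
    ids = records["id"].astype(str).to_numpy()
    g = records["generation"].to_numpy()
    in_test = np.isin(g, list(test_gens))
    in_tune = np.isin(g, list(tune_gens))
    return SplitPlan(
        train_ids=ids[~in_test & ~in_tune],
        tune_ids=ids[in_tune],
        test_ids=ids[in_test],
        generation_map=dict(zip(ids, g)),
    )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def nested_subsamples(train_ids, fractions=DEFAULT_FRACTIONS,
                      seed=0) -> SubsampleLadder:
    """Nested random subsets: one permutation, subset k = first f_k% of it.

    Sizes are round-half-away-from-zero of f*n/100; nesting is automatic
    because every subset is a prefix of the same permutation.
    """
    train_ids = np.asarray(train_ids)
    fr = tuple(fractions)
    if any(f2 <= f1 for f1, f2 in zip(fr, fr[1:])) or not all(0 < f <= 100 for f in fr):
        raise ValueError("fractions must be strictly ascending in (0, 100]")
    perm = np.random.default_rng(seed).permutation(train_ids)
    subsets = []
    for f in fr:
        k = _round_half_away(f * len(train_ids) / 100.0)
        if k == 0:
            raise ValueError(f"fraction {f}% yields an empty subset")
        subsets.append(perm[:k].copy())
    return SubsampleLadder(fractions=fr, subsets=subsets)


# ----------------------------------------------------------------------
# metrics


def prediction_correlation(y_star_test, y_hat_test) -> float:
    """Pearson correlation between pre-adjusted and predicted values."""
    a = np.asarray(y_star_test, dtype=float).ravel()
    b = np.asarray(y_hat_test, dtype=float).ravel()
    if len(a) < 3:
        raise ValueError("need at least 3 records")
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def msep(y_star_test, y_hat_test) -> float:
    """Mean square error of prediction on the test set."""
    a = np.asarray(y_star_test, dtype=float).ravel()
    b = np.asarray(y_hat_test, dtype=float).ravel()
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("need equal non-empty vectors")
    return float(np.mean((a - b) ** 2))


def relative_gain(r1, r2) -> float:
    """RG = (r1 - r2) / r2 * 100 (percent change of method 1 vs baseline 2)."""
    if r2 == 0:
        raise ValueError("baseline criterion r2 is zero")
    return (r1 - r2) / r2 * 100.0


def predictive_bias(y_star_test, y_hat_test, direction="obs_on_pred") -> float:
    """OLS slope between observed and predicted values; 1 = unbiased.

    Default regresses y* on y_hat (slope > 1 means over-shrunk/deflated
    predictions); ``direction="pred_on_obs"`` flips the regression.
    """
    a = np.asarray(y_star_test, dtype=float).ravel()
    b = np.asarray(y_hat_test, dtype=float).ravel()
    if direction == "pred_on_obs":
        a, b = b, a
    if np.var(b) == 0:
        return np.nan
    return float(np.cov(a, b, ddof=1)[0, 1] / np.var(b, ddof=1))


def spearman_between(y_hat_A, y_hat_B) -> float:
    """Spearman rank correlation (mid-ranks for ties) between two predictions."""
    a = np.asarray(y_hat_A, dtype=float).ravel()
    b = np.asarray(y_hat_B, dtype=float).ravel()
    if len(a) < 3:
        raise ValueError("need at least 3 records")
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.spearmanr(a, b).statistic)


def topk_agreement(y_hat_A, y_hat_B, k_fraction=0.10, k=None,
                   ids=None) -> float:
    """Percent overlap of the top-k individuals ranked by each prediction.

    ``k`` overrides ``k_fraction`` (fraction of n, rounded half away from
    zero).  Ties broken by stable id order (position order if no ids).
    """
    a = np.asarray(y_hat_A, dtype=float).ravel()
    b = np.asarray(y_hat_B, dtype=float).ravel()
    n = len(a)
    if len(b) != n:
        raise ValueError("prediction vectors differ in length")
    if k is None:
        k = _round_half_away(k_fraction * n)
    if k < 1:
        raise ValueError("k must be >= 1 after rounding")
    if k > n:
        raise ValueError("k exceeds the number of individuals")
    order_ids = np.arange(n) if ids is None else np.asarray(ids)
    # stable sort on (-value, id order): descending by value, id breaks ties
    top_a = set(order_ids[np.lexsort((np.arange(n), -a))[:k]])
    top_b = set(order_ids[np.lexsort((np.arange(n), -b))[:k]])
    return 100.0 * len(top_a & top_b) / k


# ----------------------------------------------------------------------
# the comparison harness


@dataclass
class EvaluationReport:
    """Tidy per-method metrics plus between-method agreement tables."""

    metrics: pd.DataFrame          # method, fraction, metric, value
    agreement: pd.DataFrame        # method_a, method_b, fraction, metric, value
    predictions: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    leaderboards: dict = field(default_factory=dict)   # fraction -> DataFrame

    def wide(self, metric: str) -> pd.DataFrame:
        sub = self.metrics[self.metrics["metric"] == metric]
        return sub.pivot(index="method", columns="fraction", values="value")

    def agreement_wide(self, metric: str) -> pd.DataFrame:
        sub = self.agreement[self.agreement["metric"] == metric].copy()
        sub["pair"] = sub["method_a"] + " x " + sub["method_b"]
        return sub.pivot(index="pair", columns="fraction", values="value")

    def summary(self) -> str:
        lines = ["Evaluation report", "=" * 60,
                 "Prediction correlation by training fraction (%):",
                 self.wide("prediction_correlation").round(3).to_string(),
                 "", "MSEP by training fraction (%):",
                 self.wide("msep").round(1).to_string()]
        if self.failures:
            lines += ["", f"failures: {self.failures}"]
        return "\n".join(lines)


def run_comparison(y_star: pd.Series, G, split: SplitPlan,
                   ladder: SubsampleLadder,
                   methods=("BRR", "BayesCpi", "DNN", "BRR-WT", "BayesCpi-WT"),
                   mcmc: McmcConfig = McmcConfig(),
                   prior: PriorSpec = PriorSpec(),
                   train_config: TrainConfig = TrainConfig(),
                   search_space: SearchSpace = SearchSpace(),
                   n_candidates: int = 200,
                   dnn_arch=None,
                   k_fraction: float = 0.10,
                   seed: int = 0) -> EvaluationReport:
    """Fit every method on every ladder subset; evaluate on the fixed test set.

    ``y_star`` is the pre-adjusted phenotype indexed by individual id;
    ``G`` a complete (imputed) GenotypeMatrix covering all split ids.  The
    neural net trains on the subset and early-stops on the tuning set
    (``dnn_arch=None`` triggers a random architecture search per subset);
    BRR/Bayes C-pi train on the subset alone and their WT variants on
    subset + tuning set.  Per-cell failures are recorded and the run
    continues.
    """
    def standardize(M):
        # tolerant variant: a marker monomorphic within a small training
        # subset (but polymorphic panel-wide) is kept as an all-zero column
        # so marker indices stay aligned with the test set
        means = M.mean(axis=0)
        sds = M.std(axis=0, ddof=1)
        sds = np.where(sds == 0, 1.0, sds)
        return (M - means) / sds, means, sds

    y_star = y_star.copy()
    y_star.index = y_star.index.astype(str)
    id_pos = {iid: i for i, iid in enumerate(G.ids)}
    test_ids = np.asarray(split.test_ids, dtype=str)
    tune_ids = np.asarray(split.tune_ids, dtype=str)
    y_test = y_star.loc[test_ids].to_numpy()

    def design(ids):
        rows = np.array([id_pos[i] for i in ids])
        return G.dosages[rows]

    X_test_raw = design(test_ids)
    X_tune_raw = design(tune_ids)
    y_tune = y_star.loc[tune_ids].to_numpy()

    met_rows, agree_rows, failures = [], [], []
    predictions: dict = {}
    leaderboards: dict = {}
    rng = np.random.default_rng(seed)
    for frac, subset in zip(ladder.fractions, ladder.subsets):
        subset = np.asarray(subset, dtype=str)
        preds_here = {}
        for method in methods:
            wt = method.endswith("-WT")
            ids_fit = np.concatenate([subset, tune_ids]) if wt else subset
            try:
                X_fit = design(ids_fit)
                y_fit = y_star.loc[ids_fit].to_numpy()
                fit_seed = int(rng.integers(2**31))
                if method.startswith("BRR"):
                    Zs, mu_, sd_ = standardize(X_fit)
                    post = BayesianRidge(y_fit, Zs, transform=(mu_, sd_)).fit(
                        mcmc=McmcConfig(mcmc.n_iter, mcmc.burn_in, mcmc.thin,
                                        fit_seed))
                    y_hat = predict_gebv(X_test_raw, (mu_, sd_), post)
                elif method.startswith("BayesCpi"):
                    Zs, mu_, sd_ = standardize(X_fit)
                    post = BayesC(y_fit, Zs, transform=(mu_, sd_)).fit(
                        mcmc=McmcConfig(mcmc.n_iter, mcmc.burn_in, mcmc.thin,
                                        fit_seed), prior=prior)
                    y_hat = predict_gebv(X_test_raw, (mu_, sd_), post)
                elif method == "DNN":
                    Zs, mu_, sd_ = standardize(X_fit)
                    Z_tune = (X_tune_raw - mu_) / sd_
                    Z_test = (X_test_raw - mu_) / sd_
                    model = MLPRegressor(y_fit, Zs, y_tune, Z_tune)
                    cfg = TrainConfig(**{**train_config.__dict__,
                                         "seed": fit_seed})
                    if dnn_arch is None:
                        res = model.fit_search(space=search_space,
                                               n_candidates=n_candidates,
                                               config=cfg, seed=fit_seed)
                        leaderboards[frac] = res.leaderboard
                    else:
                        res = model.fit(dnn_arch, cfg)
                    y_hat = res.predict(Z_test)
                else:
                    raise ValueError(f"unknown method {method!r}")
            except Exception as exc:       # record and continue
                log.warning("method %s at %s%% failed: %s", method, frac, exc)
                failures.append((method, frac, str(exc)))
                continue
            preds_here[method] = y_hat
            met_rows += [
                (method, frac, "prediction_correlation",
                 prediction_correlation(y_test, y_hat)),
                (method, frac, "msep", msep(y_test, y_hat)),
                (method, frac, "bias_slope", predictive_bias(y_test, y_hat)),
            ]
        names = [m for m in methods if m in preds_here]
        for i, ma in enumerate(names):
            for mb in names[i + 1:]:
                agree_rows += [
                    (ma, mb, frac, "spearman",
                     spearman_between(preds_here[ma], preds_here[mb])),
                    (ma, mb, frac, "topk_agreement",
                     topk_agreement(preds_here[ma], preds_here[mb],
                                    k_fraction=k_fraction, ids=test_ids)),
                ]
        predictions[frac] = preds_here
    metrics = pd.DataFrame(met_rows,
                           columns=["method", "fraction", "metric", "value"])
    agreement = pd.DataFrame(agree_rows, columns=["method_a", "method_b",
                                                  "fraction", "metric", "value"])
    return EvaluationReport(metrics=metrics, agreement=agreement,
                            predictions=predictions, failures=failures,
                            leaderboards=leaderboards)
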