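"""Marker and phenotype quality control.

Marker filters: minor allele frequency, call rate, and a 1-df chi-square
Hardy-Weinberg goodness-of-fit test; thresholds default to the values
standard in commercial-chip pipelines (MAF >= 0.01, call rate >= 95%,
HWE P >= 1e-10).  Non-autosomal or unmapped markers are handled through a
caller-supplied exclusion list, since no genetic map is simulated here.
Phenotype filter: records beyond +/- z SD of their contemporary-group mean
(z = 3.5 by default) are treated as outliers; group mean and SD include the
candidate record (sample SD, n-1 denominator).

Missing genotypes that survive the call-rate filter are imputed with the
marker's observed mean dosage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = ["QcThresholds", "marker_stats", "filter_markers", "impute_missing",
           "remove_outliers", "EmptyPanelError"]

log = logging.getLogger(__name__)


class EmptyPanelError(RuntimeError):
    """All markers failed QC."""


@dataclass
class QcThresholds:
    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-10
    outlier_z: float = 3.5

    def __post_init__(self):
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 <= self.call_rate_min <= 1:
            raise ValueError("call_rate_min must be in [0, 1]")
        if not 0 <= self.hwe_p_min <= 1:
            raise ValueError("hwe_p_min must be in [0, 1]")
        if self.outlier_z <= 0:
            raise ValueError("outlier_z must be positive")


def hwe_chisq_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square Hardy-Weinberg goodness-of-fit P-value.

    Expected genotype counts come from the observed allele frequency;
    categories with zero expectation are skipped (continuity guard), which
    happens only for monomorphic columns where the statistic is 0.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return np.nan
    p = (2 * n_bb + n_ab) / (2.0 * n)
    expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    nz = expected > 0
    chi2 = float(np.sum((observed[nz] - expected[nz]) ** 2 / expected[nz]))
    return float(stats.chi2.sf(chi2, df=1))


def marker_stats(column: np.ndarray):
    """(maf, call_rate, hwe_p) for one dosage column; NaN marks missing.

    An all-missing column returns (nan, 0, nan) — it cannot pass the
    call-rate filter.
    """
    col = np.asarray(column, dtype=float).ravel()
    obs = col[~np.isnan(col)]
    call_rate = len(obs) / len(col) if len(col) else 0.0
    if len(obs) == 0:
        return np.nan, 0.0, np.nan
    bad = ~np.isin(obs, (0.0, 1.0, 2.0))
    if bad.any():
        raise ValueError("dosages must be 0, 1, 2 or missing for marker QC")
    p = obs.mean() / 2.0
    maf = min(p, 1 - p)
    n_bb = int((obs == 2).sum())
    n_ab = int((obs == 1).sum())
    n_aa = int((obs == 0).sum())
    return maf, call_rate, hwe_chisq_p(n_aa, n_ab, n_bb)


def filter_markers(G: GenotypeMatrix, thr: QcThresholds = QcThresholds(),
                   exclude: set | None = None):
    """Apply the marker filters; returns (filtered matrix, report).

    The report attributes each removal to the first criterion failed in the
    order: exclusion list, MAF, call rate, HWE.  The kept set is identical
    whatever order the criteria are tested in.
    """
    exclude = set(exclude or ())
    records = []
    keep = np.zeros(G.m, dtype=bool)
    for j in range(G.m):
        name = G.marker_names[j]
        maf, call_rate, hwe_p = marker_stats(G.dosages[:, j])
        reason = ""
        if name in exclude:
            reason = "excluded"
        elif not (maf >= thr.maf_min):  # NaN maf fails too
            reason = "maf"
        elif call_rate < thr.call_rate_min:
            reason = "call_rate"
        elif not (np.isnan(hwe_p) or hwe_p >= thr.hwe_p_min):
            reason = "hwe"
        keep[j] = reason == ""
        records.append((name, maf, call_rate, hwe_p, keep[j], reason))
    report = pd.DataFrame(records, columns=["marker", "maf", "call_rate",
                                            "hwe_p", "kept", "reason"])
    if not keep.any():
        raise EmptyPanelError("no marker survived QC")
    return G.subset_markers(keep), report


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the marker's observed mean dosage."""
    dos = G.dosages.copy()
    nan_mask = np.isnan(dos)
    if not nan_mask.any():
        return GenotypeMatrix(G.ids, dos, G.marker_names)
    if nan_mask.all(axis=0).any():
        raise ValueError("all-missing marker: should have failed the call-rate filter")
    col_mean = np.nanmean(dos, axis=0)
    r, c = np.where(nan_mask)
    dos[r, c] = col_mean[c]
    return GenotypeMatrix(G.ids, dos, G.marker_names)


def remove_outliers(y, groups, z: float = 3.5) -> np.ndarray:
    """Indices of records within z group SDs of their group mean.

    Group statistics include the candidate record; sample SD (n-1).  A
    record in a singleton group is kept with a warning (its SD is
    undefined), and zero-SD groups keep all their records.
    """
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    keep = np.ones(len(y), dtype=bool)
    if z <= 0:
        raise ValueError("z must be positive")
    df = pd.DataFrame({"y": y, "g": groups})
    for g, sub in df.groupby("g", sort=False):
        if len(sub) < 2:
            log.warning("contemporary group %r has a single record; kept", g)
            continue
        mu = sub["y"].mean()
        sd = sub["y"].std(ddof=1)
        if sd == 0:
            continue
        bad = np.abs(sub["y"] - mu) > z * sd
        keep[sub.index[bad]] = False
    return np.flatnonzero(keep)
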