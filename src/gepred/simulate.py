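"""Synthetic broiler-like population generator.

Emulates the data structure a two-step genomic-prediction analysis of a
moderately heritable growth trait expects: SNP dosages across a spectrum of
allele frequencies, a discrete non-overlapping-generation pedigree whose dam
reuse creates maternal sibships, and a body-weight-like phenotype built as

    y = mean + sex + contemporary group + Zu (additive) + Wc (maternal) + e,

with the additive and maternal permanent-environment fractions of the
phenotypic variance hitting configurable targets (defaults h2 = 0.23,
c2 = 0.05, phenotypic variance 18,939.6 g^2 — a realistic purebred broiler
body-weight setting).  Effects are rescaled empirically per replicate, so
each generated dataset realises its variance fractions almost exactly; that
makes downstream parameter-recovery tests sharp.

Markers are drawn independently (no linkage disequilibrium); an optional
block-copy mode introduces crude within-block correlation for stress tests
but is off by default, since none of the downstream estimators uses LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .mixed import VarianceComponents

__all__ = ["SimConfig", "TrueValues", "simulate_genotypes", "simulate_pedigree",
           "simulate_phenotypes", "simulate_dataset"]


@dataclass
class SimConfig:
    """Study-design knobs for one synthetic population.

    Attributes
    ----------
    n_individuals, n_markers, n_generations : int
        Population size, SNP panel size, and number of discrete
        non-overlapping generations.
    maf_range : (float, float)
        Allele frequencies drawn Uniform on this range, within (0, 0.5].
    prop_qtl : float
        Fraction of markers with non-zero effect (1 - pi of the mixture
        prior the sparse sampler assumes).
    h2_target, c2_target : float
        Additive-genetic and maternal permanent-environment fractions of
        phenotypic variance.
    n_dams : int
        Breeding dams per generation; reuse creates maternal sibships.
    n_contemporary_groups : int
        Contemporary groups per generation (hatch batches).
    sex_effect : float
        Male-minus-female fixed difference in trait units (g).
    missing_rate : float
        Per-call missing probability for genotypes.
    trait_mean, var_phenotypic : float
        Overall mean and total phenotypic variance of the trait (g, g^2).
    cg_sd : float
        SD of contemporary-group effects (g).
    dam_sire_ratio : float
        Dams per sire when picking breeding males (commercial pedigrees
        carry roughly an order of magnitude more dams than sires).
    """

    n_individuals: int = 3000
    n_markers: int = 1000
    n_generations: int = 6
    maf_range: tuple = (0.05, 0.5)
    prop_qtl: float = 0.1
    h2_target: float = 0.23
    c2_target: float = 0.05
    n_dams: int = 60
    n_contemporary_groups: int = 8
    sex_effect: float = 300.0
    missing_rate: float = 0.0
    seed: int = 0
    trait_mean: float = 2141.8
    var_phenotypic: float = 18939.6
    cg_sd: float = 60.0
    dam_sire_ratio: float = 9.0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.h2_target + self.c2_target >= 1:
            raise ValueError("h2_target + c2_target must be < 1")
        if not 0 < self.prop_qtl <= 1:
            raise ValueError("prop_qtl must be in (0, 1]")
        for name in ("n_individuals", "n_markers", "n_generations",
                     "n_dams", "n_contemporary_groups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class TrueValues:
    """Ground-truth components behind one simulated phenotype vector."""

    marker_effects: np.ndarray
    breeding_values: np.ndarray
    maternal_effects: pd.Series
    fixed_effects: dict
    true_vc: VarianceComponents
    qtl_index: np.ndarray = field(default=None)


def simulate_genotypes(n, m, maf_range=(0.05, 0.5), missing_rate=0.0,
                       seed=0, ids=None, block_size=None,
                       mutation_rate=0.05, pedigree=None) -> GenotypeMatrix:
    """Draw an n x m dosage matrix with Binomial(2, p_j) genotypes.

    Marker frequencies p_j ~ Uniform(maf_range).  By default individuals
    are independent draws (the Hardy-Weinberg setting the QC tests assume).
    With a ``pedigree`` (id, sire, dam in topological order) genotypes are
    gene-dropped instead: founders are Binomial(2, p_j) draws and every
    non-founder inherits one allele sampled from each parent's pair, which
    gives relatives the A-structured genotype correlation a pedigree-based
    analysis expects while markers stay mutually independent (no LD).
    With ``block_size`` set, markers within a block are copies of the
    block's first marker with per-call mutation probability
    ``mutation_rate`` (crude LD stand-in).
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=m)
    if pedigree is not None:
        if block_size is not None:
            raise ValueError("block mode and pedigree mode are exclusive")
        dos = _gene_drop(pedigree, p, rng)
        if ids is None:
            ids = pedigree["id"].to_numpy()
    elif block_size is None:
        dos = rng.binomial(2, p[None, :], size=(n, m)).astype(float)
    else:
        dos = np.empty((n, m))
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            anchor = rng.binomial(2, p[start], size=n).astype(float)
            for j in range(start, stop):
                mutate = rng.random(n) < mutation_rate
                col = anchor.copy()
                col[mutate] = rng.binomial(2, p[j], size=mutate.sum())
                dos[:, j] = col
    if missing_rate > 0:
        dos[rng.random((n, m)) < missing_rate] = np.nan
    if ids is None:
        width = max(5, len(str(n)))
        ids = np.array([f"ind{i + 1:0{width}d}" for i in range(n)])
    return GenotypeMatrix(ids=np.asarray(ids, dtype=str), dosages=dos)


def _gene_drop(pedigree: pd.DataFrame, p: np.ndarray, rng) -> np.ndarray:
    """Mendelian transmission of biallelic markers down a pedigree.

    Each individual carries two allele vectors; founders draw both
    Bernoulli(p_j), non-founders receive one gamete per parent, each locus
    segregating independently (free recombination between markers).
    """
    m = len(p)
    ids = pedigree["id"].astype(str).to_numpy()
    sires = pedigree["sire"].astype(str).to_numpy()
    dams = pedigree["dam"].astype(str).to_numpy()
    hap = {}
    dos = np.empty((len(ids), m))
    for i, iid in enumerate(ids):
        pair = []
        for parent in (sires[i], dams[i]):
            if parent != "0" and parent in hap:
                h1, h2 = hap[parent]
                pick = rng.random(m) < 0.5
                pair.append(np.where(pick, h1, h2))
            else:
                pair.append((rng.random(m) < p).astype(np.int8))
        hap[iid] = (pair[0], pair[1])
        dos[i] = pair[0] + pair[1]
    return dos


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Discrete-generation pedigree with dam reuse.

    Returns a table (id, sire, dam, generation, contemporary_group, sex);
    sex is 1 = male, 2 = female, parent code "0" means unknown (founders).
    Every non-founder's parents belong to the previous generation, so the
    table is topologically ordered by construction.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    n, G = cfg.n_individuals, cfg.n_generations
    per_gen = [n // G + (1 if g < n % G else 0) for g in range(G)]
    width = max(5, len(str(n)))
    rows = []
    prev_males, prev_females = [], []
    counter = 0
    for g in range(G):
        sires = dams = None
        if g > 0:
            n_sires = max(1, int(round(cfg.n_dams / cfg.dam_sire_ratio)))
            if not prev_males or not prev_females:
                raise ValueError("previous generation lacks one sex entirely; "
                                 "increase generation size")
            sires = rng.choice(prev_males, size=min(n_sires, len(prev_males)),
                               replace=False)
            dams = rng.choice(prev_females, size=min(cfg.n_dams, len(prev_females)),
                              replace=False)
        males, females = [], []
        for _ in range(per_gen[g]):
            counter += 1
            iid = f"ind{counter:0{width}d}"
            sex = 1 if rng.random() < 0.5 else 2
            cg = g * cfg.n_contemporary_groups + int(
                rng.integers(cfg.n_contemporary_groups))
            if g == 0:
                sire = dam = "0"
            else:
                sire = str(rng.choice(sires))
                dam = str(rng.choice(dams))
            rows.append((iid, sire, dam, g, f"cg{cg:04d}", sex))
            (males if sex == 1 else females).append(iid)
        prev_males, prev_females = males, females
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "generation",
                                       "contemporary_group", "sex"])


def _fill_centered(dosages: np.ndarray) -> np.ndarray:
    """Column-center dosages, mean-filling missing calls first."""
    filled = dosages.copy()
    col_mean = np.nanmean(filled, axis=0)
    nan_r, nan_c = np.where(np.isnan(filled))
    filled[nan_r, nan_c] = col_mean[nan_c]
    return filled - col_mean


def _rescale(x: np.ndarray, target_sd: float) -> tuple[np.ndarray, float]:
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if target_sd == 0.0 or sd == 0.0:
        return np.zeros_like(x), 0.0
    return x * (target_sd / sd), target_sd / sd


def simulate_phenotypes(G: GenotypeMatrix, pedigree: pd.DataFrame,
                        config: SimConfig):
    """Overlay the trait on genotypes + pedigree.

    A fraction ``prop_qtl`` of markers receives Gaussian effects; breeding
    values, maternal effects and residuals are each rescaled so their sample
    variances hit the configured fractions of ``var_phenotypic`` exactly.
    Records with unknown dam receive their own singleton maternal level (the
    permanent environment they were reared in is still real, just unshared).

    Returns (phenotype table, TrueValues).
    """
    cfg = config
    ped = pedigree.set_index("id", drop=False)
    if not set(G.ids) <= set(ped.index):
        raise ValueError("genotypes and pedigree must share ids")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    n, m = G.n, G.m
    var_p = cfg.var_phenotypic

    n_qtl = max(1, int(round(cfg.prop_qtl * m)))
    qtl = rng.choice(m, size=n_qtl, replace=False)
    a = np.zeros(m)
    a[qtl] = rng.normal(size=n_qtl)
    Zc = _fill_centered(G.dosages)
    u_raw = Zc @ a
    u, scale = _rescale(u_raw, np.sqrt(cfg.h2_target * var_p))
    a *= scale

    rows = ped.loc[G.ids]
    dam_level = np.where(rows["dam"].to_numpy() == "0",
                         "self:" + rows["id"].to_numpy().astype(object),
                         rows["dam"].to_numpy()).astype(str)
    levels = pd.unique(dam_level)
    dam_vals = pd.Series(rng.normal(size=len(levels)), index=levels)
    c_raw = dam_vals[dam_level].to_numpy()
    c, c_scale = _rescale(c_raw, np.sqrt(cfg.c2_target * var_p))
    dam_vals = dam_vals * c_scale

    e_raw = rng.normal(size=n)
    resid_frac = 1.0 - cfg.h2_target - cfg.c2_target
    e, _ = _rescale(e_raw, np.sqrt(resid_frac * var_p))

    sex = rows["sex"].to_numpy()
    sex_term = np.where(sex == 1, cfg.sex_effect / 2.0, -cfg.sex_effect / 2.0)
    cgs = pd.unique(rows["contemporary_group"])
    cg_vals = pd.Series(rng.normal(0.0, cfg.cg_sd, size=len(cgs)), index=cgs)
    cg_term = cg_vals[rows["contemporary_group"]].to_numpy()

    y = cfg.trait_mean + sex_term + cg_term + u + c + e
    phen = pd.DataFrame({
        "id": G.ids,
        "sex": sex,
        "contemporary_group": rows["contemporary_group"].to_numpy(),
        "dam": rows["dam"].to_numpy(),
        "generation": rows["generation"].to_numpy(),
        "weight": y,
    })
    true_vc = VarianceComponents(
        sigma2_u=float(np.var(u, ddof=1)),
        sigma2_c=float(np.var(c, ddof=1)),
        sigma2_e=float(np.var(e, ddof=1)),
    )
    truth = TrueValues(marker_effects=a, breeding_values=u,
                       maternal_effects=dam_vals,
                       fixed_effects={"sex_effect": cfg.sex_effect,
                                      "contemporary_group": cg_vals.to_dict(),
                                      "intercept": cfg.trait_mean},
                       true_vc=true_vc, qtl_index=qtl)
    return phen, truth


def simulate_dataset(config: SimConfig):
    """Full bundle: (GenotypeMatrix, pedigree, phenotypes, TrueValues)."""
    ped = simulate_pedigree(config)
    G = simulate_genotypes(config.n_individuals, config.n_markers,
                           maf_range=config.maf_range,
                           missing_rate=config.missing_rate,
                           seed=np.random.SeedSequence([config.seed, 7]),
                           ids=ped["id"].to_numpy(), pedigree=ped)
    phen, truth = simulate_phenotypes(G, ped, config)
    return G, ped, phen, truth
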