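"""Synthetic hosts, genotypes and parasite outcomes with known ground truth.

The generator emulates a mark-recapture study of a mid-sized mammal host:
~380 hosts trapped at 12 forested sites nested in 6 source areas over two
years and five months, with site-level food/aggregation treatments,
individual age class, sex and body measurements; 14 microsatellite loci
with 6-19 alleles each and high heterozygosity (mean He ~ 0.79); and
parasite outcomes — overdispersed tick counts in two repletion classes,
lice counts, and a 16-taxon endoparasite presence matrix whose row sums
give species richness.

Identity disequilibrium (the heterozygosity correlation across loci that
HFC theory rests on) is induced by a per-individual inbreeding coefficient
F: at each locus, with probability F the two allele copies are identical by
descent (one draw, duplicated), else drawn independently from the pooled
frequencies.  A Beta-distributed F across individuals produces variance in
inbreeding and hence identity disequilibrium; F = 0 gives Hardy-Weinberg
panels.

Outcomes are generated only from the variables named in the truth record:
counts are NB2 (gamma-Poisson) on a log-linear predictor built with the
same design encoding the model stage uses, so a recovered coefficient is
directly comparable to its generating value; richness is a per-taxon
Bernoulli sum with host-level logit shifts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import DesignEncoder, ModelSpec, _make_term, standardize_2sd
from .genotypes import MISSING, GenotypeTable, LocusDef

__all__ = [
    "SimulationConfig",
    "ResponseTruth",
    "paperlike_config",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_counts",
    "simulate_richness",
    "simulate_dataset",
    "recovery_experiment",
    "PAPERLIKE_CATEGORIES",
]

PAPERLIKE_CATEGORIES = {
    "aggregation": ["no", "yes"],
    "food": ["no", "yes"],
    "month": ["April", "May", "June", "July", "August"],
    "year": ["2006", "2007"],
    "age": ["I", "II", "III", "IV"],
    "sex": ["Female", "Male"],
    "area": ["A1", "A2", "A3", "A4", "A5", "A6"],
}

# 14 loci, allele counts spanning 6-19 (mean ~11.3), fragment-length labels
_PAPERLIKE_ALLELES = (6, 7, 8, 9, 10, 10, 11, 11, 12, 12, 13, 14, 16, 19)


@dataclass(frozen=True)
class ResponseTruth:
    """Generating model for one outcome: family, intercept, effects, dispersion."""

    family: str  # "negbin" | "bernoulli_richness"
    intercept: float
    coef: Mapping[str, float] = field(default_factory=dict)
    theta: float = 1.5  # NB2 dispersion (counts only)
    n_taxa: int = 16  # richness only
    prevalence_range: tuple = (0.14, 0.89)  # richness only


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 380
    allele_counts: tuple = _PAPERLIKE_ALLELES
    concentration: float = 0.7  # symmetric Dirichlet; ~0.7 gives mean He ~ 0.79
    f_model: tuple = ("constant", 0.0)  # or ("beta", a, b)
    dropout: float = 0.03  # per-call missingness
    n_sites: int = 12
    n_areas: int = 6
    treatment_sites: tuple = (5, 3, 4)  # aggregated-food, dispersed-food, control
    month_probs: tuple = (0.15, 0.2, 0.25, 0.25, 0.15)
    year_probs: tuple = (0.5, 0.5)
    age_probs: tuple = (0.4, 0.3, 0.2, 0.1)
    p_male: float = 0.5
    truth: Mapping[str, ResponseTruth] = field(default_factory=dict)

    def __post_init__(self):
        if sum(self.treatment_sites) != self.n_sites:
            raise ValueError("treatment site counts must sum to n_sites")
        if not all(k >= 2 for k in self.allele_counts):
            raise ValueError("every locus needs >= 2 alleles")


def paperlike_config(**overrides) -> SimulationConfig:
    """Study-scale defaults: sample sizes, effect directions and magnitudes
    chosen to give realistic burden structure (aggregation and July peak
    tick abundance, food-reduced non-replete burdens, a negative quadratic
    diversity effect on replete ticks, diversity- and sex-linked endoparasite
    richness)."""
    truth = {
        # intercepts are net of the covariate-mix multiplier so realized
        # sample means land near the targets (replete ~2, non-replete ~21,
        # lice ~3 per host)
        "replete_ticks": ResponseTruth(
            family="negbin",
            intercept=-0.65,
            theta=1.5,
            coef={
                "aggregation[yes]": 0.60,
                "food[yes]": -0.14,
                "month[May]": 0.58,
                "month[June]": 0.57,
                "month[July]": 0.85,
                "month[August]": -0.18,
                "area[A2]": 0.82,
                "area[A3]": 0.15,
                "area[A4]": 1.10,
                "area[A5]": 0.17,
                "area[A6]": 0.89,
                "IR": 0.40,
                "IR^2": -0.52,
            },
        ),
        "nonreplete_ticks": ResponseTruth(
            family="negbin",
            intercept=1.48,
            theta=1.0,
            coef={
                "aggregation[yes]": 0.36,
                "food[yes]": -0.41,
                "month[May]": 0.45,
                "month[June]": 0.71,
                "month[July]": 0.95,
                "month[August]": -0.87,
                "year[2007]": -0.12,
                "sex[Male]": 0.31,
                "age[II]": -0.07,
                "age[III]": 0.12,
                "age[IV]": 0.05,
                "area[A2]": 1.53,
                "area[A3]": 1.31,
                "area[A4]": 1.32,
                "area[A5]": 0.83,
                "area[A6]": 0.39,
            },
        ),
        "lice": ResponseTruth(
            family="negbin",
            intercept=1.05,
            theta=0.3,
            coef={
                "aggregation[yes]": -0.5,
                "sex[Male]": 0.3,
                "age[II]": 0.2,
                "age[III]": 0.1,
                "age[IV]": -0.1,
            },
        ),
        # intercept centers the mean host-level logit shift so realized
        # per-taxon prevalences keep the configured 0.14-0.89 span
        "endo_richness": ResponseTruth(
            family="bernoulli_richness",
            intercept=-0.85,
            coef={
                "IR": 0.39,
                "sex[Male]": -0.37,
                "year[2007]": 0.53,
                "food[yes]": 0.89,
                "age[II]": 0.13,
                "age[III]": 0.69,
                "age[IV]": -0.02,
            },
        ),
    }
    base = SimulationConfig(f_model=("beta", 0.5, 9.5), truth=truth)
    return replace(base, **overrides) if overrides else base


# -- genotypes --------------------------------------------------------------------


def simulate_frequencies(config: SimulationConfig, seed=None) -> dict:
    """Per-locus allele frequencies from a symmetric Dirichlet.

    Allele labels are synthetic fragment lengths (3-digit, step 2).
    """
    rng = np.random.default_rng(seed)
    freqs = {}
    for i, k in enumerate(config.allele_counts):
        p = rng.dirichlet(np.full(k, config.concentration))
        # avoid pathological zero-frequency alleles in the generating pool
        p = np.maximum(p, 1e-6)
        p = p / p.sum()
        alleles = [100 + 2 * a for a in range(k)]
        freqs[f"L{i + 1:02d}"] = {int(a): float(pp) for a, pp in zip(alleles, p)}
    return freqs


def _draw_f(config: SimulationConfig, n: int, rng) -> np.ndarray:
    kind = config.f_model[0]
    if kind == "constant":
        return np.full(n, float(config.f_model[1]))
    if kind == "beta":
        a, b = config.f_model[1], config.f_model[2]
        return rng.beta(a, b, size=n)
    raise ValueError(f"unknown inbreeding model {config.f_model!r}")


def simulate_genotypes(
    freqs: dict, f: np.ndarray, seed=None, dropout: float = 0.0, ids=None
) -> GenotypeTable:
    """Diploid genotypes under per-individual inbreeding coefficients ``f``.

    At each (individual, locus): with probability ``f_i`` one allele is drawn
    and duplicated (identical by descent), otherwise two independent draws.
    ``dropout`` is the per-call probability of a missing genotype.
    """
    rng = np.random.default_rng(seed)
    f = np.asarray(f, dtype=float)
    n = len(f)
    if not ((f >= 0) & (f < 1)).all():
        raise ValueError("inbreeding coefficients must lie in [0, 1)")
    ids = ids if ids is not None else [f"ind{i + 1:04d}" for i in range(n)]
    locus_names = list(freqs)
    calls = np.empty((n, len(locus_names), 2), dtype=np.int64)
    for j, name in enumerate(locus_names):
        alleles = np.array(list(freqs[name]), dtype=np.int64)
        p = np.array([freqs[name][int(a)] for a in alleles])
        draws = rng.choice(alleles, size=(n, 2), p=p)
        ibd = rng.random(n) < f
        draws[ibd, 1] = draws[ibd, 0]
        calls[:, j, :] = draws
    if dropout > 0:
        miss = rng.random((n, len(locus_names))) < dropout
        calls[miss] = MISSING
    loci = [
        LocusDef(name, frozenset(int(a) for a in freqs[name])) for name in locus_names
    ]
    return GenotypeTable(ids, loci, calls)


# -- covariates -------------------------------------------------------------------


def simulate_covariates(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Host covariate table: sites nested in areas, site-level treatments,
    month/year/age/sex, and body mass linear in body size plus noise."""
    rng = np.random.default_rng(seed)
    n = config.n_individuals
    cats = PAPERLIKE_CATEGORIES
    sites = [f"S{i + 1:02d}" for i in range(config.n_sites)]
    per_area = config.n_sites // config.n_areas
    site_area = {s: f"A{i // per_area + 1}" for i, s in enumerate(sites)}
    # treatments are blocked within areas (as in the field design): every
    # area mixes treatment types, so treatment dummies are never collinear
    # with area dummies
    if (config.n_sites, config.n_areas, config.treatment_sites) == (12, 6, (5, 3, 4)):
        patterns = [
            ("aggregated", "control"),
            ("aggregated", "dispersed"),
            ("aggregated", "control"),
            ("aggregated", "dispersed"),
            ("aggregated", "control"),
            ("dispersed", "control"),
        ]
    else:
        n_agg, n_disp, _ = config.treatment_sites
        flat = ["aggregated"] * n_agg + ["dispersed"] * n_disp
        flat += ["control"] * (config.n_sites - len(flat))
        patterns = [tuple(flat[i::config.n_areas]) for i in range(config.n_areas)]
    order = rng.permutation(config.n_areas)
    site_trt = {}
    for a in range(config.n_areas):
        pat = list(patterns[order[a]])
        rng.shuffle(pat)
        for s_idx, t in enumerate(pat):
            site_trt[sites[a * per_area + s_idx]] = t

    site_col = rng.choice(sites, size=n)
    df = pd.DataFrame(
        {
            "id": [f"ind{i + 1:04d}" for i in range(n)],
            "site": site_col,
            "area": [site_area[s] for s in site_col],
            "treatment": [site_trt[s] for s in site_col],
            "month": rng.choice(cats["month"], size=n, p=config.month_probs),
            "year": rng.choice(cats["year"], size=n, p=config.year_probs),
            "age": rng.choice(cats["age"], size=n, p=config.age_probs),
            "sex": np.where(rng.random(n) < config.p_male, "Male", "Female"),
        }
    )
    df["aggregation"] = np.where(df["treatment"] == "aggregated", "yes", "no")
    df["food"] = np.where(df["treatment"].isin(["aggregated", "dispersed"]), "yes", "no")
    size = rng.normal(60.0, 5.0, size=n)
    mass = 1.5 + 0.08 * size + rng.normal(0.0, 0.5, size=n)
    df["body_size"] = size
    df["body_mass"] = mass
    return df


def attach_diversity(
    cov: pd.DataFrame, div: pd.DataFrame, metric: str = "IR"
) -> pd.DataFrame:
    """Merge diversity records and add the 2-SD standardized metric column.

    The raw index is kept as ``<metric>_raw``; the column named ``metric``
    is the standardized version the model stage consumes (its quadratic is
    derived inside design encoding).
    """
    out = cov.merge(div[[metric]], left_on="id", right_index=True, how="inner")
    out = out.rename(columns={metric: f"{metric}_raw"})
    std, _, _ = standardize_2sd(out[f"{metric}_raw"].to_numpy())
    out[metric] = std
    return out.reset_index(drop=True)


# -- outcomes ---------------------------------------------------------------------


def _truth_design(df: pd.DataFrame, truth: ResponseTruth) -> np.ndarray:
    """Linear predictor (without intercept) from the truth's named effects."""
    tokens = []
    for key in truth.coef:
        tok = key.split("[")[0] if "[" in key else key
        if tok not in tokens:
            tokens.append(tok)
    terms = tuple(_make_term(t, PAPERLIKE_CATEGORIES) for t in tokens)
    spec = ModelSpec("_truth", "gaussian", terms, PAPERLIKE_CATEGORIES)
    X = DesignEncoder(spec).fit(df).transform(df)
    lp = np.zeros(len(df))
    for key, beta in truth.coef.items():
        if key not in X.columns:
            raise KeyError(f"truth coefficient {key!r} has no design column")
        lp += beta * X[key].to_numpy()
    return lp


def simulate_counts(df: pd.DataFrame, truth: ResponseTruth, seed=None) -> np.ndarray:
    """NB2 counts via the gamma-Poisson mixture on a log-linear predictor."""
    if truth.family != "negbin":
        raise ValueError("simulate_counts requires a negbin truth")
    rng = np.random.default_rng(seed)
    mu = np.exp(truth.intercept + _truth_design(df, truth))
    lam = rng.gamma(shape=truth.theta, scale=mu / truth.theta)
    return rng.poisson(lam)


def simulate_richness(
    df: pd.DataFrame, truth: ResponseTruth, seed=None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-taxon Bernoulli presence with host-level logit shifts; richness =
    row sum.  Returns (richness, presence matrix)."""
    if truth.family != "bernoulli_richness":
        raise ValueError("simulate_richness requires a bernoulli_richness truth")
    rng = np.random.default_rng(seed)
    lo, hi = truth.prevalence_range
    base = np.linspace(lo, hi, truth.n_taxa)
    shift = truth.intercept + _truth_design(df, truth)
    probs = expit(logit(base)[None, :] + shift[:, None])
    presence = (rng.random(probs.shape) < probs).astype(int)
    cols = [f"taxon{t + 1:02d}" for t in range(truth.n_taxa)]
    mat = pd.DataFrame(presence, columns=cols, index=df.index)
    return presence.sum(axis=1), mat


# -- full datasets and recovery ---------------------------------------------------


@dataclass
class SyntheticDataset:
    genotypes: GenotypeTable
    covariates: pd.DataFrame  # includes standardized diversity + outcomes
    diversity: pd.DataFrame
    presence: pd.DataFrame
    truth: SimulationConfig
    freqs: dict


def simulate_dataset(config: SimulationConfig, seed=None) -> SyntheticDataset:
    """Genotypes, covariates and every configured outcome, from one seed."""
    from .diversity import diversity_table  # local import avoids a cycle
    from .genotypes import allele_frequencies

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_freq, s_geno, s_cov, s_out = ss.spawn(4)
    gen_freqs = simulate_frequencies(config, s_freq)
    rng = np.random.default_rng(s_geno)
    f = _draw_f(config, config.n_individuals, rng)
    geno = simulate_genotypes(
        gen_freqs, f, seed=rng, dropout=config.dropout,
        ids=[f"ind{i + 1:04d}" for i in range(config.n_individuals)],
    )
    cov = simulate_covariates(config, s_cov)
    div = diversity_table(geno, allele_frequencies(geno))
    data = attach_diversity(cov, div, metric="IR")
    data = data.merge(div[["HL", "sMLH", "n_typed"]], left_on="id", right_index=True)

    out_rng = np.random.default_rng(s_out)
    presence = pd.DataFrame(index=data.index)
    for name, truth in config.truth.items():
        child = out_rng.spawn(1)[0]
        if truth.family == "negbin":
            data[name] = simulate_counts(data, truth, child)
        else:
            richness, presence = simulate_richness(data, truth, child)
            data[name] = richness
    return SyntheticDataset(geno, data, div, presence, config, gen_freqs)


def recovery_experiment(
    n_replicates: int = 100,
    n_individuals: int = 1000,
    beta_ir2: float = -0.5,
    beta_ir: float = 0.4,
    theta: float = 1.5,
    seed: int = 0,
    response: str = "replete_ticks",
) -> dict:
    """Simulate -> two-stage selection -> model averaging, replicated.

    Reports per-parameter recovery of the quadratic diversity effect:
    mean estimate, bias, empirical SE, 95% CI coverage of the generating
    value, and the fraction of replicates whose top model contains a
    genetic term.  Deterministic given ``seed``.
    """
    from .selection import TwoStageAICcSelector

    if n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    base = paperlike_config(n_individuals=n_individuals, dropout=0.0)
    truth_r = base.truth[response]
    coef = dict(truth_r.coef)
    coef["IR^2"] = beta_ir2
    coef["IR"] = beta_ir
    if beta_ir == 0 and beta_ir2 == 0:
        coef = {k: v for k, v in coef.items() if k not in ("IR", "IR^2")}
    truth_r = replace(truth_r, coef=coef, theta=theta)
    config = replace(base, truth={response: truth_r})

    formulas = [
        f"{response} ~ aggregation + food + month",
        f"{response} ~ aggregation + month",
    ]
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep_seed in ss.spawn(n_replicates):
        ds = simulate_dataset(config, rep_seed)
        sel = TwoStageAICcSelector(
            formulas, family="negbin", categories=PAPERLIKE_CATEGORIES
        ).fit(ds.covariates)
        row = {"genetic_top": sel.genetic_in_top_}
        if "IR^2" in sel.averaged_.index:
            est = sel.averaged_.loc["IR^2"]
            row.update(
                estimate=float(est.beta),
                ci_lo=float(est.ci_lo),
                ci_hi=float(est.ci_hi),
                covered=bool(est.ci_lo <= beta_ir2 <= est.ci_hi),
            )
        rows.append(row)
    reps = pd.DataFrame(rows)
    with_est = reps.dropna(subset=["estimate"]) if "estimate" in reps else reps.iloc[0:0]
    report = {
        "n_replicates": n_replicates,
        "n_individuals": n_individuals,
        "beta_ir2": beta_ir2,
        "beta_ir": beta_ir,
        "theta": theta,
        "n_with_estimate": int(len(with_est)),
        "mean_estimate": float(with_est["estimate"].mean()) if len(with_est) else None,
        "bias": float(with_est["estimate"].mean() - beta_ir2) if len(with_est) else None,
        "empirical_se": float(with_est["estimate"].std(ddof=1))
        if len(with_est) > 1
        else None,
        "coverage": float(with_est["covered"].mean()) if len(with_est) else None,
        "frac_genetic_top": float(reps["genetic_top"].mean()),
    }
    report["replicates"] = reps
    return report


def write_truth_json(config: SimulationConfig, path) -> None:
    """Serialize the generating configuration next to a written dataset."""
    def _default(o):
        if isinstance(o, (ResponseTruth, SimulationConfig)):
            return {k: v for k, v in o.__dict__.items()}
        if isinstance(o, (np.floating, np.integer)):
            return float(o)
        if isinstance(o, (tuple, set)):
            return list(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(config, fh, default=_default, indent=2)
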