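"""Two-stage AICc model selection and multimodel averaging.

Stage one ranks an a-priori candidate set of non-genetic models of a
parasite response and shortlists every model within 2 AICc units of the
best.  Stage two augments each shortlisted model with the genetic-diversity
term and/or its quadratic (to allow curvilinear
heterozygosity-parasitism relationships) and a source-area covariate
guarding against population-structure artifacts, then re-ranks the expanded
set.  Parameters are summarized over the 90% confidence set (smallest
prefix of models whose Akaike weights sum to >= 0.90) by conditional model
averaging with Burnham-Anderson unconditional standard errors:

    w_i   = exp(-dAICc_i / 2) / sum_j exp(-dAICc_j / 2)
    beta~ = sum_i w_i beta_i                       (weights renormalized)
    SE_u  = sum_i w_i sqrt(SE_i^2 + (beta_i - beta~)^2)

Odds ratios are exp(beta) with the CI mapped through exp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .design import ModelSpec, parse_model
from .glm import FitResult, aicc, fit_model

logger = logging.getLogger(__name__)

__all__ = [
    "rank_models",
    "stage_one",
    "stage_two",
    "confidence_set",
    "model_average",
    "write_ranking_table",
    "write_averaged_table",
    "TwoStageAICcSelector",
]


def rank_models(fits: list[FitResult], n: int | None = None) -> pd.DataFrame:
    """Rank fitted candidates by AICc.

    Columns: Model, k, logL, AICc, dAICc, Wi (Akaike weight over the full
    candidate set), Di (evidence ratio w_best/w_i = exp(dAICc/2)).  Ties are
    broken by smaller k, then label.  All fits must share the same n.
    """
    if not fits:
        raise ValueError("empty candidate set")
    ns = {f.nobs for f in fits}
    if len(ns) > 1:
        raise ValueError(f"candidates fitted on different n: {sorted(ns)}")
    if n is not None and n not in ns:
        raise ValueError(f"stated n={n} does not match fits (n={ns.pop()})")
    rows = pd.DataFrame(
        {
            "Model": [f.label for f in fits],
            "k": [f.k for f in fits],
            "logL": [f.llf for f in fits],
            "AICc": [aicc(f) for f in fits],
        }
    )
    rows["dAICc"] = rows["AICc"] - rows["AICc"].min()
    rel = np.exp(-0.5 * rows["dAICc"])
    rows["Wi"] = rel / rel.sum()
    rows["Di"] = np.exp(0.5 * rows["dAICc"])
    rows = rows.sort_values(["AICc", "k", "Model"], kind="mergesort").reset_index(
        drop=True
    )
    return rows


def _fit_candidates(specs, data, **kw):
    fits, failures = [], {}
    for spec in specs:
        try:
            fits.append(fit_model(spec, data, **kw))
        except Exception as exc:  # noqa: BLE001 - logged, stage continues
            logger.warning("model %s failed to fit: %s", spec.label, exc)
            failures[spec.label] = str(exc)
    if not fits:
        raise RuntimeError(f"every candidate failed to fit: {failures}")
    return fits, failures


def stage_one(
    specs: list[ModelSpec], data: pd.DataFrame, delta_threshold: float = 2.0
) -> tuple[pd.DataFrame, list[ModelSpec], dict]:
    """Fit the non-genetic candidates; shortlist those with dAICc <= threshold."""
    fits, failures = _fit_candidates(specs, data)
    ranking = rank_models(fits)
    by_label = {f.label: f for f in fits}
    shortlist = [
        by_label[row.Model].spec
        for row in ranking.itertuples()
        if row.dAICc <= delta_threshold
    ]
    return ranking, shortlist, {"fits": by_label, "failures": failures}


def genetic_variants(
    spec: ModelSpec, genetic_term: str = "IR", area_term: str = "area"
) -> list[ModelSpec]:
    """The four stage-two expansions of one shortlisted model.

    {no genetic term, +G, +G^2, +G+G^2}, each augmented with the area
    covariate.  G^2 alone is a legitimate candidate: a purely curvilinear
    association need not have a linear component.
    """
    quad = f"{genetic_term}^2"
    combos = [[], [genetic_term], [quad], [genetic_term, quad]]
    out = []
    for combo in combos:
        out.append(spec.with_terms(combo + [area_term]))
    return out


def stage_two(
    shortlist: list[ModelSpec],
    data: pd.DataFrame,
    genetic_term: str = "IR",
    area_term: str = "area",
) -> tuple[pd.DataFrame, dict]:
    """Expand the shortlist with genetic terms + area, fit and rank."""
    if not shortlist:
        raise ValueError("empty shortlist")
    specs, seen = [], set()
    for s in shortlist:
        for v in genetic_variants(s, genetic_term, area_term):
            if v.label not in seen:
                specs.append(v)
                seen.add(v.label)
    fits, failures = _fit_candidates(specs, data)
    ranking = rank_models(fits)
    return ranking, {"fits": {f.label: f for f in fits}, "failures": failures}


def confidence_set(ranking: pd.DataFrame, mass: float = 0.90) -> pd.DataFrame:
    """Smallest prefix of the ranking whose cumulative Akaike weight >= mass."""
    cum = ranking["Wi"].cumsum()
    stop = int(np.searchsorted(cum.to_numpy(), mass - 1e-12) + 1)
    return ranking.iloc[:stop].copy()


def model_average(
    fits: dict, conf: pd.DataFrame, z: float = 1.96, shrink: bool = False
) -> pd.DataFrame:
    """Model-averaged estimates over a confidence set.

    Weights are renormalized within the set.  By default averaging is
    conditional ("natural"): a parameter is averaged only over the models
    that contain it, with those models' weights renormalized.  With
    ``shrink=True`` a model lacking the parameter contributes beta = 0, SE =
    0 with its full weight (zero-substitution averaging).

    Returns one row per parameter: beta, SE (unconditional), ci_lo, ci_hi,
    odds (+CI), and the summed weight of the models containing it.
    """
    if conf.empty:
        raise ValueError("empty confidence set")
    labels = conf["Model"].tolist()
    w = conf["Wi"].to_numpy(dtype=float)
    w = w / w.sum()
    sub = [fits[lab] for lab in labels]
    params = []
    for f in sub:
        params.extend(p for p in f.params.index if p not in params)
    rows = []
    for p in params:
        betas, ses, ws = [], [], []
        for wi, f in zip(w, sub):
            if p in f.params.index:
                betas.append(float(f.params[p]))
                ses.append(float(f.bse[p]))
                ws.append(wi)
            elif shrink:
                betas.append(0.0)
                ses.append(0.0)
                ws.append(wi)
        betas, ses, ws = np.array(betas), np.array(ses), np.array(ws)
        importance = float(
            sum(wi for wi, f in zip(w, sub) if p in f.params.index)
        )
        ws = ws / ws.sum()
        beta = float(np.sum(ws * betas))
        se_u = float(np.sum(ws * np.sqrt(ses**2 + (betas - beta) ** 2)))
        lo, hi = beta - z * se_u, beta + z * se_u
        rows.append(
            {
                "parameter": p,
                "beta": beta,
                "SE": se_u,
                "ci_lo": lo,
                "ci_hi": hi,
                "odds": np.exp(beta),
                "odds_lo": np.exp(lo),
                "odds_hi": np.exp(hi),
                "weight": importance,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def reference_parameters(specs: list[ModelSpec]) -> list[str]:
    """``name[reference_level]`` labels for every categorical term involved."""
    out = []
    for spec in specs:
        for t in spec.terms:
            if t.kind == "categorical" and t.token in spec.categories:
                lab = f"{t.token}[{spec.categories[t.token][0]}]"
                if lab not in out:
                    out.append(lab)
    return out


# -- report writers ---------------------------------------------------------------


def write_ranking_table(ranking: pd.DataFrame, path) -> None:
    """TSV mirror of a ranking table: Model, k, dAICc, Wi, Di, logL at 2 dp."""
    out = ranking[["Model", "k", "dAICc", "Wi", "Di", "logL"]].copy()
    for c in ("dAICc", "Wi", "Di", "logL"):
        out[c] = out[c].map(lambda v: f"{v:.2f}")
    out.to_csv(path, sep="\t", index=False)


def write_averaged_table(
    averaged: pd.DataFrame, path, reference_levels: list[str] | None = None
) -> None:
    """TSV of averaged estimates; reference levels appear as beta 0 with dashes."""
    rows = []
    for p, r in averaged.iterrows():
        rows.append(
            {
                "Predictor": p,
                "Beta": f"{r.beta:.2f}",
                "CI_lo": f"{r.ci_lo:.2f}",
                "CI_hi": f"{r.ci_hi:.2f}",
                "SE": f"{r.SE:.2f}",
                "Odds": f"{r.odds:.2f}",
                "Odds_lo": f"{r.odds_lo:.2f}",
                "Odds_hi": f"{r.odds_hi:.2f}",
            }
        )
    for p in reference_levels or []:
        rows.append(
            {
                "Predictor": p,
                "Beta": "0.00",
                "CI_lo": "-",
                "CI_hi": "-",
                "SE": "-",
                "Odds": "-",
                "Odds_lo": "-",
                "Odds_hi": "-",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- estimator facade -------------------------------------------------------------


class TwoStageAICcSelector(BaseEstimator):
    """scikit-learn-style estimator running the full two-stage procedure.

    Parameters
    ----------
    stage1_formulas : list of str
        A-priori non-genetic candidate models, e.g.
        ``"replete_ticks ~ aggregation + food + month"``.
    family : {"negbin", "gaussian"}
    categories : mapping
        Column -> ordered levels (first = reference) for categorical terms.
    genetic_term, area_term : str
        Names of the standardized diversity column and the source-area
        covariate added in stage two.
    delta_threshold : float
        Stage-one shortlist cut (dAICc <= threshold).
    conf_mass : float
        Cumulative-weight mass of the confidence set used for averaging.

    Fitted attributes: ``stage1_ranking_``, ``shortlist_``, ``ranking_``,
    ``fits_``, ``confidence_set_``, ``averaged_``, ``top_spec_``,
    ``genetic_in_top_``.
    """

    def __init__(
        self,
        stage1_formulas,
        family="negbin",
        categories=None,
        genetic_term="IR",
        area_term="area",
        delta_threshold=2.0,
        conf_mass=0.90,
    ):
        self.stage1_formulas = stage1_formulas
        self.family = family
        self.categories = categories
        self.genetic_term = genetic_term
        self.area_term = area_term
        self.delta_threshold = delta_threshold
        self.conf_mass = conf_mass

    def fit(self, X: pd.DataFrame, y=None):
        cats = self.categories or {}
        specs = [parse_model(f, self.family, cats) for f in self.stage1_formulas]
        self.stage1_ranking_, self.shortlist_, s1 = stage_one(
            specs, X, self.delta_threshold
        )
        self.stage1_fits_ = s1["fits"]
        self.ranking_, s2 = stage_two(
            self.shortlist_, X, self.genetic_term, self.area_term
        )
        self.fits_ = s2["fits"]
        self.confidence_set_ = confidence_set(self.ranking_, self.conf_mass)
        self.averaged_ = model_average(self.fits_, self.confidence_set_)
        top_label = self.ranking_.iloc[0]["Model"]
        self.top_fit_ = self.fits_[top_label]
        self.top_spec_ = self.top_fit_.spec
        gen_tokens = {self.genetic_term, f"{self.genetic_term}^2"}
        self.genetic_in_top_ = bool(
            gen_tokens & {t.token for t in self.top_spec_.terms}
        )
        return self
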