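"""Single-locus decomposition of a multilocus heterozygosity effect.

When the best burden model contains a multilocus diversity term, the
question remains whether the association is genome-wide or driven by one
or a few markers.  The top model is refit with the diversity term(s)
replaced by one binary heterozygosity indicator per locus (0 homozygous,
1 heterozygous), on the individuals with complete genotypes.  Four
summaries follow:

* a nested-style F-test of whether the locus-level model explains more
  variance than the multilocus one (RSS-based for Gaussian fits,
  deviance-based at the locus model's theta for negative-binomial fits);
* per-locus effect sizes as partial correlations r = t / sqrt(t^2 + df),
  with Fisher-z 95% intervals;
* an exact binomial sign test of whether positive and negative locus
  effects occur equally often;
* Pearson regressions of locus effect size on locus diversity
  (number of alleles, Ho, He).

A genome-wide effect spread weakly over many loci of one sign tends to
leave the F-test silent while the sign test rejects — the dissociation the
decomposition is designed to expose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelSpec
from .glm import FitResult, fit_model, refit_negbin_fixed_theta

logger = logging.getLogger(__name__)

__all__ = [
    "build_replacement_model",
    "variance_explained_f_test",
    "effect_sizes",
    "sign_test",
    "effect_vs_diversity",
    "SingleLocusReport",
    "run_single_locus_stage",
]


def build_replacement_model(
    top_spec: ModelSpec, locus_names: list, genetic_term: str = "IR"
) -> ModelSpec:
    """Swap the multilocus diversity term(s) for per-locus binary terms."""
    if not locus_names:
        raise ValueError("no loci to substitute")
    gen_tokens = [
        t.token
        for t in top_spec.terms
        if t.token in (genetic_term, f"{genetic_term}^2")
    ]
    if not gen_tokens:
        raise ValueError(
            f"top model {top_spec.label!r} contains no {genetic_term} term"
        )
    return top_spec.without_terms(gen_tokens).with_terms(list(locus_names))


def variance_explained_f_test(
    fit_mlh: FitResult, fit_sl: FitResult
) -> tuple[float, int, int, float]:
    """F-test comparing the multilocus and single-locus models.

    df1 = difference in regression df, df2 = residual df of the locus-level
    model.  Gaussian: F built from residual sums of squares; negative
    binomial: from deviances, both evaluated at the locus model's theta
    (the caller is responsible for that refit).  The models are not strictly
    nested, so F can be negative when the locus model fits worse; the upper
    tail p-value is still the relevant summary ("does the locus model
    explain significantly more variance").
    """
    if fit_mlh.nobs != fit_sl.nobs:
        raise ValueError("fits must share the same observations")
    df1 = fit_sl.n_coef - fit_mlh.n_coef
    if df1 <= 0:
        raise ValueError("single-locus model must have more parameters")
    df2 = fit_sl.df_resid
    if fit_mlh.family == "gaussian":
        num, den = fit_mlh.extra["rss"], fit_sl.extra["rss"]
    else:
        num, den = fit_mlh.deviance, fit_sl.deviance
    if den <= 0:
        raise ValueError("degenerate (zero) residual variance in locus model")
    f = ((num - den) / df1) / (den / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), int(df1), int(df2), p


def effect_sizes(fit_sl: FitResult, locus_names: list, z: float = 1.96) -> pd.DataFrame:
    """Partial-correlation effect size per locus coefficient, with 95% CI.

    r = t / sqrt(t^2 + df_resid); the interval is the Fisher z transform
    +- z / sqrt(n - 3), back-transformed.  A zero SE yields a flagged NaN row.
    """
    df = fit_sl.df_resid
    n = fit_sl.nobs
    rows = []
    for name in locus_names:
        beta, se = float(fit_sl.params[name]), float(fit_sl.bse[name])
        if se == 0:
            rows.append(
                {"locus": name, "r": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                 "status": "undefined"}
            )
            continue
        t = beta / se
        r = t / np.sqrt(t * t + df)
        zr = np.arctanh(r)
        half = z / np.sqrt(n - 3)
        rows.append(
            {
                "locus": name,
                "r": r,
                "ci_lo": np.tanh(zr - half),
                "ci_hi": np.tanh(zr + half),
                "status": "ok",
            }
        )
    return pd.DataFrame(rows).set_index("locus")


def sign_test(signs) -> tuple[int, int, float]:
    """Exact two-sided binomial test (p0 = 0.5) on effect-size signs.

    Zeros are excluded (logged).  p = min(1, 2 * min(P(X <= k), P(X >= k)))
    with k = number of positive signs among the nonzero ones.
    """
    signs = np.sign(np.asarray(signs, dtype=float))
    n_zero = int((signs == 0).sum())
    if n_zero:
        logger.info("sign test: excluding %d zero effect(s)", n_zero)
    nz = signs[signs != 0]
    if len(nz) == 0:
        raise ValueError("all effects are zero; sign test undefined")
    n_pos = int((nz > 0).sum())
    n = len(nz)
    lower = stats.binom.cdf(n_pos, n, 0.5)
    upper = stats.binom.sf(n_pos - 1, n, 0.5)
    p = min(1.0, 2.0 * min(lower, upper))
    return n_pos, n - n_pos, float(p)


def effect_vs_diversity(
    effects: pd.DataFrame, summaries: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r of locus effect size against n_alleles, Ho and He."""
    joined = effects.join(summaries[["n_alleles", "Ho", "He"]], how="inner")
    if len(joined) < 3:
        raise ValueError("need >= 3 loci")
    r_vals = joined["r"].to_numpy(dtype=float)
    rows = []
    for metric in ("n_alleles", "Ho", "He"):
        x = joined[metric].to_numpy(dtype=float)
        if np.std(r_vals) == 0 or np.std(x) == 0:
            rows.append({"metric": metric, "r": np.nan, "p": np.nan,
                         "status": "undefined"})
        else:
            r, p = stats.pearsonr(r_vals, x)
            rows.append({"metric": metric, "r": r, "p": p, "status": "ok"})
    return pd.DataFrame(rows).set_index("metric")


@dataclass
class SingleLocusReport:
    response: str
    effects: pd.DataFrame
    F: float
    df1: int
    df2: int
    p_value: float
    n_pos: int
    n_neg: int
    sign_p: float
    diversity_regressions: pd.DataFrame
    n_complete: int
    extra: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "response": self.response,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "sign_p": self.sign_p,
            "n_complete": self.n_complete,
        }


def run_single_locus_stage(
    top_spec: ModelSpec,
    data: pd.DataFrame,
    sl_matrix: pd.DataFrame,
    summaries: pd.DataFrame,
    genetic_term: str = "IR",
    id_column: str = "id",
) -> SingleLocusReport:
    """Full decomposition for one response.

    ``data`` must carry one row per individual (indexed or keyed by
    ``id_column``) including the response and covariates; ``sl_matrix`` is
    the complete-genotype binary heterozygosity matrix.  Both models are
    refit on the complete-genotype subset.
    """
    locus_names = list(sl_matrix.columns)
    if id_column in data.columns:
        sub = data.set_index(id_column)
    else:
        sub = data
    keep = sub.index.intersection(sl_matrix.index)
    sub = sub.loc[keep].copy()
    for name in locus_names:
        sub[name] = sl_matrix.loc[keep, name].astype(float)
    sl_spec = build_replacement_model(top_spec, locus_names, genetic_term)
    fit_sl = fit_model(sl_spec, sub)
    if top_spec.family == "negbin":
        # evaluate both deviances at the locus model's theta
        fit_mlh = refit_negbin_fixed_theta(top_spec, sub, fit_sl.dispersion)
    else:
        fit_mlh = fit_model(top_spec, sub)
    f, df1, df2, p = variance_explained_f_test(fit_mlh, fit_sl)
    eff = effect_sizes(fit_sl, locus_names)
    n_pos, n_neg, sign_p = sign_test(eff["r"].fillna(0.0).to_numpy())
    reg = effect_vs_diversity(eff, summaries)
    return SingleLocusReport(
        response=top_spec.response,
        effects=eff,
        F=f,
        df1=df1,
        df2=df2,
        p_value=p,
        n_pos=n_pos,
        n_neg=n_neg,
        sign_p=sign_p,
        diversity_regressions=reg,
        n_complete=len(sub),
        extra={"fit_sl": fit_sl, "fit_mlh": fit_mlh},
    )
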