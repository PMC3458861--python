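"""Model specifications and design-matrix encoding.

A :class:`ModelSpec` is parsed from a compact formula string such as::

    "replete_ticks ~ aggregation + food + month + IR + IR^2 + area"
    "lice ~ aggregation + age + sex + age*sex"

Term kinds are inferred from a ``categories`` mapping (column -> ordered
levels, first level = reference): listed columns are categorical
(treatment/dummy coded with the reference dropped), ``name^2`` is the
quadratic of a continuous term, ``a*b`` adds the products of the encoded
columns of ``a`` and ``b`` (main effects must be listed separately if
wanted), and anything else is continuous and passed through unchanged.

Continuous effect-size predictors are put on a common scale by 2-SD
standardization ((x - mean) / (2 sd), sample sd), which gives binary and
continuous coefficients comparable magnitudes.  A quadratic column is the
square of its (already standardized) base, itself re-standardized, so both
carry SD 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Term",
    "ModelSpec",
    "parse_model",
    "standardize_2sd",
    "DesignEncoder",
    "body_condition_residuals",
]


@dataclass(frozen=True)
class Term:
    """One model term; ``token`` is its appearance in the formula string."""

    token: str
    kind: str  # "categorical" | "continuous" | "quadratic" | "interaction"
    base: str | None = None  # quadratic: underlying continuous column
    parts: tuple = ()  # interaction: component tokens


@dataclass(frozen=True)
class ModelSpec:
    """A response, an error family, and an ordered list of terms."""

    response: str
    family: str  # "negbin" | "gaussian"
    terms: tuple
    categories: Mapping[str, Sequence[str]] = field(default_factory=dict, hash=False)

    def __post_init__(self):
        if self.family not in ("negbin", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        tokens = [t.token for t in self.terms]
        if len(set(tokens)) != len(tokens):
            raise ValueError(f"duplicate terms in model: {tokens}")
        # a quadratic needs its base *data column* at encoding time, not a
        # linear term in the model: purely curvilinear candidates are legal

    @property
    def label(self) -> str:
        return "+".join(t.token for t in self.terms) if self.terms else "intercept"

    def with_terms(self, extra_tokens: Sequence[str]) -> "ModelSpec":
        """Return a spec with additional terms appended (duplicates skipped)."""
        have = {t.token for t in self.terms}
        new = list(self.terms)
        for tok in extra_tokens:
            if tok not in have:
                new.append(_make_term(tok, self.categories))
                have.add(tok)
        return replace(self, terms=tuple(new))

    def without_terms(self, tokens: Sequence[str]) -> "ModelSpec":
        drop = set(tokens)
        return replace(self, terms=tuple(t for t in self.terms if t.token not in drop))


def _make_term(token: str, categories: Mapping) -> Term:
    token = token.strip()
    if "*" in token:
        parts = tuple(p.strip() for p in token.split("*"))
        if len(parts) != 2:
            raise ValueError(f"only two-way interactions supported: {token!r}")
        return Term(token, "interaction", parts=parts)
    if token.endswith("^2"):
        return Term(token, "quadratic", base=token[:-2])
    if token in categories:
        return Term(token, "categorical")
    return Term(token, "continuous")


def parse_model(formula: str, family: str, categories: Mapping | None = None) -> ModelSpec:
    """Parse ``"response ~ term + term + ..."`` into a :class:`ModelSpec`.

    ``"response ~ 1"`` (or an empty right side) gives an intercept-only model.
    """
    categories = dict(categories or {})
    if "~" not in formula:
        raise ValueError(f"formula needs '~': {formula!r}")
    lhs, _, rhs = formula.partition("~")
    response = lhs.strip()
    if not response:
        raise ValueError("empty response")
    tokens = [t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"]
    terms = tuple(_make_term(t, categories) for t in tokens)
    return ModelSpec(response, family, terms, categories)


def standardize_2sd(values) -> tuple[np.ndarray, float, float]:
    """Center and scale by twice the sample SD: out mean 0, SD 0.5.

    Returns ``(standardized, mean, sd)``; raises on zero variance.
    """
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("standardize_2sd requires >= 2 distinct values")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:  # distinct values can still underflow to zero variance
        raise ValueError("zero variance; cannot standardize")
    return (x - mean) / (2 * sd), mean, sd


class DesignEncoder:
    """Builds the design matrix for a :class:`ModelSpec`.

    ``fit`` records categorical levels (from the spec's ``categories`` or,
    if a column is unlisted there, the sorted observed values) and the
    mean/SD used for quadratic-column standardization, so ``transform`` on
    new data is consistent; an unseen categorical level then raises.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec

    def fit(self, df: pd.DataFrame) -> "DesignEncoder":
        self.levels_ = {}
        self.quad_scale_ = {}
        for t in self._expand_terms():
            if t.kind == "categorical":
                if t.token in self.spec.categories:
                    self.levels_[t.token] = list(self.spec.categories[t.token])
                else:
                    self.levels_[t.token] = sorted(df[t.token].astype(str).unique())
            elif t.kind == "quadratic":
                sq = df[t.base].to_numpy(dtype=float) ** 2
                _, mean, sd = standardize_2sd(sq)
                self.quad_scale_[t.token] = (mean, sd)
        return self

    def _expand_terms(self):
        """Terms plus any categorical parts referenced only via interactions."""
        seen = {t.token for t in self.spec.terms}
        out = list(self.spec.terms)
        for t in self.spec.terms:
            if t.kind == "interaction":
                for p in t.parts:
                    if p not in seen:
                        out.append(_make_term(p, self.spec.categories))
                        seen.add(p)
        return out

    def _encode_single(self, t: Term, df: pd.DataFrame) -> pd.DataFrame:
        if t.kind == "categorical":
            levels = self.levels_[t.token]
            vals = df[t.token].astype(str)
            unseen = set(vals.unique()) - set(levels)
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} for {t.token!r}")
            ref = levels[0]
            return pd.DataFrame(
                {
                    f"{t.token}[{lev}]": (vals == lev).astype(float).to_numpy()
                    for lev in levels
                    if lev != ref
                },
                index=df.index,
            )
        if t.kind == "continuous":
            return pd.DataFrame({t.token: df[t.token].astype(float)}, index=df.index)
        if t.kind == "quadratic":
            mean, sd = self.quad_scale_[t.token]
            sq = df[t.base].to_numpy(dtype=float) ** 2
            return pd.DataFrame({t.token: (sq - mean) / (2 * sd)}, index=df.index)
        raise AssertionError(t.kind)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        cols = [pd.DataFrame({"const": np.ones(len(df))}, index=df.index)]
        encoded = {}
        for t in self._expand_terms():
            if t.kind != "interaction":
                encoded[t.token] = self._encode_single(t, df)
        for t in self.spec.terms:
            if t.kind == "interaction":
                a, b = (encoded[p] for p in t.parts)
                inter = {}
                for ca in a.columns:
                    for cb in b.columns:
                        inter[f"{ca}*{cb}"] = a[ca].to_numpy() * b[cb].to_numpy()
                cols.append(pd.DataFrame(inter, index=df.index))
            else:
                cols.append(encoded[t.token])
        X = pd.concat(cols, axis=1)
        return X

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)


def body_condition_residuals(mass, size) -> np.ndarray:
    """OLS residuals of body mass regressed on body size (relative condition)."""
    mass = np.asarray(mass, dtype=float)
    size = np.asarray(size, dtype=float)
    if mass.shape != size.shape or mass.ndim != 1:
        raise ValueError("mass and size must be 1-D and paired")
    if len(mass) < 3:
        raise ValueError("need >= 3 individuals")
    if np.std(size) == 0:
        raise ValueError("zero variance in body size")
    X = np.column_stack([np.ones_like(size), size])
    beta, *_ = np.linalg.lstsq(X, mass, rcond=None)
    return mass - X @ beta
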