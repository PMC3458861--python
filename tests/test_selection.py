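import numpy as np
import pandas as pd
import pytest

from hfcpipe.design import parse_model
from hfcpipe.glm import FitResult
from hfcpipe.selection import (
    TwoStageAICcSelector,
    confidence_set,
    genetic_variants,
    model_average,
    rank_models,
    reference_parameters,
    stage_one,
    stage_two,
    write_averaged_table,
    write_ranking_table,
)
from hfcpipe.simulate import PAPERLIKE_CATEGORIES, paperlike_config, simulate_dataset


def fake_fit(label, k, llf, n=259, params=None, bse=None, family="negbin"):
    params = pd.Series(params or {}, dtype=float)
    bse = pd.Series(bse or {c: 0.0 for c in params.index}, dtype=float)
    return FitResult(label, family, params, bse, llf=llf, k=k, nobs=n,
                     deviance=0.0, df_resid=n - k + 1, dispersion=1.0, converged=True)


def fits_with_daicc(deltas, n=259, k=5):
    """Fabricate fits whose AICc values differ by the requested deltas."""
    # AICc = -2 llf + const(k, n); with equal k, llf = -(delta)/2 shifts AICc by delta
    return [
        fake_fit(f"m{i}", k, -200.0 - d / 2, n=n) for i, d in enumerate(deltas)
    ]


class TestRankModels:
    def test_single_candidate(self):
        r = rank_models([fake_fit("only", 3, -100.0)])
        assert r.loc[0, "dAICc"] == 0.0
        assert r.loc[0, "Wi"] == pytest.approx(1.0)
        assert r.loc[0, "Di"] == pytest.approx(1.0)

    def test_two_model_weights_closed_form(self):
        r = rank_models(fits_with_daicc([0.0, 2.0]))
        assert r["Wi"].tolist() == pytest.approx([0.7311, 0.2689], abs=5e-5)

    def test_evidence_ratio_formula(self):
        r = rank_models(fits_with_daicc([0.0, 0.74]))
        assert r.loc[1, "Di"] == pytest.approx(np.exp(0.37))
        assert round(float(r.loc[1, "Di"]), 2) == 1.45

    def test_weights_sum_to_one_and_di_monotone(self):
        r = rank_models(fits_with_daicc([0.0, 0.5, 1.7, 3.2, 9.0]))
        assert r["Wi"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(r["Di"]) >= 0).all()

    def test_tie_broken_by_smaller_k(self):
        a = fake_fit("big", 6, -200.0 - 1.0)   # same AICc arithmetic shift
        b = fake_fit("small", 5, -200.0 - 1.0)
        # craft llf so AICc ties exactly
        from hfcpipe.glm import aicc
        b.llf = -(aicc(a) - 2 * b.k - 2 * b.k * (b.k + 1) / (b.nobs - b.k - 1)) / 2
        r = rank_models([a, b])
        assert r.loc[0, "Model"] == "small"

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError, match="different n"):
            rank_models([fake_fit("a", 3, -10.0, n=100), fake_fit("b", 3, -10.0, n=99)])


class TestStages:
    def test_equivalent_candidates_all_shortlisted(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=80), "z": rng.normal(size=80)})
        df["y"] = 1 + 0.5 * df["x"] + rng.normal(size=80)
        specs = [
            parse_model("y ~ x + z", "gaussian"),
            parse_model("y ~ z + x", "gaussian"),
        ]
        ranking, shortlist, _ = stage_one(specs, df)
        assert len(shortlist) == 2

    def test_shortlist_boundary_inclusive(self):
        # a model at dAICc exactly 2.0 is kept
        fits = fits_with_daicc([0.0, 2.0, 2.1])
        r = rank_models(fits)
        kept = r[r["dAICc"] <= 2.0]
        assert len(kept) == 2

    def test_stage_two_expansion_count_and_labels(self):
        spec = parse_model(
            "y ~ aggregation + food + month", "negbin", PAPERLIKE_CATEGORIES
        )
        variants = genetic_variants(spec, "IR", "area")
        labels = [v.label for v in variants]
        assert len(variants) == 4
        assert "aggregation+food+month+area" in labels
        assert "aggregation+food+month+IR^2+area" in labels
        assert "aggregation+food+month+IR+IR^2+area" in labels

    def test_true_model_wins_stage_one_consistently(self):
        # data generated from one candidate's truth should rank it first
        rng = np.random.default_rng(42)
        wins = 0
        n_rep = 30
        for _ in range(n_rep):
            n = 500
            x = rng.normal(size=n)
            z = rng.normal(size=n)
            df = pd.DataFrame({"x": x, "z": z})
            df["y"] = 1 + 0.8 * x + 0.8 * z + rng.normal(size=n)
            specs = [
                parse_model("y ~ x + z", "gaussian"),
                parse_model("y ~ x", "gaussian"),
                parse_model("y ~ z", "gaussian"),
            ]
            ranking, _, _ = stage_one(specs, df)
            wins += ranking.loc[0, "Model"] == "x+z"
        assert wins / n_rep >= 0.9

    def test_quadratic_truth_ranks_quadratic_model_first(self, paperlike_dataset):
        # paperlike truth has a nonzero IR^2 effect on replete ticks
        del paperlike_dataset  # study-scale fixture not needed; use larger n
        from hfcpipe.simulate import recovery_experiment

        rep = recovery_experiment(n_replicates=10, n_individuals=1000, seed=5)
        assert rep["frac_genetic_top"] >= 0.9


class TestConfidenceSet:
    def test_dominant_first_model(self):
        r = rank_models(fits_with_daicc([0.0, 6.0]))  # weights ~0.95/0.05
        assert len(confidence_set(r, 0.90)) == 1

    def test_cumulative_prefix(self):
        deltas = [0.0, 2 * np.log(0.5 / 0.3), 2 * np.log(0.5 / 0.15), 2 * np.log(0.5 / 0.05)]
        r = rank_models(fits_with_daicc(deltas))
        assert np.allclose(r["Wi"], [0.5, 0.3, 0.15, 0.05], atol=1e-9)
        assert len(confidence_set(r, 0.90)) == 3

    def test_singleton(self):
        r = rank_models([fake_fit("m", 3, -5.0)])
        assert len(confidence_set(r)) == 1


class TestModelAverage:
    def test_singleton_set_returns_model_estimates(self):
        fit = fake_fit("m", 3, -5.0, params={"const": 1.0, "IR^2": -0.52},
                       bse={"const": 0.5, "IR^2": 0.25})
        r = rank_models([fit])
        avg = model_average({"m": fit}, confidence_set(r))
        assert avg.loc["IR^2", "beta"] == pytest.approx(-0.52)
        assert avg.loc["IR^2", "SE"] == pytest.approx(0.25)

    def test_unconditional_se_hand_case(self):
        # weights 0.6/0.4, beta 1/2, SE 0: SE_u = 0.6*0.4 + 0.4*0.6 = 0.48
        f1 = fake_fit("a", 3, 0.0, params={"b": 1.0}, bse={"b": 0.0})
        f2 = fake_fit("b", 3, 0.0, params={"b": 2.0}, bse={"b": 0.0})
        conf = pd.DataFrame({"Model": ["a", "b"], "Wi": [0.6, 0.4]})
        avg = model_average({"a": f1, "b": f2}, conf)
        assert avg.loc["b", "beta"] == pytest.approx(1.4)
        assert avg.loc["b", "SE"] == pytest.approx(0.48)

    def test_odds_ratio_mapping(self):
        fit = fake_fit("m", 3, -5.0, params={"IR^2": -0.52}, bse={"IR^2": 0.25})
        r = rank_models([fit])
        avg = model_average({"m": fit}, confidence_set(r))
        row = avg.loc["IR^2"]
        assert round(row.odds, 2) == 0.59
        assert round(row.odds_lo, 2) == 0.36
        assert round(row.odds_hi, 2) == 0.97

    def test_average_within_per_model_range(self):
        rng = np.random.default_rng(1)
        fits, labels = {}, []
        betas = rng.normal(size=5)
        for i, b in enumerate(betas):
            f = fake_fit(f"m{i}", 4, -100 - rng.random(), params={"p": b},
                         bse={"p": 0.1})
            fits[f.label] = f
            labels.append(f.label)
        r = rank_models(list(fits.values()))
        avg = model_average(fits, confidence_set(r, 1.0))
        assert betas.min() <= avg.loc["p", "beta"] <= betas.max()

    def test_shrinkage_option_pulls_toward_zero(self):
        f1 = fake_fit("a", 3, 0.0, params={"b": 1.0, "c": 1.0},
                      bse={"b": 0.1, "c": 0.1})
        f2 = fake_fit("b", 3, 0.0, params={"c": 1.0}, bse={"c": 0.1})
        conf = pd.DataFrame({"Model": ["a", "b"], "Wi": [0.5, 0.5]})
        natural = model_average({"a": f1, "b": f2}, conf)
        shrunk = model_average({"a": f1, "b": f2}, conf, shrink=True)
        assert natural.loc["b", "beta"] == pytest.approx(1.0)
        assert shrunk.loc["b", "beta"] == pytest.approx(0.5)


class TestWriters:
    def test_ranking_table_round_trip(self, tmp_path):
        r = rank_models(fits_with_daicc([0.0, 0.74, 1.69]))
        path = tmp_path / "rank.tsv"
        write_ranking_table(r, path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == ["Model", "k", "dAICc", "Wi", "Di", "logL"]
        assert len(back) == 3
        assert back["dAICc"].tolist() == [0.00, 0.74, 1.69]
        assert back.loc[0, "Di"] == 1.00  # top-row evidence ratio convention

    def test_averaged_table_reference_rows(self, tmp_path):
        fit = fake_fit("m", 3, -5.0, params={"sex[Male]": 0.31}, bse={"sex[Male]": 0.11})
        r = rank_models([fit])
        avg = model_average({"m": fit}, confidence_set(r))
        path = tmp_path / "avg.tsv"
        write_averaged_table(avg, path, reference_levels=["sex[Female]"])
        back = pd.read_csv(path, sep="\t", dtype=str)
        ref = back[back["Predictor"] == "sex[Female]"].iloc[0]
        assert ref["Beta"] == "0.00"
        assert ref["SE"] == "-"
        est = back[back["Predictor"] == "sex[Male]"].iloc[0]
        assert float(est["Beta"]) == 0.31

    def test_reference_parameters_from_specs(self):
        spec = parse_model("y ~ sex + month", "negbin", PAPERLIKE_CATEGORIES)
        refs = reference_parameters([spec])
        assert refs == ["sex[Female]", "month[April]"]


def test_selector_end_to_end_attributes():
    ds = simulate_dataset(paperlike_config(n_individuals=400, dropout=0.0), seed=77)
    sel = TwoStageAICcSelector(
        ["replete_ticks ~ aggregation + month", "replete_ticks ~ aggregation"],
        family="negbin",
        categories=PAPERLIKE_CATEGORIES,
    ).fit(ds.covariates)
    assert sel.ranking_["Wi"].sum() == pytest.approx(1.0, abs=1e-9)
    assert set(sel.confidence_set_["Model"]) <= set(sel.ranking_["Model"])
    assert "const" in sel.averaged_.index
    # sklearn-style parameter plumbing
    assert sel.get_params()["genetic_term"] == "IR"
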