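"""End-to-end orchestration: descriptives, diversity, selection, decomposition.

``run_full_analysis`` executes, in order: locus exclusion and min-typed
filtering, pooled allele frequencies, per-locus summaries with
Hardy-Weinberg tests and Bonferroni flags, the three diversity indices and
their correlations, per-response two-stage AICc selection with model
averaging, and — only when the top model for a response contains a genetic
term — the single-locus decomposition.  Every table is written as TSV under
the configured output directory together with a provenance record (config
hash, seed, package versions) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import body_condition_residuals
from .diversity import diversity_table, metric_correlations, single_locus_matrix
from .genotypes import (
    allele_frequencies,
    bonferroni_flag,
    filter_individuals,
    hwe_exact_test,
    locus_summaries,
    read_genepop,
    read_genotype_csv,
)
from .selection import (
    TwoStageAICcSelector,
    reference_parameters,
    write_averaged_table,
    write_ranking_table,
)
from .single_locus import run_single_locus_stage

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "RunReport", "parasite_descriptives", "run_full_analysis"]


@dataclass
class ResponseConfig:
    name: str
    family: str
    stage1: list

    def __post_init__(self):
        if self.family not in ("negbin", "gaussian"):
            raise ValueError(f"{self.name}: family must be negbin or gaussian")


@dataclass
class AnalysisConfig:
    genotypes: str
    covariates: str
    responses: list
    genotype_format: str = "csv"  # "csv" | "genepop"
    outcomes: str | None = None  # defaults to the covariates file
    presence: str | None = None
    categories: dict = field(default_factory=dict)
    min_typed: int = 12
    exclude_loci: list = field(default_factory=list)
    genetic_metric: str = "IR"
    area_term: str = "area"
    delta_threshold: float = 2.0
    conf_mass: float = 0.90
    hwe_permutations: int = 10000
    single_locus: bool = True
    outdir: str = "hfc_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["responses"] = [ResponseConfig(**r) for r in raw.get("responses", [])]
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid config {path}: {exc}") from exc

    def content_hash(self) -> str:
        blob = json.dumps(
            {k: (v if not isinstance(v, list) else [getattr(x, "__dict__", x) for x in v])
             for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    locus_summary: pd.DataFrame
    diversity: pd.DataFrame
    correlations: pd.DataFrame
    descriptives: pd.DataFrame
    selections: dict  # response -> TwoStageAICcSelector
    single_locus: dict  # response -> SingleLocusReport
    failures: dict
    provenance: dict


def parasite_descriptives(
    outcomes: pd.DataFrame, count_columns, presence: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Prevalence and mean abundance per count outcome, richness summaries,
    and per-taxon prevalence from a presence/absence matrix.

    Prevalence = fraction of hosts with count > 0 (or presence true); mean
    abundance averages over all hosts including zeros.
    """
    if outcomes.empty:
        raise ValueError("empty outcome table")
    rows = []
    for col in count_columns:
        y = outcomes[col].to_numpy(dtype=float)
        rows.append(
            {
                "outcome": col,
                "n": len(y),
                "prevalence": float((y > 0).mean()),
                "mean_abundance": float(y.mean()),
                "max": float(y.max()),
            }
        )
    if presence is not None and not presence.empty:
        richness = presence.sum(axis=1).to_numpy(dtype=float)
        rows.append(
            {
                "outcome": "endo_richness",
                "n": len(richness),
                "prevalence": float((richness > 0).mean()),
                "mean_abundance": float(richness.mean()),
                "max": float(richness.max()),
            }
        )
        for taxon in presence.columns:
            rows.append(
                {
                    "outcome": f"prevalence:{taxon}",
                    "n": len(presence),
                    "prevalence": float(presence[taxon].mean()),
                    "mean_abundance": float("nan"),
                    "max": float("nan"),
                }
            )
    return pd.DataFrame(rows).set_index("outcome")


def _read_genotypes(config: AnalysisConfig):
    if config.genotype_format == "genepop":
        return read_genepop(config.genotypes)
    if config.genotype_format == "csv":
        return read_genotype_csv(config.genotypes)
    raise ValueError(f"unknown genotype format {config.genotype_format!r}")


def run_full_analysis(config: AnalysisConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failures = {}

    table = _read_genotypes(config)
    if config.exclude_loci:
        table = table.drop_loci(config.exclude_loci)
    table = filter_individuals(table, min(config.min_typed, table.n_loci))

    freqs = allele_frequencies(table)
    summary = locus_summaries(table, freqs)
    hwe_seed = np.random.SeedSequence(config.seed).spawn(1)[0]
    hwe_rng = np.random.default_rng(hwe_seed)
    hwe_p = {}
    for locus in table.locus_names:
        res = hwe_exact_test(
            table, locus, n_permutations=config.hwe_permutations, seed=hwe_rng
        )
        hwe_p[locus] = res.p_value if res.status == "ok" else float("nan")
    summary["hwe_p"] = pd.Series(hwe_p)
    flags = bonferroni_flag(hwe_p, alpha=0.05)
    summary["hwe_flag"] = pd.Series(flags)
    summary.to_csv(outdir / "locus_summary.tsv", sep="\t")

    div = diversity_table(table, freqs)
    div.to_csv(outdir / "diversity.tsv", sep="\t")
    corr = metric_correlations(div)
    corr.to_csv(outdir / "metric_correlations.tsv", sep="\t")

    cov = pd.read_csv(config.covariates, sep="\t", dtype=str)
    outcomes = (
        pd.read_csv(config.outcomes, sep="\t")
        if config.outcomes
        else cov.copy()
    )
    presence = (
        pd.read_csv(config.presence, sep="\t", index_col=0)
        if config.presence
        else None
    )
    if "capture_event" in cov.columns:
        # first capture only, one record per host
        cov = cov.sort_values("capture_event").drop_duplicates("id", keep="first")
    if {"body_mass", "body_size"} <= set(cov.columns):
        cov["condition"] = body_condition_residuals(
            cov["body_mass"].astype(float), cov["body_size"].astype(float)
        )

    count_cols = [r.name for r in config.responses if r.family == "negbin"]
    have_counts = [c for c in count_cols if c in outcomes.columns]
    descr = parasite_descriptives(outcomes, have_counts, presence)
    descr.to_csv(outdir / "descriptives.tsv", sep="\t")

    from .simulate import attach_diversity  # shared standardization path

    metric = config.genetic_metric
    data = attach_diversity(cov, div, metric=metric)
    num_candidates = [r.name for r in config.responses]
    for col in num_candidates:
        if col in outcomes.columns and col not in data.columns:
            merged = outcomes[["id", col]] if "id" in outcomes.columns else outcomes[[col]]
            if "id" in outcomes.columns:
                data = data.merge(merged, on="id", how="inner")
            else:
                data[col] = outcomes[col].to_numpy()
    selections, single = {}, {}
    sl_matrix = single_locus_matrix(table)
    for resp in config.responses:
        if resp.name not in data.columns:
            failures[resp.name] = "response column missing"
            continue
        sub = data.dropna(subset=[resp.name]).copy()
        sub[resp.name] = pd.to_numeric(sub[resp.name])
        try:
            sel = TwoStageAICcSelector(
                resp.stage1,
                family=resp.family,
                categories=config.categories,
                genetic_term=metric,
                area_term=config.area_term,
                delta_threshold=config.delta_threshold,
                conf_mass=config.conf_mass,
            ).fit(sub)
        except Exception as exc:  # noqa: BLE001 - partial report, recorded
            logger.error("selection failed for %s: %s", resp.name, exc)
            failures[resp.name] = str(exc)
            continue
        selections[resp.name] = sel
        write_ranking_table(sel.stage1_ranking_, outdir / f"{resp.name}_stage1.tsv")
        write_ranking_table(sel.ranking_, outdir / f"{resp.name}_stage2.tsv")
        conf_specs = [sel.fits_[m].spec for m in sel.confidence_set_["Model"]]
        write_averaged_table(
            sel.averaged_.drop(index="const", errors="ignore"),
            outdir / f"{resp.name}_averaged.tsv",
            reference_levels=reference_parameters(conf_specs),
        )
        if config.single_locus and sel.genetic_in_top_:
            try:
                rep = run_single_locus_stage(
                    sel.top_spec_, sub, sl_matrix, summary, genetic_term=metric
                )
            except Exception as exc:  # noqa: BLE001
                failures[f"{resp.name}:single_locus"] = str(exc)
                continue
            single[resp.name] = rep
            rep.effects.to_csv(outdir / f"{resp.name}_single_locus.tsv", sep="\t")
            with open(outdir / f"{resp.name}_single_locus.json", "w") as fh:
                json.dump(rep.summary_dict(), fh, indent=2)

    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "hfcpipe_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_individuals": table.n_individuals,
        "n_loci": table.n_loci,
        "failures": failures,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return RunReport(
        locus_summary=summary,
        diversity=div,
        correlations=corr,
        descriptives=descr,
        selections=selections,
        single_locus=single,
        failures=failures,
        provenance=provenance,
    )
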