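"""Per-individual genetic diversity indices for HFC analyses.

Three standard indices are computed from a genotype table and pooled allele
frequencies:

* **sMLH** (standardized multilocus heterozygosity): the individual's
  heterozygous-locus count divided by the summed population observed
  heterozygosity of the loci it was typed at,
  ``sMLH = sum_l h_il / sum_l H_l``.  Population mean is ~1 by construction
  and the index controls for how many loci were typed.
* **IR** (internal relatedness): ``IR = (2H - sum f_i) / (2N - sum f_i)``
  where ``H`` is the number of homozygous typed loci, ``N`` the typed-locus
  count and ``sum f_i`` the summed population frequencies of all ``2N``
  allele copies carried (a homozygote contributes its allele's frequency
  twice).  Homozygosity for rare alleles is up-weighted; range [-1, 1].
* **HL** (homozygosity by locus): ``HL = sum_h E_h / (sum_h E_h + sum_j E_j)``
  summing plug-in expected heterozygosities ``E = 1 - sum p^2`` over
  homozygous (h) and heterozygous (j) typed loci; range [0, 1] with more
  variable loci weighted more heavily.

The three indices are strongly (anti-)correlated in practice; pairwise
Pearson correlations are provided so an analysis can pick one and avoid
pseudoreplication.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeTable, allele_frequencies

__all__ = [
    "compute_smlh",
    "compute_ir",
    "compute_hl",
    "diversity_table",
    "metric_correlations",
    "single_locus_matrix",
]


def compute_smlh(het: np.ndarray, typed: np.ndarray, locus_ho: np.ndarray) -> float:
    """sMLH for one individual.

    Parameters are per-locus vectors: ``het`` (bool, heterozygous), ``typed``
    (bool, call present) and ``locus_ho`` (population observed
    heterozygosity per locus).
    """
    typed = np.asarray(typed, dtype=bool)
    if typed.sum() == 0:
        raise ValueError("individual typed at zero loci")
    denom = float(np.asarray(locus_ho)[typed].sum())
    if denom == 0:
        raise ValueError("sum of locus heterozygosities is zero; sMLH undefined")
    return float(np.asarray(het, dtype=float)[typed].sum()) / denom


def compute_ir(calls: np.ndarray, freqs: dict, locus_names) -> float:
    """Internal relatedness for one individual (calls: (n_loci, 2) array)."""
    typed = calls[:, 0] != MISSING
    n = int(typed.sum())
    if n == 0:
        raise ValueError("individual typed at zero loci")
    hom = 0
    fsum = 0.0
    for j in np.flatnonzero(typed):
        a1, a2 = int(calls[j, 0]), int(calls[j, 1])
        f = freqs[locus_names[j]]["freqs"]
        # .get: under leave-one-out pooling a private allele can vanish
        # from the pool entirely (frequency 0)
        fsum += f.get(a1, 0.0) + f.get(a2, 0.0)
        if a1 == a2:
            hom += 1
    denom = 2 * n - fsum
    if denom <= 0:
        raise ValueError("IR denominator non-positive; degenerate frequencies")
    return (2 * hom - fsum) / denom


def compute_hl(het: np.ndarray, typed: np.ndarray, locus_e: np.ndarray) -> float:
    """Homozygosity by locus for one individual.

    ``locus_e`` holds plug-in expected heterozygosities ``1 - sum p^2``.
    Monomorphic loci (E = 0) contribute nothing; if every typed locus is
    monomorphic the index is undefined and NaN is returned.
    """
    typed = np.asarray(typed, dtype=bool)
    if typed.sum() == 0:
        raise ValueError("individual typed at zero loci")
    het = np.asarray(het, dtype=bool)
    e = np.asarray(locus_e, dtype=float)
    e_hom = float(e[typed & ~het].sum())
    e_het = float(e[typed & het].sum())
    if e_hom + e_het == 0:
        return float("nan")
    return e_hom / (e_hom + e_het)


def _plugin_e(freqs: dict, locus_names) -> np.ndarray:
    return np.array(
        [1.0 - sum(p * p for p in freqs[name]["freqs"].values()) for name in locus_names]
    )


def _leave_one_out_freqs(table: GenotypeTable, freqs: dict, i: int) -> dict:
    """Recompute pooled frequencies with individual ``i``'s copies removed."""
    out = {}
    for j, name in enumerate(table.locus_names):
        entry = freqs[name]
        n, f = entry["n_typed"], dict(entry["freqs"])
        a1, a2 = table.calls[i, j]
        if a1 == MISSING:
            out[name] = entry
            continue
        total = 2 * n
        counts = {a: p * total for a, p in f.items()}
        counts[int(a1)] -= 1
        counts[int(a2)] -= 1
        new_total = total - 2
        if new_total <= 0:
            raise ValueError(f"locus {name}: leave-one-out leaves no allele copies")
        out[name] = {
            "freqs": {a: c / new_total for a, c in counts.items() if c > 1e-9},
            "n_typed": n - 1,
        }
    return out


def diversity_table(
    table: GenotypeTable, freqs: dict | None = None, leave_one_out: bool = False
) -> pd.DataFrame:
    """One row per individual: n_typed, sMLH, IR, HL.

    ``leave_one_out=True`` recomputes IR with the focal individual's allele
    copies excluded from the frequency pool (sensitivity analysis); by
    default the pooled frequencies include the focal individual.
    """
    if freqs is None:
        freqs = allele_frequencies(table)
    het = table.heterozygous_mask()
    typed = table.typed_mask()
    locus_ho = het.sum(axis=0) / np.maximum(typed.sum(axis=0), 1)
    locus_e = _plugin_e(freqs, table.locus_names)
    rows = []
    for i, ind in enumerate(table.individuals):
        f_i = _leave_one_out_freqs(table, freqs, i) if leave_one_out else freqs
        rows.append(
            {
                "id": ind,
                "n_typed": int(typed[i].sum()),
                "sMLH": compute_smlh(het[i], typed[i], locus_ho),
                "IR": compute_ir(table.calls[i], f_i, table.locus_names),
                "HL": compute_hl(het[i], typed[i], locus_e),
            }
        )
    return pd.DataFrame(rows).set_index("id")


def metric_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r (with two-sided t p-values) among sMLH, IR, HL.

    A metric with zero variance yields NaN r and status ``"undefined"``.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 records for correlations")
    pairs = [("sMLH", "IR"), ("IR", "HL"), ("HL", "sMLH")]
    rows = []
    for a, b in pairs:
        x, y = records[a].to_numpy(), records[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"pair": f"{a}-{b}", "r": np.nan, "p": np.nan, "status": "undefined"})
        else:
            r, p = stats.pearsonr(x, y)
            rows.append({"pair": f"{a}-{b}", "r": r, "p": p, "status": "ok"})
    return pd.DataFrame(rows).set_index("pair")


def single_locus_matrix(table: GenotypeTable) -> pd.DataFrame:
    """Binary individuals x loci heterozygosity matrix (1 = heterozygous).

    Restricted to individuals with complete genotypes: single-locus
    replacement models require every locus observed on every row.
    """
    complete = table.n_typed() == table.n_loci
    het = table.heterozygous_mask()[complete].astype(int)
    ids = [ind for ind, c in zip(table.individuals, complete) if c]
    return pd.DataFrame(het, index=pd.Index(ids, name="id"), columns=table.locus_names)
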