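"""Codominant multilocus genotype tables: parsing, validation and summaries.

Genotypes are unordered diploid allele pairs at microsatellite loci, with
allele labels conventionally given as fragment lengths.  Two on-disk dialects
are supported: GenePop (title line, locus names, POP blocks, fixed-width
2- or 3-digit allele codes with ``00``/``000`` marking missing data) and a
wide CSV with an ``id`` column and two columns per locus (``<locus>_1``,
``<locus>_2``).

The module also provides allele frequencies pooled over all individuals,
per-locus diversity summaries (observed and unbiased expected
heterozygosity), a Monte-Carlo exact test for Hardy-Weinberg equilibrium
oriented toward heterozygote deficit, and Bonferroni flagging of the
resulting p-values.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing allele in the internal call array
MISSING = -1


class GenotypeParseError(ValueError):
    """Malformed genotype input; message names the offending line/row."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus and the set of allele labels observed at it."""

    name: str
    alleles: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.name:
            raise ValueError("locus name must be non-empty")


class GenotypeTable:
    """Individuals x loci matrix of unordered diploid allele pairs.

    Parameters
    ----------
    individuals : sequence of str
        Unique individual identifiers, order preserved.
    loci : sequence of LocusDef
        Locus definitions; names must be unique.
    calls : ndarray of shape (n_individuals, n_loci, 2)
        Integer allele labels; both entries ``MISSING`` for an untyped call.
        Pairs are stored sorted so (a, b) and (b, a) compare equal.
    site : sequence of str, optional
        Per-individual site/population label (e.g. a GenePop POP block).
    """

    def __init__(self, individuals, loci, calls, site=None):
        self.individuals = list(individuals)
        if len(set(self.individuals)) != len(self.individuals):
            dupes = sorted({i for i in self.individuals if self.individuals.count(i) > 1})
            raise GenotypeParseError(f"duplicate individual id(s): {dupes}")
        self.loci = list(loci)
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise GenotypeParseError("duplicate locus names in panel")
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        # demote half-missing calls, sort pairs so unordered pairs are canonical
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            logger.warning("%d half-missing calls demoted to missing", int(half.sum()))
            calls[half] = MISSING
        calls = np.sort(calls, axis=2)
        self.calls = calls
        self.site = list(site) if site is not None else None
        if self.site is not None and len(self.site) != len(self.individuals):
            raise ValueError("site labels must match number of individuals")
        self._validate_alleles()

    def _validate_alleles(self):
        for j, locus in enumerate(self.loci):
            observed = self.calls[:, j, :]
            observed = set(observed[observed != MISSING].tolist())
            if locus.alleles and not observed <= set(locus.alleles):
                bad = sorted(observed - set(locus.alleles))
                raise GenotypeParseError(
                    f"locus {locus.name}: allele(s) {bad} not in declared allele set"
                )

    # -- basic derived quantities -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list:
        return [l.name for l in self.loci]

    def typed_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): call present."""
        return self.calls[:, :, 0] != MISSING

    def n_typed(self) -> np.ndarray:
        """Typed-locus count per individual."""
        return self.typed_mask().sum(axis=1)

    def heterozygous_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): typed and heterozygous."""
        return self.typed_mask() & (self.calls[:, :, 0] != self.calls[:, :, 1])

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeTable(
            [self.individuals[i] for i in idx],
            self.loci,
            self.calls[idx].copy(),
            site=[self.site[i] for i in idx] if self.site is not None else None,
        )

    def drop_loci(self, names: Iterable[str]) -> "GenotypeTable":
        drop = set(names)
        missing = drop - set(self.locus_names)
        if missing:
            raise KeyError(f"cannot drop unknown loci: {sorted(missing)}")
        keep = [j for j, l in enumerate(self.loci) if l.name not in drop]
        return GenotypeTable(
            self.individuals,
            [self.loci[j] for j in keep],
            self.calls[:, keep].copy(),
            site=self.site,
        )

    def __eq__(self, other):
        return (
            isinstance(other, GenotypeTable)
            and self.individuals == other.individuals
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
        )


def _table_from_records(ids, locus_names, rows, sites=None):
    calls = np.asarray(rows, dtype=np.int64)
    loci = []
    for j, name in enumerate(locus_names):
        observed = calls[:, j, :] if len(calls) else np.empty((0, 2), dtype=np.int64)
        alleles = frozenset(int(a) for a in np.unique(observed) if a != MISSING)
        loci.append(LocusDef(name, alleles))
    return GenotypeTable(ids, loci, calls, site=sites)


# -- GenePop dialect ---------------------------------------------------------------


def read_genepop(path) -> GenotypeTable:
    """Read a GenePop file into a :class:`GenotypeTable`.

    Locus names may be comma-separated on one line or one per line.  Allele
    codes are fixed-width 2 or 3 digits; ``00``/``000`` is missing.  POP block
    membership is recorded as a per-individual site label (``pop1``, ...).
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    if not lines:
        raise GenotypeParseError("empty GenePop file")
    header, body = lines[0], lines[1:]
    locus_names: list = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        chunk = body[i].strip()
        if chunk:
            locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        i += 1
    if i == len(body):
        raise GenotypeParseError("no POP separator found")
    ids, rows, sites = [], [], []
    pop_idx = 0
    for lineno, line in enumerate(body[i:], start=i + 2):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.upper() == "POP":
            pop_idx += 1
            continue
        if pop_idx == 0:
            raise GenotypeParseError(f"line {lineno}: individual before first POP")
        if "," not in stripped:
            raise GenotypeParseError(f"line {lineno}: expected 'id , genotypes'")
        ind_id, _, geno = stripped.partition(",")
        ind_id = ind_id.strip()
        tokens = geno.split()
        if len(tokens) != len(locus_names):
            raise GenotypeParseError(
                f"line {lineno}: {len(tokens)} genotypes for {len(locus_names)} loci"
            )
        row = []
        for tok, locus in zip(tokens, locus_names):
            if len(tok) == 4:
                w = 2
            elif len(tok) == 6:
                w = 3
            else:
                raise GenotypeParseError(
                    f"line {lineno}: malformed allele code {tok!r} at locus {locus}"
                )
            if not tok.isdigit():
                raise GenotypeParseError(
                    f"line {lineno}: malformed allele code {tok!r} at locus {locus}"
                )
            a1, a2 = int(tok[:w]), int(tok[w:])
            row.append([a1 if a1 else MISSING, a2 if a2 else MISSING])
        ids.append(ind_id)
        rows.append(row)
        sites.append(f"pop{pop_idx}")
    if not ids:
        raise GenotypeParseError("GenePop file contains no individuals")
    return _table_from_records(ids, locus_names, rows, sites)


def write_genepop(table: GenotypeTable, path, title="hfcpipe export", digits=3) -> None:
    """Write a table in the GenePop dialect, one POP block per site label."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    maxa = int(table.calls.max(initial=0))
    if maxa >= 10 ** digits:
        raise ValueError(f"allele label {maxa} does not fit in {digits} digits")
    out = io.StringIO()
    out.write(title + "\n")
    for name in table.locus_names:
        out.write(name + "\n")
    sites = table.site if table.site is not None else ["pop1"] * table.n_individuals
    current = None
    for i, ind in enumerate(table.individuals):
        if sites[i] != current:
            out.write("POP\n")
            current = sites[i]
        codes = []
        for j in range(table.n_loci):
            a1, a2 = table.calls[i, j]
            a1 = 0 if a1 == MISSING else int(a1)
            a2 = 0 if a2 == MISSING else int(a2)
            codes.append(f"{a1:0{digits}d}{a2:0{digits}d}")
        out.write(f"{ind} , " + " ".join(codes) + "\n")
    if hasattr(path, "write"):
        path.write(out.getvalue())
    else:
        with open(path, "w") as fh:
            fh.write(out.getvalue())


# -- two-columns-per-locus CSV dialect ---------------------------------------------


def read_genotype_csv(path, id_column="id") -> GenotypeTable:
    """Read the wide CSV dialect (``id`` plus ``<locus>_1``/``<locus>_2`` pairs).

    Empty or NA cells mark missing alleles; a call with exactly one missing
    allele is demoted to fully missing (logged by the table constructor).
    """
    df = pd.read_csv(path, dtype={id_column: str})
    if id_column not in df.columns:
        raise GenotypeParseError(f"CSV lacks id column {id_column!r}")
    allele_cols = [c for c in df.columns if c != id_column and c != "site"]
    if len(allele_cols) % 2:
        raise GenotypeParseError(f"odd number of allele columns ({len(allele_cols)})")
    locus_names = []
    for c1, c2 in zip(allele_cols[::2], allele_cols[1::2]):
        m1, m2 = re.fullmatch(r"(.+)_1", c1), re.fullmatch(r"(.+)_2", c2)
        if not (m1 and m2 and m1.group(1) == m2.group(1)):
            raise GenotypeParseError(f"columns {c1!r}, {c2!r} are not a <locus>_1/_2 pair")
        locus_names.append(m1.group(1))
    vals = df[allele_cols].to_numpy(dtype=float)
    vals = np.where(np.isnan(vals), MISSING, vals).astype(np.int64)
    rows = vals.reshape(len(df), len(locus_names), 2)
    sites = df["site"].astype(str).tolist() if "site" in df.columns else None
    return _table_from_records(df[id_column].tolist(), locus_names, rows, sites)


def write_genotype_csv(table: GenotypeTable, path) -> None:
    data = {"id": table.individuals}
    if table.site is not None:
        data["site"] = table.site
    for j, name in enumerate(table.locus_names):
        for a in (0, 1):
            col = table.calls[:, j, a].astype(object)
            data[f"{name}_{a + 1}"] = [None if v == MISSING else int(v) for v in col]
    pd.DataFrame(data).to_csv(path, index=False)


# -- filtering and summaries -------------------------------------------------------


def filter_individuals(table: GenotypeTable, min_typed: int) -> GenotypeTable:
    """Retain individuals typed at >= ``min_typed`` loci, order preserved."""
    if not 0 <= min_typed <= table.n_loci:
        raise ValueError(f"min_typed must be in [0, {table.n_loci}]")
    return table.subset_individuals(table.n_typed() >= min_typed)


def allele_frequencies(table: GenotypeTable) -> dict:
    """Pooled allele frequencies per locus.

    Returns ``{locus: {"freqs": {allele: freq}, "n_typed": n}}`` with
    frequency = allele count / (2 * n_typed); missing calls are excluded.
    """
    if table.n_individuals == 0:
        raise ValueError("empty genotype table")
    out = {}
    for j, locus in enumerate(table.loci):
        col = table.calls[:, j, :]
        typed = col[col[:, 0] != MISSING]
        if len(typed) == 0:
            raise ValueError(f"locus {locus.name}: zero typed individuals")
        alleles, counts = np.unique(typed.ravel(), return_counts=True)
        total = counts.sum()
        out[locus.name] = {
            "freqs": {int(a): c / total for a, c in zip(alleles, counts)},
            "n_typed": len(typed),
        }
    return out


def expected_heterozygosity(freqs: Mapping[int, float], n_typed=None) -> float:
    """Expected heterozygosity 1 - sum(p^2); unbiased (2n/(2n-1)) if n given."""
    h = 1.0 - sum(p * p for p in freqs.values())
    if n_typed is not None:
        n2 = 2 * n_typed
        h *= n2 / (n2 - 1)
    return h


def locus_summaries(table: GenotypeTable, freqs=None) -> pd.DataFrame:
    """Per-locus diversity summary: n_typed, n_alleles, Ho, He (unbiased)."""
    if freqs is None:
        freqs = allele_frequencies(table)
    rows = []
    het = table.heterozygous_mask()
    typed = table.typed_mask()
    for j, locus in enumerate(table.loci):
        f = freqs[locus.name]
        n = f["n_typed"]
        ho = het[:, j].sum() / typed[:, j].sum()
        rows.append(
            {
                "locus": locus.name,
                "n_typed": n,
                "n_alleles": len(f["freqs"]),
                "Ho": ho,
                "He": expected_heterozygosity(f["freqs"], n_typed=n),
            }
        )
    return pd.DataFrame(rows).set_index("locus")


# -- Hardy-Weinberg ---------------------------------------------------------------


@dataclass
class HWEResult:
    locus: str
    p_value: float | None
    observed_het: int | None
    n_typed: int | None
    status: str  # "ok" or "not_testable"
    alternative: str = "deficit"


def hwe_exact_test(
    table: GenotypeTable,
    locus: str,
    n_permutations: int = 10000,
    seed=None,
    alternative: str = "deficit",
    randomized: bool = False,
    min_typed: int = 5,
) -> HWEResult:
    """Monte-Carlo exact HWE test by shuffling observed alleles into pairs.

    The default alternative is one-sided toward heterozygote deficit:
    p = (1 + #{permutations with het count <= observed}) / (n_permutations + 1).
    ``alternative="excess"`` flips the tail; ``"two-sided"`` doubles the
    smaller corrected tail (capped at 1).  Fewer than ``min_typed`` typed
    individuals (default 5) or a monomorphic locus yields status
    ``"not_testable"`` instead of a p-value; lower ``min_typed`` only for
    validation against exhaustive enumeration on tiny cases.

    The reported p with the +1 correction is valid but (necessarily)
    conservative on the discrete heterozygote-count support.
    ``randomized=True`` instead returns the randomized (mid-) Monte-Carlo
    p-value, exactly Uniform(0,1) under the null — the right variant for
    calibration studies, not for reporting.
    """
    if alternative not in ("deficit", "excess", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if n_permutations < 1000:
        raise ValueError("n_permutations must be >= 1000")
    try:
        j = table.locus_names.index(locus)
    except ValueError:
        raise KeyError(f"unknown locus {locus!r}") from None
    col = table.calls[:, j, :]
    typed = col[col[:, 0] != MISSING]
    n = len(typed)
    alleles = typed.ravel()
    if n < min_typed or len(np.unique(alleles)) < 2:
        return HWEResult(locus, None, None, n, "not_testable", alternative)
    obs_het = int((typed[:, 0] != typed[:, 1]).sum())
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(alleles, (n_permutations, 1)), axis=1)
    het_counts = (perms[:, 0::2] != perms[:, 1::2]).sum(axis=1)
    if randomized:
        u = rng.random()
        n_eq = int((het_counts == obs_het).sum())
        p_def = (int((het_counts < obs_het).sum()) + u * (n_eq + 1)) / (
            n_permutations + 1
        )
        p_exc = (int((het_counts > obs_het).sum()) + u * (n_eq + 1)) / (
            n_permutations + 1
        )
    else:
        p_def = (1 + int((het_counts <= obs_het).sum())) / (n_permutations + 1)
        p_exc = (1 + int((het_counts >= obs_het).sum())) / (n_permutations + 1)
    if alternative == "deficit":
        p = p_def
    elif alternative == "excess":
        p = p_exc
    else:
        p = min(1.0, 2.0 * min(p_def, p_exc))
    return HWEResult(locus, p, obs_het, n, "ok", alternative)


def bonferroni_flag(p_values: Mapping[str, float], alpha: float = 0.05) -> dict:
    """Flag tests with p < alpha / n_tests (Bonferroni); NaN/None never flagged."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    valid = {k: p for k, p in p_values.items() if p is not None and not np.isnan(p)}
    n = len(valid)
    return {
        k: (p is not None and not np.isnan(p) and p < alpha / n) if n else False
        for k, p in p_values.items()
    }
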