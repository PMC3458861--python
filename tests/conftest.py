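import numpy as np
import pytest

from hfcpipe.genotypes import GenotypeTable, LocusDef, MISSING, allele_frequencies
from hfcpipe.simulate import paperlike_config, simulate_dataset, simulate_frequencies


def make_table(calls, ids=None, locus_names=None, site=None):
    """Build a GenotypeTable from a nested list of (a1, a2) pairs or None."""
    n = len(calls)
    n_loci = len(calls[0])
    arr = np.full((n, n_loci, 2), MISSING, dtype=np.int64)
    for i, row in enumerate(calls):
        for j, pair in enumerate(row):
            if pair is not None:
                arr[i, j] = pair
    ids = ids or [f"ind{i + 1}" for i in range(n)]
    locus_names = locus_names or [f"L{j + 1}" for j in range(n_loci)]
    loci = []
    for j, name in enumerate(locus_names):
        observed = arr[:, j, :]
        loci.append(
            LocusDef(name, frozenset(int(a) for a in np.unique(observed) if a != MISSING))
        )
    return GenotypeTable(ids, loci, arr, site=site)


@pytest.fixture(scope="session")
def paper_panel():
    """Outbred (F = 0) panel at study scale: 380 hosts, 14 loci, no dropout."""
    from hfcpipe.simulate import simulate_genotypes

    cfg = paperlike_config()
    ss = np.random.SeedSequence(2024)
    freqs = simulate_frequencies(cfg, ss.spawn(1)[0])
    table = simulate_genotypes(freqs, np.zeros(380), seed=2024, dropout=0.0)
    return table, allele_frequencies(table)


@pytest.fixture(scope="session")
def paperlike_dataset():
    """One full synthetic dataset at the default (study-scale) configuration."""
    return simulate_dataset(paperlike_config(), seed=42)
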