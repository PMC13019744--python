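import numpy as np
import pytest

from rohscan.panel import GenotypePanel, SnpRecord


def make_panel(
    calls,
    positions=None,
    chromosomes=None,
    individual_ids=None,
    spacing=1000,
):
    """Build a small panel from a 2-D array of genotype codes.

    ``positions``/``chromosomes`` default to one chromosome "1" with
    evenly spaced markers.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_snps = calls.shape
    if positions is None:
        positions = [1 + j * spacing for j in range(n_snps)]
    if chromosomes is None:
        chromosomes = ["1"] * n_snps
    if individual_ids is None:
        individual_ids = [f"ind_{i + 1}" for i in range(n_ind)]
    snps = [
        SnpRecord(f"snp_{j + 1}", str(chromosomes[j]), int(positions[j]))
        for j in range(n_snps)
    ]
    return GenotypePanel(list(individual_ids), snps, calls)


@pytest.fixture
def panel_factory():
    return make_panel


def random_panel(rng, n_ind, n_snps, hom_bias=0.75, missing_rate=0.02, n_chrom=1,
                 max_gap=None, spacing_mean=20_000):
    """Random panel used by the oracle-equivalence tests.

    ``hom_bias`` is the probability mass on homozygous states, so runs of
    homozygosity actually occur at small n.
    """
    p_hom = hom_bias / 2
    codes = rng.choice(
        [0, 1, 2, 3],
        size=(n_ind, n_snps),
        p=[p_hom, 1 - hom_bias - missing_rate, p_hom, missing_rate],
    )
    boundaries = np.sort(rng.choice(np.arange(1, n_snps), size=n_chrom - 1, replace=False)) if n_chrom > 1 else []
    chroms = np.empty(n_snps, dtype=object)
    start = 0
    for c, b in enumerate(list(boundaries) + [n_snps]):
        chroms[start:b] = str(c + 1)
        start = b
    positions = np.empty(n_snps, dtype=np.int64)
    start = 0
    for c in range(n_chrom):
        block = chroms == str(c + 1)
        gaps = rng.exponential(spacing_mean, size=block.sum()).astype(np.int64) + 1
        positions[block] = np.cumsum(gaps)
        start += block.sum()
    return make_panel(codes, positions=positions, chromosomes=chroms)
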