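"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the HWE oracle uses
exact rational arithmetic, and the ROH oracle enumerates every SNP
interval and keeps maximal intervals satisfying the final constraints,
recomputing the windowed in-run mask with naive per-window loops.
"""

from fractions import Fraction
from math import comb, factorial

import numpy as np

HOM_A, HET, HOM_B, MISSING = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# exact HWE distribution (Levene–Haldane) in rational arithmetic
# ---------------------------------------------------------------------------
def hwe_distribution_exact(n_hom_a: int, n_het: int, n_hom_b: int) -> dict[int, Fraction]:
    """P(heterozygote count = h | allele counts) for every compatible h."""
    n = n_hom_a + n_het + n_hom_b
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    denom = comb(2 * n, n_a)
    out: dict[int, Fraction] = {}
    for h in range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2):
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        out[h] = Fraction(
            factorial(n) * 2**h, factorial(a) * factorial(h) * factorial(b)
        ) / denom
    return out


def hwe_p_exact(n_hom_a: int, n_het: int, n_hom_b: int) -> Fraction:
    dist = hwe_distribution_exact(n_hom_a, n_het, n_hom_b)
    p_obs = dist[n_het]
    return sum((p for p in dist.values() if p <= p_obs), Fraction(0))


# ---------------------------------------------------------------------------
# exhaustive-interval ROH oracle
# ---------------------------------------------------------------------------
def window_mask_bruteforce(
    calls_row: np.ndarray,
    window_snps: int,
    max_het: int,
    max_missing: int,
    threshold: float,
) -> np.ndarray:
    """Per-SNP in-run mask from naive per-window counting."""
    m = len(calls_row)
    w = window_snps
    n_win = m - w + 1
    mask = np.zeros(m, dtype=bool)
    if n_win <= 0:
        return mask
    win_ok = [
        ((calls_row[k : k + w] == HET).sum() <= max_het)
        and ((calls_row[k : k + w] == MISSING).sum() <= max_missing)
        for k in range(n_win)
    ]
    for j in range(m):
        ks = [k for k in range(n_win) if k <= j <= k + w - 1]
        frac = sum(win_ok[k] for k in ks) / len(ks)
        mask[j] = frac > threshold
    return mask


def bruteforce_roh(
    calls_row: np.ndarray,
    positions: np.ndarray,
    window_snps: int,
    max_het: int,
    max_missing: int,
    threshold: float,
    max_gap_bp: int,
    min_length_bp: int,
    min_snps: int,
    min_density_bp_per_snp: int,
) -> list[tuple[int, int, int, int]]:
    """All segments on one chromosome of one individual.

    Enumerates every SNP interval; a candidate must consist solely of
    in-run SNPs, start and end on homozygous non-missing calls and have
    no internal gap above the cap. Maximal candidates (not contained in
    another candidate) are then filtered by length, SNP count and mean
    density. Returns (start_bp, end_bp, n_snps, length_bp) tuples.
    """
    m = len(calls_row)
    mask = window_mask_bruteforce(calls_row, window_snps, max_het, max_missing, threshold)
    hom = (calls_row == HOM_A) | (calls_row == HOM_B)
    run_cum = np.concatenate([[0], np.cumsum(mask)])
    candidates: list[tuple[int, int]] = []
    for i in range(m):
        if not (mask[i] and hom[i]):
            continue
        for j in range(i, m):
            if run_cum[j + 1] - run_cum[i] != j - i + 1:
                break  # a non-in-run SNP entered the interval
            if j > i and positions[j] - positions[j - 1] > max_gap_bp:
                break
            if hom[j]:
                candidates.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in candidates
        if not any((oi <= i and j <= oj) and (oi, oj) != (i, j) for oi, oj in candidates)
    ]
    out = []
    for i, j in maximal:
        n_snps = j - i + 1
        length = int(positions[j] - positions[i] + 1)
        if length < min_length_bp or n_snps < min_snps:
            continue
        if length / n_snps > min_density_bp_per_snp:
            continue
        out.append((int(positions[i]), int(positions[j]), n_snps, length))
    return sorted(out)


# ---------------------------------------------------------------------------
# interval membership oracle for incidence
# ---------------------------------------------------------------------------
def incidence_bruteforce(segments_rows, snp_table) -> np.ndarray:
    """Per-SNP count of individuals covered, by direct per-pair testing.

    ``segments_rows`` is an iterable of (individual_id, chromosome,
    start_bp, end_bp); ``snp_table`` of (chromosome, position_bp).
    """
    counts = np.zeros(len(snp_table), dtype=int)
    for j, (chrom, pos) in enumerate(snp_table):
        covered_by = set()
        for iid, seg_chrom, start, end in segments_rows:
            if seg_chrom == chrom and start <= pos <= end:
                covered_by.add(iid)
        counts[j] = len(covered_by)
    return counts
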