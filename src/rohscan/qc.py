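"""SNP- and individual-level quality control for array genotype panels.

Filters (applied in a fixed, documented order):

1. non-autosomal and unplaced markers (chromosome label outside the
   autosome set, label "0"/"", or position 0) are dropped;
2. individuals with genotype missing rate > ``max_individual_missing``;
3. SNPs with call rate < ``min_snp_call_rate``;
4. SNPs with minor allele frequency < ``min_maf``;
5. SNPs with exact Hardy–Weinberg test p-value < ``hwe_p_floor``.

Individuals are filtered before the SNP-frequency filters because MAF and
HWE depend on the retained individual set. Inequalities are strict on the
removal side throughout. The HWE test is the exact conditional
(Levene–Haldane) test, two-sided by probability mass — at a p-value floor
of 1e-6 the chi-square approximation is unreliable, so the exact test is
used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import HET, HOM_A, HOM_B, MISSING, GenotypePanel, default_autosome_labels


class QcError(ValueError):
    """Invalid QC input."""


class EmptyResultError(QcError):
    """QC removed every SNP or every individual."""

    def __init__(self, message: str, report: "QcReport"):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; defaults are the standard array-QC settings
    (call rate 90%, MAF 0.05, HWE p 1e-6, individual missingness 10%)."""

    min_snp_call_rate: float = 0.90
    min_maf: float = 0.05
    hwe_p_floor: float = 1e-6
    max_individual_missing: float = 0.10
    autosomes: frozenset[str] = field(
        default_factory=lambda: frozenset(default_autosome_labels())
    )

    def __post_init__(self) -> None:
        for name in ("min_snp_call_rate", "min_maf", "max_individual_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise QcError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.hwe_p_floor <= 1.0:
            raise QcError(f"hwe_p_floor must be in [0,1], got {self.hwe_p_floor}")


@dataclass
class QcReport:
    """Per-criterion removal accounting for one QC pass."""

    input_snps: int = 0
    input_individuals: int = 0
    nonautosomal_removed: int = 0
    individuals_removed: int = 0
    call_rate_removed: int = 0
    maf_removed: int = 0
    hwe_removed: int = 0
    retained_snps: int = 0
    retained_individuals: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": list(self.__dict__), "count": list(self.__dict__.values())}
        )


# ---------------------------------------------------------------------------
# exact Hardy–Weinberg test
# ---------------------------------------------------------------------------
def hwe_het_probabilities(
    n_hom_a: int, n_het: int, n_hom_b: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count.

    Given observed genotype counts, condition on the sample allele counts
    and return every compatible heterozygote count (same parity as the
    minor-allele count) together with its Levene–Haldane probability

        P(n_het = h) ∝ n! / (n_aa! h! n_bb!) · 2^h

    with ``n_aa = (n_A − h)/2`` and ``n_bb = (n_B − h)/2``. The returned
    probabilities are normalised and sum to 1.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise QcError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n < 1:
        raise QcError("exact HWE test undefined for all-zero genotype counts")
    n_a = 2 * n_hom_a + n_het
    n_b = 2 * n_hom_b + n_het
    rare = min(n_a, n_b)

    h = np.arange(rare % 2, rare + 1, 2)
    log_num = h * np.log(2.0) - (
        gammaln((n_a - h) / 2 + 1) + gammaln(h + 1) + gammaln((n_b - h) / 2 + 1)
    )
    log_num -= log_num.max()
    probs = np.exp(log_num)
    probs /= probs.sum()
    return h, probs


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value.

    Sums the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed count. A monomorphic
    marker admits a single configuration, so p = 1.
    """
    h, probs = hwe_het_probabilities(n_hom_a, n_het, n_hom_b)
    p_obs = probs[np.searchsorted(h, n_het)]
    # tolerate float round-off when comparing tied configurations
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def hwe_p_values(panel: GenotypePanel) -> np.ndarray:
    """Exact HWE p-value for every SNP of a panel."""
    n_aa = (panel.calls == HOM_A).sum(axis=0)
    n_ab = (panel.calls == HET).sum(axis=0)
    n_bb = (panel.calls == HOM_B).sum(axis=0)
    out = np.ones(panel.n_snps)
    for j in range(panel.n_snps):
        if n_aa[j] + n_ab[j] + n_bb[j] > 0:
            out[j] = hwe_exact_test(int(n_aa[j]), int(n_ab[j]), int(n_bb[j]))
    return out


# ---------------------------------------------------------------------------
# panel-level filtering
# ---------------------------------------------------------------------------
def apply_qc(
    panel: GenotypePanel, thresholds: QcThresholds | None = None
) -> tuple[GenotypePanel, QcReport]:
    """Apply all filters in the fixed order; return the clean panel and report.

    Raises :class:`EmptyResultError` (report attached) if no SNP or no
    individual survives.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    if panel.n_snps == 0 or panel.n_individuals == 0:
        raise QcError("apply_qc requires a non-empty panel")

    report = QcReport(input_snps=panel.n_snps, input_individuals=panel.n_individuals)

    # 1. autosomal, placed markers only
    keep_snp = np.array(
        [
            (s.chromosome in thresholds.autosomes)
            and s.chromosome not in ("0", "")
            and s.position_bp >= 1
            for s in panel.snps
        ]
    )
    report.nonautosomal_removed = int((~keep_snp).sum())
    panel = panel.subset(snp_mask=keep_snp)
    _check_nonempty(panel, report, "autosome filter")

    # 2. individual missing rate (strict >)
    keep_ind = panel.individual_missing_rate() <= thresholds.max_individual_missing
    report.individuals_removed = int((~keep_ind).sum())
    panel = panel.subset(individual_mask=keep_ind)
    _check_nonempty(panel, report, "individual missingness filter")

    # 3. SNP call rate (strict <)
    keep_snp = panel.snp_call_rate() >= thresholds.min_snp_call_rate
    report.call_rate_removed = int((~keep_snp).sum())
    panel = panel.subset(snp_mask=keep_snp)
    _check_nonempty(panel, report, "call-rate filter")

    # 4. MAF (strict <); SNPs with zero non-missing calls were removed above
    maf = panel.maf()
    keep_snp = ~(maf < thresholds.min_maf) & ~np.isnan(maf)
    report.maf_removed = int((~keep_snp).sum())
    panel = panel.subset(snp_mask=keep_snp)
    _check_nonempty(panel, report, "MAF filter")

    # 5. HWE exact test (strict <)
    keep_snp = hwe_p_values(panel) >= thresholds.hwe_p_floor
    report.hwe_removed = int((~keep_snp).sum())
    panel = panel.subset(snp_mask=keep_snp)
    _check_nonempty(panel, report, "HWE filter")

    report.retained_snps = panel.n_snps
    report.retained_individuals = panel.n_individuals
    return panel, report


def _check_nonempty(panel: GenotypePanel, report: QcReport, stage: str) -> None:
    if panel.n_snps == 0 or panel.n_individuals == 0:
        report.retained_snps = panel.n_snps
        report.retained_individuals = panel.n_individuals
        raise EmptyResultError(f"no data left after {stage}", report)
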