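"""Genomic inbreeding coefficients and their correlations.

Two estimators are computed per individual:

* ``F_ROH`` — the fraction of the SNP-covered autosomal genome inside the
  individual's runs of homozygosity, Σ L_ROH / L_auto, with L_auto the
  span (first to last marker, summed over chromosomes) of the array. It
  is also decomposed by ROH length class (1–5, 5–10, 10–20, >20 Mb); the
  overall value is the exact sum of the four class components.
* ``F_HOM`` — the method-of-moments excess-homozygosity coefficient:
  for individual j over its non-missing SNPs, (O_hom − E_hom) / (m −
  E_hom), where O_hom is the observed homozygote count, m the SNP count
  and E_hom the expected homozygote count under Hardy–Weinberg with the
  finite-sample correction N/(N−1) on expected heterozygosity (N = 2 ×
  non-missing individuals at the marker). F_HOM is negative when an
  individual is less homozygous than expected — a one-line "proportion of
  homozygotes" cannot go negative, which is why the excess form is used.

Pearson correlations among the six measures are computed from the
product-moment formula with a two-sided t-test on n−2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .panel import HET, HOM_A, HOM_B, MISSING, GenotypePanel
from .roh import LENGTH_CLASSES

#: Column names of the class-specific F_ROH components, in class order.
CLASS_COLUMNS = ("f_roh_1_5", "f_roh_5_10", "f_roh_10_20", "f_roh_gt20")

#: Display names used in correlation output.
MEASURES = ("F_HOM", "F_ROH", "F_ROH_1_5", "F_ROH_5_10", "F_ROH_10_20", "F_ROH_gt20")


class InbreedingError(ValueError):
    """Invalid inbreeding-estimator input."""


# ---------------------------------------------------------------------------
# F_ROH
# ---------------------------------------------------------------------------
def autosome_span(panel: GenotypePanel) -> int:
    """SNP-covered autosomal length: Σ per chromosome of (last − first + 1).

    A chromosome carrying a single marker contributes 1 bp (degenerate
    but well defined).
    """
    positions = panel.positions
    total = 0
    for sl in panel.chromosome_slices().values():
        total += int(positions[sl.stop - 1] - positions[sl.start] + 1)
    return total


def f_roh(
    segments: pd.DataFrame,
    l_auto_bp: int,
    individual_ids: list[str],
    length_class: str | None = None,
) -> pd.Series:
    """Per-individual Σ L_ROH / L_auto, optionally restricted to one class.

    ``length_class`` is one of "1-5", "5-10", "10-20", ">20" (Mb).
    Individuals with no qualifying segments get 0.
    """
    if l_auto_bp <= 0:
        raise InbreedingError("l_auto_bp must be positive")
    sub = segments
    if len(sub) and sub["length_bp"].max() > l_auto_bp:
        raise InbreedingError("segment longer than the autosomal span")
    if length_class is not None:
        bounds = {c[0]: (c[1], c[2]) for c in LENGTH_CLASSES}
        if length_class not in bounds:
            raise InbreedingError(f"unknown length class {length_class!r}")
        lo, hi = bounds[length_class]
        if len(sub):
            sub = sub[(sub["length_bp"] >= lo) & (sub["length_bp"] < hi)]
    totals = (
        sub.groupby("individual_id")["length_bp"].sum() if len(sub) else pd.Series(dtype=float)
    )
    return pd.Series(
        [totals.get(iid, 0) / l_auto_bp for iid in individual_ids],
        index=pd.Index(individual_ids, name="individual_id"),
        dtype=float,
    )


# ---------------------------------------------------------------------------
# F_HOM
# ---------------------------------------------------------------------------
def f_hom(panel: GenotypePanel, small_sample_correction: bool = True) -> pd.Series:
    """Method-of-moments excess-homozygosity coefficient per individual.

    With ``small_sample_correction`` the expected heterozygosity at each
    marker is 2p̂(1−p̂)·N/(N−1) with N the non-missing allele count;
    without it, plain 2p̂(1−p̂). Monomorphic markers contribute equally
    to observed and expected homozygosity and cancel; a panel whose
    polymorphic content is empty is degenerate and rejected.
    """
    if panel.n_individuals < 2:
        raise InbreedingError("F_HOM needs >= 2 individuals for allele frequencies")
    obs = panel.calls != MISSING
    p = panel.allele_b_frequency()
    n_alleles = 2.0 * obs.sum(axis=0)
    exp_het = 2.0 * p * (1.0 - p)
    if small_sample_correction:
        with np.errstate(invalid="ignore", divide="ignore"):
            exp_het = np.where(
                n_alleles > 2, exp_het * n_alleles / (n_alleles - 1.0), exp_het
            )
    exp_hom_snp = 1.0 - exp_het  # per-SNP expected homozygote probability

    is_hom = (panel.calls == HOM_A) | (panel.calls == HOM_B)
    o_hom = (is_hom & obs).sum(axis=1).astype(float)
    e_hom = obs @ np.nan_to_num(exp_hom_snp)
    m = obs.sum(axis=1).astype(float)
    denom = m - e_hom
    if np.all(denom <= 0):
        raise InbreedingError(
            "F_HOM undefined: expected homozygosity equals the SNP count "
            "(monomorphic-only panel)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, (o_hom - e_hom) / denom, np.nan)
    return pd.Series(
        f, index=pd.Index(panel.individual_ids, name="individual_id"), dtype=float
    )


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------
def inbreeding_profiles(
    panel: GenotypePanel,
    segments: pd.DataFrame,
    l_auto_bp: int | None = None,
    small_sample_correction: bool = True,
) -> pd.DataFrame:
    """Per-individual table of F_HOM, F_ROH and the four class components.

    The overall ``f_roh`` column is computed as the sum of the four class
    components, so the additivity identity holds exactly.
    """
    if l_auto_bp is None:
        l_auto_bp = autosome_span(panel)
    out = pd.DataFrame(
        {"f_hom": f_hom(panel, small_sample_correction=small_sample_correction)}
    )
    class_cols = {}
    for (label, _, _), col in zip(LENGTH_CLASSES, CLASS_COLUMNS):
        class_cols[col] = f_roh(segments, l_auto_bp, panel.individual_ids, label)
    out["f_roh"] = sum(class_cols.values())
    for col, series in class_cols.items():
        out[col] = series
    out.attrs["l_auto_bp"] = l_auto_bp
    return out.reset_index()


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p_value: float
    n: int


def pearson_correlation(
    x: np.ndarray, y: np.ndarray, names: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value.

    r = Σ(x−x̄)(y−ȳ) / sqrt(Σ(x−x̄)² Σ(y−ȳ)²); the test statistic is
    t = r sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InbreedingError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise InbreedingError("correlation needs n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise InbreedingError("correlation undefined for a constant vector")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(pair=names, r=r, p_value=min(1.0, max(0.0, p)), n=n)


def correlation_matrix(
    profiles: pd.DataFrame, on_constant: str = "raise"
) -> pd.DataFrame:
    """All 15 pairwise correlations among the six inbreeding measures.

    ``on_constant="nan"`` reports NaN for pairs involving a constant
    vector (e.g. no segments in a length class anywhere in the panel)
    instead of raising.
    """
    if len(profiles) < 3:
        raise InbreedingError("correlation matrix needs >= 3 profiles")
    columns = dict(zip(MEASURES, ["f_hom", "f_roh", *CLASS_COLUMNS]))
    rows = []
    for a, b in combinations(MEASURES, 2):
        try:
            res = pearson_correlation(
                profiles[columns[a]].to_numpy(),
                profiles[columns[b]].to_numpy(),
                names=(a, b),
            )
            row = {"r": res.r, "p_value": res.p_value, "n": res.n}
        except InbreedingError:
            if on_constant != "nan":
                raise
            row = {"r": float("nan"), "p_value": float("nan"), "n": len(profiles)}
        rows.append({"measure_1": a, "measure_2": b, **row})
    return pd.DataFrame(rows)
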