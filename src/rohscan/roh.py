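"""Sliding-window runs-of-homozygosity detection and summaries.

The detector reproduces the windowed scanning procedure of the standard
SNP-array toolchain: a window of ``window_snps`` consecutive markers
slides one marker at a time along each chromosome of each individual; a
window is *homozygous* if it contains at most ``max_het_per_window``
heterozygous and ``max_missing_per_window`` missing calls; each SNP is
scored with the fraction of overlapping windows that are homozygous, and
SNPs whose fraction exceeds ``window_hit_threshold`` are *in-run*.
Maximal stretches of in-run SNPs are split at inter-marker gaps larger
than ``max_gap_bp``, trimmed so they start and end on homozygous
non-missing calls, and kept only if they satisfy the minimum length, the
minimum SNP count, and the mean marker density bound.

The minimum SNP count defaults to the false-positive-controlled value of
Lencz et al.:

    l = ceil( ln(alpha / (ns * ni)) / ln(1 - het) )

where ``ns`` is the SNP count, ``ni`` the individual count and ``het``
the mean heterozygosity of the panel — the run length that genome-wide
chance homozygosity exceeds with probability at most ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import HET, HOM_A, HOM_B, MISSING, GenotypePanel

#: The four ROH length classes (label, lower bp inclusive, upper bp exclusive).
LENGTH_CLASSES: tuple[tuple[str, int, float], ...] = (
    ("1-5", 1_000_000, 5_000_000),
    ("5-10", 5_000_000, 10_000_000),
    ("10-20", 10_000_000, 20_000_000),
    (">20", 20_000_000, math.inf),
)

SEGMENT_COLUMNS = ["individual_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_bp"]


class RohError(ValueError):
    """Invalid ROH-caller input."""


@dataclass(frozen=True)
class RohParams:
    """Detection parameters.

    Defaults are the medium-density array settings: 50-SNP window, one
    heterozygous and one missing call allowed per window, 1 Mb maximum
    gap, at least 1 SNP per 100 kb, 1 Mb minimum length, alpha = 0.05 for
    the Lencz minimum-SNP count, and the conventional 0.05 window-hit
    proportion.
    """

    window_snps: int = 50
    fp_alpha: float = 0.05
    max_het_per_window: int = 1
    max_missing_per_window: int = 1
    max_gap_bp: int = 1_000_000
    min_density_bp_per_snp: int = 100_000
    min_length_bp: int = 1_000_000
    window_hit_threshold: float = 0.05
    min_snps_override: int | None = None
    # strict per-segment caps mirroring a literal "per ROH" reading of the
    # het/missing allowance; disabled by default (window semantics rule)
    segment_het_cap: int | None = None
    segment_missing_cap: int | None = None

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise RohError("window_snps must be >= 2")
        if not 0 < self.fp_alpha < 1:
            raise RohError("fp_alpha must be in (0,1)")
        for name in ("max_gap_bp", "min_density_bp_per_snp", "min_length_bp"):
            if getattr(self, name) <= 0:
                raise RohError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# panel statistics feeding the minimum-SNP rule
# ---------------------------------------------------------------------------
def mean_heterozygosity(panel: GenotypePanel) -> float:
    """Fraction of heterozygous calls among all non-missing calls."""
    n_het = int((panel.calls == HET).sum())
    n_obs = int((panel.calls != MISSING).sum())
    if n_obs == 0:
        raise RohError("mean heterozygosity undefined: all calls missing")
    return n_het / n_obs


def lencz_min_snps(
    fp_alpha: float, n_snps: int, n_individuals: int, mean_het: float
) -> int:
    """Minimum SNPs per run so chance runs occur at rate <= ``fp_alpha``."""
    if not 0 < fp_alpha < 1:
        raise RohError("fp_alpha must be in (0,1)")
    if n_snps < 1 or n_individuals < 1:
        raise RohError("n_snps and n_individuals must be >= 1")
    if not 0 < mean_het < 1:
        raise RohError(f"mean_het must be in (0,1), got {mean_het}")
    l = math.log(fp_alpha / (n_snps * n_individuals)) / math.log(1.0 - mean_het)
    return max(1, math.ceil(l))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------
def window_homozygosity_fractions(
    calls_block: np.ndarray, params: RohParams
) -> np.ndarray:
    """Per-SNP fraction of overlapping windows that are homozygous.

    ``calls_block`` is (individuals × SNPs) for one chromosome. When the
    chromosome has fewer SNPs than the window, no window exists and every
    fraction is 0.
    """
    n_ind, m = calls_block.shape
    w = params.window_snps
    if m < w:
        return np.zeros((n_ind, m))

    het = (calls_block == HET).astype(np.int32)
    mis = (calls_block == MISSING).astype(np.int32)

    def _window_sums(x: np.ndarray) -> np.ndarray:
        c = np.concatenate(
            [np.zeros((n_ind, 1), dtype=np.int64), np.cumsum(x, axis=1)], axis=1
        )
        return c[:, w:] - c[:, :-w]  # (n_ind, m - w + 1)

    window_ok = (
        (_window_sums(het) <= params.max_het_per_window)
        & (_window_sums(mis) <= params.max_missing_per_window)
    ).astype(np.int64)

    n_win = m - w + 1
    cum_ok = np.concatenate(
        [np.zeros((n_ind, 1), dtype=np.int64), np.cumsum(window_ok, axis=1)], axis=1
    )
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    hits = cum_ok[:, hi + 1] - cum_ok[:, lo]
    denom = hi - lo + 1
    return hits / denom


def detect_roh(
    panel: GenotypePanel,
    params: RohParams | None = None,
    min_snps: int | None = None,
) -> pd.DataFrame:
    """Detect runs of homozygosity for every individual of a panel.

    Parameters
    ----------
    panel
        Post-QC genotype panel (SNPs sorted by chromosome and position;
        enforced by the panel itself).
    params
        Detection parameters.
    min_snps
        Minimum SNPs per segment. When omitted, ``params.min_snps_override``
        is used if set, otherwise the Lencz count computed from this
        panel's dimensions and mean heterozygosity.

    Returns
    -------
    DataFrame with columns ``individual_id, chromosome, start_bp, end_bp,
    n_snps, length_bp``, sorted by (individual, chromosome, start) in
    panel order.
    """
    if params is None:
        params = RohParams()
    if min_snps is None:
        min_snps = (
            params.min_snps_override
            if params.min_snps_override is not None
            else lencz_min_snps(
                params.fp_alpha,
                panel.n_snps,
                panel.n_individuals,
                mean_heterozygosity(panel),
            )
        )

    rows: list[tuple] = []
    positions = panel.positions
    for chrom, sl in panel.chromosome_slices().items():
        block = panel.calls[:, sl]
        pos = positions[sl]
        frac = window_homozygosity_fractions(block, params)
        in_run = frac > params.window_hit_threshold
        gap_break = np.flatnonzero(np.diff(pos) > params.max_gap_bp)  # break after idx
        for i, iid in enumerate(panel.individual_ids):
            for a, b in _candidate_stretches(in_run[i], gap_break):
                seg = _finalize_stretch(block[i], pos, a, b, params, min_snps)
                if seg is not None:
                    rows.append((iid, chrom, *seg))

    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    ind_order = {iid: k for k, iid in enumerate(panel.individual_ids)}
    chrom_order = {c: k for k, c in enumerate(panel.chromosomes)}
    if len(df):
        df = (
            df.assign(
                _i=df["individual_id"].map(ind_order),
                _c=df["chromosome"].map(chrom_order),
            )
            .sort_values(["_i", "_c", "start_bp"], kind="mergesort")
            .drop(columns=["_i", "_c"])
            .reset_index(drop=True)
        )
    return df


def _candidate_stretches(
    in_run: np.ndarray, gap_break: np.ndarray
) -> list[tuple[int, int]]:
    """Maximal in-run index intervals, split at oversized gaps.

    ``gap_break`` holds indices i where the gap between SNP i and i+1
    exceeds the cap. Returns inclusive (start, end) index pairs.
    """
    if not in_run.any():
        return []
    padded = np.concatenate([[False], in_run, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    out: list[tuple[int, int]] = []
    for a, b in zip(starts, ends):
        cuts = gap_break[(gap_break >= a) & (gap_break < b)]
        lo = a
        for c in cuts:
            out.append((lo, int(c)))
            lo = int(c) + 1
        out.append((lo, int(b)))
    return out


def _finalize_stretch(
    calls_row: np.ndarray,
    pos: np.ndarray,
    a: int,
    b: int,
    params: RohParams,
    min_snps: int,
) -> tuple[int, int, int, int] | None:
    """Trim a candidate stretch and apply the final filters.

    Returns (start_bp, end_bp, n_snps, length_bp) or None if discarded.
    """
    hom = (calls_row == HOM_A) | (calls_row == HOM_B)
    while a <= b and not hom[a]:
        a += 1
    while b >= a and not hom[b]:
        b -= 1
    if a > b:
        return None
    n_snps = b - a + 1
    length = int(pos[b] - pos[a] + 1)
    if length < params.min_length_bp or n_snps < min_snps:
        return None
    if length / n_snps > params.min_density_bp_per_snp:
        return None
    if params.segment_het_cap is not None:
        if int((calls_row[a : b + 1] == HET).sum()) > params.segment_het_cap:
            return None
    if params.segment_missing_cap is not None:
        if int((calls_row[a : b + 1] == MISSING).sum()) > params.segment_missing_cap:
            return None
    return int(pos[a]), int(pos[b]), int(n_snps), length


def validate_segments(
    segments: pd.DataFrame,
    params: RohParams,
    min_snps: int,
    panel: GenotypePanel | None = None,
) -> None:
    """Assert every segment invariant; raises :class:`RohError` on violation.

    When a panel is supplied, the member-SNP gap bound is also checked.
    """
    for row in segments.itertuples():
        if row.end_bp < row.start_bp:
            raise RohError(f"segment {row.Index}: end < start")
        if row.length_bp != row.end_bp - row.start_bp + 1:
            raise RohError(f"segment {row.Index}: length_bp inconsistent")
        if row.length_bp < params.min_length_bp:
            raise RohError(f"segment {row.Index}: below minimum length")
        if row.n_snps < min_snps:
            raise RohError(f"segment {row.Index}: below minimum SNP count")
        if row.length_bp / row.n_snps > params.min_density_bp_per_snp:
            raise RohError(f"segment {row.Index}: density bound violated")
    if panel is not None:
        slices = panel.chromosome_slices()
        positions = panel.positions
        for row in segments.itertuples():
            sl = slices[row.chromosome]
            pos = positions[sl]
            member = pos[(pos >= row.start_bp) & (pos <= row.end_bp)]
            if len(member) and np.any(np.diff(member) > params.max_gap_bp):
                raise RohError(f"segment {row.Index}: member gap exceeds cap")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------
def length_class_of(length_bp: np.ndarray | pd.Series) -> pd.Categorical:
    """Assign each length to its class with half-open [lo, hi) boundaries."""
    labels = [c[0] for c in LENGTH_CLASSES]
    bins = [LENGTH_CLASSES[0][1]] + [c[2] for c in LENGTH_CLASSES]
    return pd.cut(
        np.asarray(length_bp, dtype=float), bins=bins, labels=labels, right=False
    )


def classify_roh(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-length-class descriptive statistics plus an "All" row.

    Columns: class, n_segments, pct_of_number, mean_length_mb,
    sd_length_mb (sample SD), total_length_mb, pct_of_length. Percentages
    are of the total segment count and of the total length.
    """
    rows = []
    lengths_mb = (
        segments["length_bp"].to_numpy(dtype=float) / 1e6
        if len(segments)
        else np.array([])
    )
    classes = (
        length_class_of(segments["length_bp"])
        if len(segments)
        else pd.Categorical([], categories=[c[0] for c in LENGTH_CLASSES])
    )
    n_total = len(segments)
    len_total = lengths_mb.sum()
    for label, _, _ in LENGTH_CLASSES:
        mask = np.asarray(classes == label)
        sub = lengths_mb[mask]
        rows.append(
            {
                "class": f"{label} Mb",
                "n_segments": int(mask.sum()),
                "pct_of_number": 100.0 * mask.sum() / n_total if n_total else 0.0,
                "mean_length_mb": float(sub.mean()) if len(sub) else float("nan"),
                "sd_length_mb": float(sub.std(ddof=1)) if len(sub) > 1 else float("nan"),
                "total_length_mb": float(sub.sum()),
                "pct_of_length": 100.0 * sub.sum() / len_total if len_total else 0.0,
            }
        )
    rows.append(
        {
            "class": "All",
            "n_segments": n_total,
            "pct_of_number": 100.0 if n_total else 0.0,
            "mean_length_mb": float(lengths_mb.mean()) if n_total else float("nan"),
            "sd_length_mb": float(lengths_mb.std(ddof=1)) if n_total > 1 else float("nan"),
            "total_length_mb": float(len_total),
            "pct_of_length": 100.0 if n_total else 0.0,
        }
    )
    return pd.DataFrame(rows)


def chromosome_summary(
    segments: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_individuals: int,
    per_individual: bool = True,
) -> pd.DataFrame:
    """Per-chromosome segment count, total ROH length and coverage.

    Coverage is, by default, the population-average fraction of the
    chromosome inside ROH: 100 · Σ segment lengths / (n_individuals ·
    chromosome length). With ``per_individual=False`` the denominator is
    the chromosome length alone (cohort-total variant).
    """
    if n_individuals < 1:
        raise RohError("n_individuals must be >= 1")
    unknown = set(segments["chromosome"]) - set(chrom_lengths) if len(segments) else set()
    if unknown:
        raise KeyError(
            f"segments reference chromosomes missing from the length table: "
            f"{sorted(unknown)}"
        )
    rows = []
    for chrom, clen in chrom_lengths.items():
        sub = segments[segments["chromosome"] == chrom] if len(segments) else segments
        total_bp = int(sub["length_bp"].sum()) if len(sub) else 0
        denom = clen * (n_individuals if per_individual else 1)
        rows.append(
            {
                "chromosome": chrom,
                "length_mb": clen / 1e6,
                "n_segments": len(sub),
                "total_roh_mb": total_bp / 1e6,
                "coverage_pct": 100.0 * total_bp / denom,
                "longest_mb": sub["length_bp"].max() / 1e6 if len(sub) else float("nan"),
                "shortest_mb": sub["length_bp"].min() / 1e6 if len(sub) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def per_individual_summary(segments: pd.DataFrame, individual_ids: list[str]) -> pd.DataFrame:
    """Per-individual ROH count and total/mean length (MN_ROH, ML_ROH inputs)."""
    rows = []
    grouped = segments.groupby("individual_id") if len(segments) else None
    for iid in individual_ids:
        if grouped is not None and iid in grouped.groups:
            sub = grouped.get_group(iid)
            rows.append(
                {
                    "individual_id": iid,
                    "n_roh": len(sub),
                    "total_length_mb": sub["length_bp"].sum() / 1e6,
                    "mean_length_mb": sub["length_bp"].mean() / 1e6,
                }
            )
        else:
            rows.append(
                {
                    "individual_id": iid,
                    "n_roh": 0,
                    "total_length_mb": 0.0,
                    "mean_length_mb": float("nan"),
                }
            )
    return pd.DataFrame(rows)
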