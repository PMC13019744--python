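"""ROH islands: high-incidence homozygosity regions across a population.

For every marker we count how many individuals carry a run of
homozygosity spanning it. Markers whose incidence reaches the empirical
top-``top_fraction`` (default 1%) threshold are island candidates;
maximal runs of consecutive candidates on a chromosome (at least
``min_island_snps`` markers, default 2) form the islands, which are then
annotated with overlapping genes from a GFF3 or BED gene-model file.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .panel import GenotypePanel

INCIDENCE_COLUMNS = ["snp_id", "chromosome", "position_bp", "n_in_roh", "fraction_in_roh"]


class IslandError(ValueError):
    """Invalid island-detection input."""


class DegenerateThresholdWarning(UserWarning):
    """All incidence values identical: the top-1% rule cannot discriminate."""


# ---------------------------------------------------------------------------
# per-SNP incidence
# ---------------------------------------------------------------------------
def snp_roh_incidence(segments: pd.DataFrame, panel: GenotypePanel) -> pd.DataFrame:
    """Count, per marker, the individuals whose ROH cover it.

    A marker is "in ROH" for an individual iff ``start_bp <= position <=
    end_bp`` for any of that individual's segments on the marker's
    chromosome; overlapping segments (which the caller never emits) would
    still count once.
    """
    slices = panel.chromosome_slices()
    if len(segments):
        unknown = set(segments["chromosome"]) - set(slices)
        if unknown:
            raise IslandError(
                f"segments reference chromosomes not in the panel: {sorted(unknown)}"
            )
    positions = panel.positions
    counts = np.zeros(panel.n_snps, dtype=np.int64)
    if len(segments):
        for (iid, chrom), sub in segments.groupby(
            ["individual_id", "chromosome"], sort=False
        ):
            sl = slices[chrom]
            pos = positions[sl]
            covered = np.zeros(sl.stop - sl.start, dtype=bool)
            for row in sub.itertuples():
                lo = np.searchsorted(pos, row.start_bp, side="left")
                hi = np.searchsorted(pos, row.end_bp, side="right")
                covered[lo:hi] = True
            counts[sl] += covered
    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "chromosome": panel.snp_chromosomes,
            "position_bp": positions,
            "n_in_roh": counts,
            "fraction_in_roh": counts / panel.n_individuals,
        }
    )


# ---------------------------------------------------------------------------
# threshold and island assembly
# ---------------------------------------------------------------------------
def island_threshold(incidence: pd.DataFrame, top_fraction: float = 0.01) -> float:
    """Incidence value marking the top-``top_fraction`` of markers.

    "Top 1%" is a count statement: the threshold is the k-th largest
    incidence with k = ceil(top_fraction · n_snps); every marker with
    incidence >= threshold is a candidate, so ties at the cutoff are all
    included and the candidate set has at least k members.
    """
    if not 0 < top_fraction < 1:
        raise IslandError("top_fraction must be in (0,1)")
    values = incidence["fraction_in_roh"].to_numpy(dtype=float)
    if len(values) == 0:
        raise IslandError("empty incidence list")
    if np.all(values == values[0]):
        warnings.warn(
            "all incidence values identical; threshold is degenerate "
            "(every marker ties at the cutoff)",
            DegenerateThresholdWarning,
            stacklevel=2,
        )
        return float(values[0])
    k = int(np.ceil(top_fraction * len(values)))
    return float(np.sort(values)[::-1][k - 1])


def detect_islands(
    incidence: pd.DataFrame,
    threshold: float,
    min_island_snps: int = 2,
) -> pd.DataFrame:
    """Maximal runs of consecutive above-threshold markers.

    Runs shorter than ``min_island_snps`` markers (singletons by default)
    are discarded. Island bounds are the first and last member marker
    positions (1-based, closed).
    """
    rows = []
    candidate = incidence["fraction_in_roh"].to_numpy(dtype=float) >= threshold
    chroms = incidence["chromosome"].to_numpy(dtype=object)
    pos = incidence["position_bp"].to_numpy(dtype=np.int64)
    n = len(incidence)
    i = 0
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and candidate[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        if j - i + 1 >= min_island_snps:
            rows.append(
                {
                    "chromosome": chroms[i],
                    "start_bp": int(pos[i]),
                    "end_bp": int(pos[j]),
                    "length_bp": int(pos[j] - pos[i] + 1),
                    "n_snps": j - i + 1,
                }
            )
        i = j + 1
    return pd.DataFrame(
        rows, columns=["chromosome", "start_bp", "end_bp", "length_bp", "n_snps"]
    )


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------
def annotate_islands(islands: pd.DataFrame, gene_models: pd.DataFrame) -> pd.DataFrame:
    """Attach overlapping genes (>= 1 bp, closed intervals) to each island.

    ``gene_models`` needs columns chromosome, start_bp, end_bp, gene_id
    (as produced by :func:`rohscan.genes.read_gene_models`). Raises if
    none of the island chromosomes appear in the gene file — the usual
    symptom of mismatched chromosome naming.
    """
    required = {"chromosome", "start_bp", "end_bp", "gene_id"}
    if not required.issubset(gene_models.columns):
        raise IslandError(f"gene_models must have columns {sorted(required)}")
    out = islands.copy()
    if len(out) == 0:
        out["genes"] = pd.Series(dtype=object)
        out["n_genes"] = pd.Series(dtype=int)
        return out
    gene_chroms = set(gene_models["chromosome"].astype(str))
    island_chroms = set(out["chromosome"].astype(str))
    if gene_chroms and not (island_chroms & gene_chroms):
        raise IslandError(
            "no island chromosome matches the gene file; unmatched labels: "
            f"{sorted(island_chroms)} vs gene labels like {sorted(gene_chroms)[:5]}"
        )
    trees: dict[str, IntervalTree] = {}
    for row in gene_models.itertuples():
        # IntervalTree is half-open; +1 makes the closed end inclusive
        trees.setdefault(str(row.chromosome), IntervalTree()).addi(
            int(row.start_bp), int(row.end_bp) + 1, row.gene_id
        )
    genes_col: list[list[str]] = []
    for row in out.itertuples():
        tree = trees.get(str(row.chromosome))
        hits = tree.overlap(int(row.start_bp), int(row.end_bp) + 1) if tree else set()
        genes_col.append(sorted({h.data for h in hits}))
    out["genes"] = genes_col
    out["n_genes"] = [len(g) for g in genes_col]
    return out
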