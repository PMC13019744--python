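"""Model-style front end: :class:`RohStudy` and :class:`RohStudyResults`.

`RohStudy` bundles a genotype panel with the analysis settings; `fit()`
runs the whole homozygosity analysis — quality control, sliding-window
ROH detection with the false-positive-controlled minimum-SNP count,
per-class and per-chromosome summaries, genomic inbreeding coefficients
(F_ROH overall and by length class, F_HOM) with their pairwise Pearson
correlations, and ROH-island detection with optional gene annotation —
and returns a results object carrying every table, a text ``summary()``
and report/plot helpers.

Example
-------
>>> from rohscan import RohStudy, simulate
>>> panel, truth = simulate.simulate_panel(simulate.SimConfig(seed=7))
>>> res = RohStudy(panel).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inbreeding as _inb
from . import io as _io
from . import islands as _isl
from . import qc as _qc
from . import roh as _roh
from .panel import GenotypePanel


class RohStudy:
    """A runs-of-homozygosity study of one genotype panel.

    Parameters
    ----------
    panel
        Raw genotype panel (QC is applied during ``fit`` unless
        ``apply_qc=False``).
    qc_thresholds
        SNP/individual filters; defaults to the standard array settings.
    roh_params
        Sliding-window detection parameters.
    chrom_lengths
        Optional chromosome-length table ``{label: bp}`` enabling the
        per-chromosome coverage summary.
    island_top_fraction, min_island_snps
        Incidence threshold rule (top 1% of markers) and minimum island
        size (2 consecutive markers).
    gene_models
        Optional gene intervals (``chromosome, start_bp, end_bp,
        gene_id``) for island annotation.
    small_sample_correction
        Apply the N/(N−1) finite-sample factor in the F_HOM expectation.
    """

    def __init__(
        self,
        panel: GenotypePanel,
        qc_thresholds: _qc.QcThresholds | None = None,
        roh_params: _roh.RohParams | None = None,
        chrom_lengths: dict[str, int] | None = None,
        island_top_fraction: float = 0.01,
        min_island_snps: int = 2,
        gene_models: pd.DataFrame | None = None,
        apply_qc: bool = True,
        small_sample_correction: bool = True,
        coverage_per_individual: bool = True,
    ):
        self.panel = panel
        self.qc_thresholds = qc_thresholds or _qc.QcThresholds()
        self.roh_params = roh_params or _roh.RohParams()
        self.chrom_lengths = chrom_lengths
        self.island_top_fraction = island_top_fraction
        self.min_island_snps = min_island_snps
        self.gene_models = gene_models
        self.apply_qc = apply_qc
        self.small_sample_correction = small_sample_correction
        self.coverage_per_individual = coverage_per_individual

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_ped_map(cls, ped_path, map_path, **kwargs) -> "RohStudy":
        return cls(_io.read_ped_map(ped_path, map_path), **kwargs)

    @classmethod
    def from_plink_binary(cls, prefix, **kwargs) -> "RohStudy":
        return cls(_io.read_bed_bim_fam(prefix), **kwargs)

    @classmethod
    def from_vcf(cls, vcf_path, **kwargs) -> "RohStudy":
        return cls(_io.read_vcf(vcf_path), **kwargs)

    # -- fitting --------------------------------------------------------
    def fit(self) -> "RohStudyResults":
        if self.apply_qc:
            panel, qc_report = _qc.apply_qc(self.panel, self.qc_thresholds)
        else:
            panel, qc_report = self.panel, None

        mean_het = _roh.mean_heterozygosity(panel)
        if self.roh_params.min_snps_override is not None:
            min_snps = self.roh_params.min_snps_override
        else:
            min_snps = _roh.lencz_min_snps(
                self.roh_params.fp_alpha, panel.n_snps, panel.n_individuals, mean_het
            )
        segments = _roh.detect_roh(panel, self.roh_params, min_snps=min_snps)
        class_summary = _roh.classify_roh(segments)
        chrom_summary = None
        if self.chrom_lengths is not None:
            chrom_summary = _roh.chromosome_summary(
                segments,
                self.chrom_lengths,
                panel.n_individuals,
                per_individual=self.coverage_per_individual,
            )
        individual_summary = _roh.per_individual_summary(segments, panel.individual_ids)

        profiles = _inb.inbreeding_profiles(
            panel, segments, small_sample_correction=self.small_sample_correction
        )
        correlations = (
            _inb.correlation_matrix(profiles, on_constant="nan")
            if panel.n_individuals >= 3
            else None
        )

        incidence = _isl.snp_roh_incidence(segments, panel)
        threshold = _isl.island_threshold(incidence, self.island_top_fraction)
        if incidence["fraction_in_roh"].nunique() <= 1:
            # degenerate threshold (e.g. no ROH at all): the top-1% rule
            # cannot discriminate, so the island scan is uninformative
            islands = _isl.detect_islands(incidence.iloc[0:0], threshold)
        else:
            islands = _isl.detect_islands(incidence, threshold, self.min_island_snps)
        if self.gene_models is not None and len(islands):
            islands = _isl.annotate_islands(islands, self.gene_models)

        return RohStudyResults(
            model=self,
            panel=panel,
            qc_report=qc_report,
            mean_heterozygosity=mean_het,
            min_roh_snps=min_snps,
            segments=segments,
            class_summary=class_summary,
            chrom_summary=chrom_summary,
            individual_summary=individual_summary,
            profiles=profiles,
            correlations=correlations,
            incidence=incidence,
            island_incidence_threshold=threshold,
            islands=islands,
        )


@dataclass
class RohStudyResults:
    """Fitted results of a :class:`RohStudy`; all tables are DataFrames."""

    model: RohStudy
    panel: GenotypePanel
    qc_report: _qc.QcReport | None
    mean_heterozygosity: float
    min_roh_snps: int
    segments: pd.DataFrame
    class_summary: pd.DataFrame
    chrom_summary: pd.DataFrame | None
    individual_summary: pd.DataFrame
    profiles: pd.DataFrame
    correlations: pd.DataFrame | None
    incidence: pd.DataFrame
    island_incidence_threshold: float
    islands: pd.DataFrame
    extras: dict = field(default_factory=dict)

    # -- headline statistics -------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def mn_roh(self) -> float:
        """Mean number of ROH per individual (MN_ROH)."""
        return self.n_segments / self.panel.n_individuals

    @property
    def mean_total_length_mb(self) -> float:
        """Mean cumulative ROH length per individual, Mb (ML basis)."""
        return float(self.segments["length_bp"].sum() / 1e6 / self.panel.n_individuals)

    @property
    def mean_segment_length_mb(self) -> float:
        """Mean length of a single ROH segment, Mb."""
        if self.n_segments == 0:
            return float("nan")
        return float(self.segments["length_bp"].mean() / 1e6)

    @property
    def mean_f_roh(self) -> float:
        return float(self.profiles["f_roh"].mean())

    @property
    def mean_f_hom(self) -> float:
        return float(self.profiles["f_hom"].mean())

    @property
    def n_islands(self) -> int:
        return len(self.islands)

    # -- presentation ---------------------------------------------------
    def summary(self) -> str:
        """Human-readable multi-table summary of the fitted study."""
        lines: list[str] = []
        add = lines.append
        add("Runs-of-homozygosity study summary")
        add("=" * 70)
        add(
            f"Panel after QC: {self.panel.n_individuals} individuals x "
            f"{self.panel.n_snps} SNPs on {len(self.panel.chromosomes)} chromosomes"
        )
        if self.qc_report is not None:
            r = self.qc_report
            add(
                f"QC removals: {r.nonautosomal_removed} non-autosomal/unplaced SNPs, "
                f"{r.individuals_removed} individuals (missingness), "
                f"{r.call_rate_removed} SNPs (call rate), {r.maf_removed} (MAF), "
                f"{r.hwe_removed} (HWE)"
            )
        add(
            f"Mean heterozygosity {self.mean_heterozygosity:.4f}; "
            f"minimum SNPs per run (false-positive controlled) {self.min_roh_snps}"
        )
        add("")
        add(
            f"ROH: {self.n_segments} segments; MN_ROH {self.mn_roh:.2f} per "
            f"individual; mean cumulative length {self.mean_total_length_mb:.2f} Mb; "
            f"mean segment length {self.mean_segment_length_mb:.2f} Mb"
        )
        add("")
        add("Length classes:")
        add(self.class_summary.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        add("")
        p = self.profiles
        add(
            "Inbreeding: mean F_ROH "
            f"{self.mean_f_roh:.4f} (SD {p['f_roh'].std(ddof=1):.4f}, range "
            f"{p['f_roh'].min():.4f}-{p['f_roh'].max():.4f}); mean F_HOM "
            f"{self.mean_f_hom:.4f} (SD {p['f_hom'].std(ddof=1):.4f}, range "
            f"{p['f_hom'].min():.4f}-{p['f_hom'].max():.4f})"
        )
        if self.correlations is not None:
            pair = self.correlations.query(
                "measure_1 == 'F_HOM' and measure_2 == 'F_ROH'"
            )
            if len(pair):
                add(f"F_ROH-F_HOM Pearson r {float(pair['r'].iloc[0]):.2f}")
        add("")
        add(
            f"Islands: incidence threshold {self.island_incidence_threshold:.4f} "
            f"(top {self.model.island_top_fraction:.0%} of markers); "
            f"{self.n_islands} islands on "
            f"{self.islands['chromosome'].nunique() if self.n_islands else 0} chromosomes"
        )
        if self.n_islands:
            show = self.islands.drop(columns=["genes"], errors="ignore")
            add(show.to_string(index=False))
        return "\n".join(lines)

    def save_reports(self, out_dir: str | Path) -> list[Path]:
        """Write the full TSV/BED report set; returns the written paths."""
        return _io.write_reports(self, out_dir)

    # -- plots ----------------------------------------------------------
    def plot_chromosome_roh(self, ax=None):
        """Bar chart of segment counts per chromosome, with coverage dots
        when a chromosome-length table was supplied."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        counts = (
            self.segments.groupby("chromosome").size()
            if self.n_segments
            else pd.Series(dtype=int)
        )
        chroms = self.panel.chromosomes
        ax.bar(range(len(chroms)), [counts.get(c, 0) for c in chroms], color="#4C72B0")
        ax.set_xticks(range(len(chroms)), chroms, rotation=90, fontsize=7)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("ROH count")
        if self.chrom_summary is not None:
            ax2 = ax.twinx()
            cov = self.chrom_summary.set_index("chromosome")["coverage_pct"]
            ax2.plot(
                range(len(chroms)),
                [cov.get(c, float("nan")) for c in chroms],
                "o",
                color="#C44E52",
            )
            ax2.set_ylabel("coverage (%)")
        return ax

    def plot_incidence(self, ax=None):
        """Manhattan-style plot of per-marker ROH incidence with the
        island threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3.5))
        x = np.arange(len(self.incidence))
        chroms = self.incidence["chromosome"].to_numpy(dtype=object)
        palette = ["#4C72B0", "#9AB2D4"]
        color_idx = np.zeros(len(x), dtype=int)
        seen: dict[str, int] = {}
        for i, c in enumerate(chroms):
            if c not in seen:
                seen[c] = len(seen)
            color_idx[i] = seen[c] % 2
        ax.scatter(
            x,
            self.incidence["fraction_in_roh"],
            s=2,
            c=[palette[k] for k in color_idx],
        )
        ax.axhline(self.island_incidence_threshold, color="#C44E52", lw=1)
        ax.set_xlabel("marker index (chromosome blocks alternate shade)")
        ax.set_ylabel("fraction of individuals in ROH")
        return ax

    def plot_inbreeding_distribution(self, ax=None):
        """Histograms of F_ROH and F_HOM across individuals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.hist(self.profiles["f_roh"], bins=30, alpha=0.6, label="F_ROH")
        ax.hist(self.profiles["f_hom"], bins=30, alpha=0.6, label="F_HOM")
        ax.set_xlabel("inbreeding coefficient")
        ax.set_ylabel("individuals")
        ax.legend()
        return ax
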