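"""End-to-end pipeline: config file in, TSV report set + manifest out.

Stages run in a fixed order (QC → ROH detection → summaries → inbreeding
→ islands → annotation); every stage's tables are written before the next
begins, and a JSON manifest records parameter values, input checksums,
per-table row counts and the package version so a run is auditable and
reproducible. The realized minimum-SNP count and the measured mean
heterozygosity — intermediates a reader cannot recover from the outputs
alone — are logged and stored in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import genes as _genes
from . import io as _io
from .model import RohStudy, RohStudyResults
from .qc import QcThresholds
from .roh import RohParams

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see ``RunConfig.from_yaml``)."""

    # input: either a PED/MAP pair, a PLINK binary prefix, or a VCF
    ped: str | None = None
    map: str | None = None
    bfile: str | None = None
    vcf: str | None = None
    chrom_lengths: str | None = None
    gene_models: str | None = None
    out_dir: str = "rohscan_out"
    qc: QcThresholds = field(default_factory=QcThresholds)
    roh: RohParams = field(default_factory=RohParams)
    island_top_fraction: float = 0.01
    min_island_snps: int = 2
    apply_qc: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc_kw = raw.pop("qc", {}) or {}
        if "autosomes" in qc_kw:
            qc_kw["autosomes"] = frozenset(str(c) for c in qc_kw["autosomes"])
        roh_kw = raw.pop("roh", {}) or {}
        known = {f for f in cls.__dataclass_fields__} - {"qc", "roh"}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(qc=QcThresholds(**qc_kw), roh=RohParams(**roh_kw), **raw)

    def validate(self) -> None:
        """Check referenced paths before any compute."""
        has_input = bool(self.vcf) or bool(self.bfile) or (bool(self.ped) and bool(self.map))
        if not has_input:
            raise PipelineError(
                "config must provide ped+map, bfile, or vcf as genotype input"
            )
        for name in ("ped", "map", "vcf", "chrom_lengths", "gene_models"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config path {name}={p!r} does not exist")
        if self.bfile is not None:
            for ext in (".bed", ".bim", ".fam"):
                if not Path(self.bfile).with_suffix(ext).exists():
                    raise PipelineError(f"missing PLINK binary file {self.bfile}{ext}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RohStudyResults:
    """Run the full chain and write reports + manifest to ``out_dir``.

    On stage failure the exception names the failing stage, a FAILED
    marker file is written and partial outputs are retained.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    inputs: dict[str, str] = {}
    stage = "read-genotypes"
    try:
        if config.vcf:
            panel = _io.read_vcf(config.vcf)
            inputs[config.vcf] = _sha256(config.vcf)
        elif config.bfile:
            panel = _io.read_bed_bim_fam(config.bfile)
            for ext in (".bed", ".bim", ".fam"):
                p = str(Path(config.bfile).with_suffix(ext))
                inputs[p] = _sha256(p)
        else:
            panel = _io.read_ped_map(config.ped, config.map)
            inputs[config.ped] = _sha256(config.ped)
            inputs[config.map] = _sha256(config.map)

        chrom_lengths = None
        if config.chrom_lengths:
            chrom_lengths = _io.read_chromosome_lengths(config.chrom_lengths)
            inputs[config.chrom_lengths] = _sha256(config.chrom_lengths)
        gene_models = None
        if config.gene_models:
            gene_models = _genes.read_gene_models(config.gene_models)
            inputs[config.gene_models] = _sha256(config.gene_models)

        stage = "fit"
        study = RohStudy(
            panel,
            qc_thresholds=config.qc,
            roh_params=config.roh,
            chrom_lengths=chrom_lengths,
            island_top_fraction=config.island_top_fraction,
            min_island_snps=config.min_island_snps,
            gene_models=gene_models,
            apply_qc=config.apply_qc,
        )
        results = study.fit()
        logger.info(
            "mean heterozygosity %.4f; realized minimum SNPs per run %d",
            results.mean_heterozygosity,
            results.min_roh_snps,
        )

        stage = "write-reports"
        written = results.save_reports(out_dir)
        (out_dir / "summary.txt").write_text(results.summary() + "\n")

        stage = "manifest"
        manifest = {
            "rohscan_version": __version__,
            "parameters": {
                "qc": {
                    k: (sorted(v) if isinstance(v, frozenset) else v)
                    for k, v in vars(config.qc).items()
                },
                "roh": vars(config.roh),
                "island_top_fraction": config.island_top_fraction,
                "min_island_snps": config.min_island_snps,
                "apply_qc": config.apply_qc,
                "seed": config.seed,
            },
            "input_checksums": inputs,
            "mean_heterozygosity": results.mean_heterozygosity,
            "min_roh_snps": results.min_roh_snps,
            "island_incidence_threshold": results.island_incidence_threshold,
            "row_counts": {
                "segments": len(results.segments),
                "profiles": len(results.profiles),
                "islands": len(results.islands),
                "incidence": len(results.incidence),
            },
            "reports": [p.name for p in written],
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results


def replicate_study(
    dataset_prefix: str | Path,
    chrom_lengths_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> RohStudyResults:
    """Re-run the full analysis on a deposited PLINK dataset.

    ``dataset_prefix`` points at a PED/MAP pair or a BED/BIM/FAM fileset
    (extension-less prefix). Defaults reproduce the published settings:
    standard QC thresholds, 50-SNP windows, alpha 0.05, 1 Mb gap/length,
    1 SNP per 100 kb, top-1% island rule.
    """
    prefix = Path(dataset_prefix)
    if prefix.with_suffix(".bed").exists():
        panel = _io.read_bed_bim_fam(prefix)
    elif prefix.with_suffix(".ped").exists():
        panel = _io.read_ped_map(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    else:
        raise FileNotFoundError(
            f"no PLINK dataset found at prefix {prefix} (.bed/.bim/.fam or .ped/.map)"
        )
    chrom_lengths = (
        _io.read_chromosome_lengths(chrom_lengths_path) if chrom_lengths_path else None
    )
    results = RohStudy(panel, chrom_lengths=chrom_lengths).fit()
    if out_dir is not None:
        results.save_reports(out_dir)
    return results
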