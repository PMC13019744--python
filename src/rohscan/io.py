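"""Readers and writers for standard SNP-array genotype formats.

Supported inputs: PLINK text (PED/MAP), PLINK binary (BED/BIM/FAM,
SNP-major) and VCF (GT field, biallelic records). All readers produce the
same :class:`~rohscan.panel.GenotypePanel` semantics, and write→read
round-trips preserve the genotype code matrix exactly.

Allele A/B assignment for PED input follows the first-seen rule: the first
non-missing allele observed at a marker becomes ``allele_a``. Homozygosity
analyses depend only on the hom/het/missing state, never on which allele
is which. Because PED text stores bare allele letters (no A1/A2
declaration), a PED round-trip preserves the hom/het/missing partition
exactly but may swap the two homozygous classes at markers whose first
non-missing genotype is homozygous for allele B; binary BED/BIM/FAM and
VCF round-trips are code-exact, and a second PED round-trip is a fixed
point.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    GenotypePanel,
    PanelError,
    SnpRecord,
)

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK .bed codes -> panel codes (00 hom A1, 01 missing, 10 het, 11 hom A2)
_BED_DECODE = np.array([HOM_A, MISSING, HET, HOM_B], dtype=np.int8)
_BED_ENCODE = np.empty(4, dtype=np.uint8)
_BED_ENCODE[HOM_A] = 0b00
_BED_ENCODE[MISSING] = 0b01
_BED_ENCODE[HET] = 0b10
_BED_ENCODE[HOM_B] = 0b11


class FormatError(ValueError):
    """File does not conform to its declared format."""


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------
def read_map(map_path: str | Path) -> list[SnpRecord]:
    """Read a PLINK MAP file (chrom, snp_id, cM, position) in file order."""
    records: list[SnpRecord] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise FormatError(f"{map_path}: line {ln}: expected 4 columns, got {len(fields)}")
            records.append(
                SnpRecord(
                    snp_id=fields[1],
                    chromosome=fields[0],
                    position_bp=int(fields[3]),
                )
            )
    return records


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypePanel:
    """Read a PLINK PED/MAP pair into a genotype panel.

    One individual per PED row (6 metadata columns, then two allele
    columns per MAP marker). A "0 0" allele pair is a missing call.
    Markers are re-sorted by (chromosome, position, snp_id) and the call
    matrix permuted to match.
    """
    snps_in = read_map(map_path)
    n_snps = len(snps_in)

    individual_ids: list[str] = []
    sexes: list[str] = []
    rows: list[np.ndarray] = []
    # first-seen allele per marker; index 0 -> allele_a, 1 -> allele_b
    alleles: list[list[str]] = [[] for _ in range(n_snps)]

    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}: row {ln} has {len(fields)} fields; expected "
                    f"{6 + 2 * n_snps} for {n_snps} markers"
                )
            individual_ids.append(fields[1])
            sexes.append(fields[4])
            row = np.empty(n_snps, dtype=np.int8)
            for j in range(n_snps):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                row[j] = _encode_allele_pair(a1, a2, alleles[j], snps_in[j].snp_id, ln)
            rows.append(row)

    calls = np.vstack(rows) if rows else np.empty((0, n_snps), dtype=np.int8)
    snps = [
        SnpRecord(
            snp_id=s.snp_id,
            chromosome=s.chromosome,
            position_bp=s.position_bp,
            allele_a=alleles[j][0] if len(alleles[j]) > 0 else "A",
            allele_b=alleles[j][1] if len(alleles[j]) > 1 else "B",
        )
        for j, s in enumerate(snps_in)
    ]
    return GenotypePanel.from_unsorted(individual_ids, snps, calls, sexes)


def _encode_allele_pair(
    a1: str, a2: str, seen: list[str], snp_id: str, row: int
) -> int:
    if a1 == "0" or a2 == "0":
        if a1 != a2:
            raise FormatError(
                f"row {row}, SNP {snp_id}: half-missing genotype {a1!r}/{a2!r}"
            )
        return MISSING
    for a in (a1, a2):
        if a not in seen:
            if len(seen) >= 2:
                raise FormatError(
                    f"row {row}, SNP {snp_id}: more than two alleles observed "
                    f"({seen + [a]})"
                )
            seen.append(a)
    if a1 != a2:
        return HET
    return HOM_A if a1 == seen[0] else HOM_B


def write_ped_map(panel: GenotypePanel, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a panel as a PLINK PED/MAP pair."""
    with open(map_path, "w") as fh:
        for s in panel.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\n")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(panel.individual_ids):
            parts = [f"FAM{i + 1}", iid, "0", "0", panel.sexes[i], "-9"]
            row = panel.calls[i]
            for j, s in enumerate(panel.snps):
                code = row[j]
                if code == MISSING:
                    parts += ["0", "0"]
                elif code == HOM_A:
                    parts += [s.allele_a, s.allele_a]
                elif code == HOM_B:
                    parts += [s.allele_b, s.allele_b]
                else:
                    parts += [s.allele_a, s.allele_b]
            fh.write(" ".join(parts) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM, SNP-major)
# ---------------------------------------------------------------------------
def read_bed_bim_fam(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK binary fileset ``prefix.bed/.bim/.fam``."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp", "a1", "a2"],
        dtype={"chromosome": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    n_ind, n_snps = len(fam), len(bim)

    data = Path(prefix.with_suffix(".bed")).read_bytes()
    if data[:2] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes {data[:2]!r}")
    if len(data) < 3 or data[2] != _SNP_MAJOR:
        raise FormatError(f"{prefix}.bed: not in SNP-major mode")
    bytes_per_snp = (n_ind + 3) // 4
    expected = 3 + bytes_per_snp * n_snps
    if len(data) != expected:
        raise FormatError(
            f"{prefix}.bed: expected {expected} bytes for {n_ind} individuals x "
            f"{n_snps} SNPs, found {len(data)}"
        )
    raw = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(n_snps, bytes_per_snp)
    # unpack the 2-bit fields, low bits first within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = _BED_DECODE[two_bit.reshape(n_snps, -1)[:, :n_ind]]  # (snps, ind)

    snps = [
        SnpRecord(
            snp_id=r.snp_id,
            chromosome=str(r.chromosome),
            position_bp=int(r.position_bp),
            allele_a=r.a1,
            allele_b=r.a2,
        )
        for r in bim.itertuples()
    ]
    return GenotypePanel.from_unsorted(
        fam["iid"].tolist(), snps, np.ascontiguousarray(codes.T), fam["sex"].tolist()
    )


def write_bed_bim_fam(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as a PLINK binary fileset (SNP-major)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in panel.snps:
            fh.write(
                f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\t{s.allele_a}\t{s.allele_b}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, iid in enumerate(panel.individual_ids):
            fh.write(f"FAM{i + 1} {iid} 0 0 {panel.sexes[i]} -9\n")

    n_ind = panel.n_individuals
    pad = (-n_ind) % 4
    codes = _BED_ENCODE[panel.calls.T]  # (snps, ind), 2-bit values
    if pad:
        codes = np.pad(codes, ((0, 0), (0, pad)), constant_values=_BED_ENCODE[MISSING])
    grouped = codes.reshape(panel.n_snps, -1, 4).astype(np.uint8)
    packed = (
        grouped[:, :, 0]
        | (grouped[:, :, 1] << 2)
        | (grouped[:, :, 2] << 4)
        | (grouped[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------
def read_vcf(vcf_path: str | Path) -> GenotypePanel:
    """Read biallelic GT calls from a VCF into a panel.

    Records that are not biallelic SNVs are skipped (the skip count is
    logged). 0/0 → HOM_A, 0/1 or 1/0 → HET, 1/1 → HOM_B, ./. → MISSING;
    phasing is ignored. REF becomes allele_a, ALT allele_b.
    """
    import pysam

    with pysam.VariantFile(str(vcf_path)) as vf:
        if "GT" not in vf.header.formats:
            raise FormatError(f"{vcf_path}: no GT key in FORMAT header")
        sample_ids = list(vf.header.samples)
        snps: list[SnpRecord] = []
        columns: list[np.ndarray] = []
        n_skipped = 0
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            col = np.empty(len(sample_ids), dtype=np.int8)
            for k, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    col[k] = MISSING
                else:
                    n_alt = sum(gt)
                    col[k] = (HOM_A, HET, HOM_B)[n_alt]
            snps.append(
                SnpRecord(
                    snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chromosome=str(rec.chrom),
                    position_bp=int(rec.pos),
                    allele_a=rec.ref or "N",
                    allele_b=rec.alts[0],
                )
            )
            columns.append(col)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic records", n_skipped)
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypePanel.from_unsorted(sample_ids, snps, calls)


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------
def read_chromosome_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column (label, length_bp) TSV; a header line is tolerated."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or line.startswith("#"):
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}: line {ln}: need 2 columns")
            try:
                out[fields[0]] = int(float(fields[1]))
            except ValueError:
                if ln == 1:  # header
                    continue
                raise FormatError(f"{path}: line {ln}: bad length {fields[1]!r}")
    if not out:
        raise FormatError(f"{path}: no chromosome lengths found")
    return out


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------
def _fmt(value, decimals: int = 4) -> str:
    if isinstance(value, float):
        return f"{value:.{decimals}f}"
    return str(value)


def write_tsv(
    df: pd.DataFrame, path: str | Path, float_decimals: int = 4, mb_decimals: int = 2
) -> None:
    """Write a DataFrame as TSV with fixed float formatting.

    Columns whose name ends in ``_mb`` (megabase summaries) are printed
    with ``mb_decimals`` digits, other floats with ``float_decimals``.
    """
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            dec = mb_decimals if str(col).lower().endswith("_mb") or str(col).lower().endswith("pct") else float_decimals
            out[col] = out[col].map(lambda v, d=dec: "" if pd.isna(v) else f"{v:.{d}f}")
    out.to_csv(path, sep="\t", index=False)


def write_islands_bed(islands: pd.DataFrame, path: str | Path) -> None:
    """Write islands as 0-based half-open BED for interoperability."""
    with open(path, "w") as fh:
        for i, row in enumerate(islands.itertuples(), start=1):
            fh.write(
                f"{row.chromosome}\t{row.start_bp - 1}\t{row.end_bp}\tisland_{i}\n"
            )


def write_reports(results, out_dir: str | Path) -> list[Path]:
    """Write the full TSV report set for a fitted study.

    ``results`` is a :class:`rohscan.model.RohStudyResults` (or any object
    exposing the same DataFrame attributes). Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame | None, name: str, **kw) -> None:
        if df is None:
            return
        path = out_dir / name
        write_tsv(df, path, **kw)
        written.append(path)

    emit(getattr(results, "segments", None), "roh_segments.tsv")
    emit(getattr(results, "class_summary", None), "roh_class_summary.tsv")
    emit(getattr(results, "chrom_summary", None), "chromosome_summary.tsv")
    emit(getattr(results, "profiles", None), "inbreeding.tsv")
    emit(getattr(results, "correlations", None), "correlations.tsv")
    qc_report = getattr(results, "qc_report", None)
    if qc_report is not None:
        emit(qc_report.to_frame(), "qc_report.tsv")
    islands = getattr(results, "islands", None)
    if islands is not None:
        island_table = islands.copy()
        if "genes" in island_table.columns:
            island_table["genes"] = island_table["genes"].map(
                lambda g: ",".join(g) if isinstance(g, (list, tuple)) else (g or "")
            )
        emit(island_table, "islands.tsv")
        bed_path = out_dir / "islands.bed"
        write_islands_bed(islands, bed_path)
        written.append(bed_path)
    incidence = getattr(results, "incidence", None)
    emit(incidence, "snp_incidence.tsv")
    return written
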