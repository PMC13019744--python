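"""Gene-model input for island annotation (GFF3 or BED)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


class GeneModelError(ValueError):
    """Unreadable or malformed gene-model file."""


def read_gene_models(path: str | Path, feature_type: str = "gene") -> pd.DataFrame:
    """Read gene intervals from a GFF3 or BED file.

    Returns a DataFrame with columns ``chromosome, start_bp, end_bp,
    gene_id`` on 1-based closed coordinates. GFF3 files are filtered to
    ``feature_type`` records (gene identifiers from the Name or ID
    attribute); BED files need at least four columns and are converted
    from 0-based half-open coordinates.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".gff", ".gff3", ".gtf"}:
        return _read_gff3(path, feature_type)
    if suffix == ".bed":
        return _read_bed(path)
    # sniff: GFF3 lines have 9 tab-separated columns with '=' attributes
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return (
                _read_gff3(path, feature_type)
                if len(line.rstrip("\n").split("\t")) >= 8
                else _read_bed(path)
            )
    raise GeneModelError(f"{path}: empty gene-model file")


def _read_gff3(path: Path, feature_type: str) -> pd.DataFrame:
    import pyranges as pr

    gr = pr.read_gff3(str(path))
    df = gr.df
    if feature_type and "Feature" in df.columns:
        df = df[df["Feature"] == feature_type]
    if df.empty:
        raise GeneModelError(f"{path}: no {feature_type!r} records found")
    name = df["Name"] if "Name" in df.columns else pd.Series(index=df.index, dtype=object)
    ident = df["ID"] if "ID" in df.columns else pd.Series(index=df.index, dtype=object)
    gene_id = name.fillna(ident)
    if gene_id.isna().any():
        gene_id = gene_id.fillna(
            df["Chromosome"].astype(str) + ":" + (df["Start"] + 1).astype(str)
        )
    return pd.DataFrame(
        {
            "chromosome": df["Chromosome"].astype(str).to_numpy(),
            "start_bp": (df["Start"] + 1).astype(int).to_numpy(),  # 0-based -> 1-based
            "end_bp": df["End"].astype(int).to_numpy(),
            "gene_id": gene_id.astype(str).to_numpy(),
        }
    )


def _read_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4:
                raise GeneModelError(f"{path}: line {ln}: BED needs >= 4 columns")
            rows.append(
                {
                    "chromosome": fields[0],
                    "start_bp": int(fields[1]) + 1,
                    "end_bp": int(fields[2]),
                    "gene_id": fields[3],
                }
            )
    if not rows:
        raise GeneModelError(f"{path}: no gene records found")
    return pd.DataFrame(rows)
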