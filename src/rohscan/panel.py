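"""In-memory representation of a diploid SNP-array genotype panel.

The panel is the central container of the package: an ordered set of
individuals, an ordered map of markers (sorted by chromosome block and
1-based physical position) and a dense ``int8`` matrix of genotype codes.
Genotypes are collapsed to four states — homozygous for allele A,
heterozygous, homozygous for allele B, missing — which is all the
downstream homozygosity analyses need; allele identity is retained per
marker for round-tripping the standard file formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Genotype codes. Kept as small ints so the calls matrix is a compact
# numpy array; MISSING deliberately sorts last.
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = 3

GENOTYPE_CODES = (HOM_A, HET, HOM_B, MISSING)

#: Human-readable names, index-aligned with the codes above.
CODE_NAMES = ("HOM_A", "HET", "HOM_B", "MISSING")


class PanelError(ValueError):
    """Malformed or inconsistent genotype panel input."""


@dataclass(frozen=True)
class SnpRecord:
    """One array marker.

    Positions are 1-based and inclusive throughout the package, matching
    the PLINK MAP/BIM convention.
    """

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise PanelError(
                f"SNP {self.snp_id}: position_bp must be >= 0, got {self.position_bp}"
            )


@dataclass
class GenotypePanel:
    """Individuals × SNPs genotype matrix with marker metadata.

    Parameters
    ----------
    individual_ids
        Ordered, unique individual identifiers (matrix rows).
    snps
        Ordered markers (matrix columns). Must be sorted by chromosome
        block and strictly ascending position within a chromosome; use
        :meth:`from_unsorted` when the input order is arbitrary.
    calls
        ``int8`` matrix of genotype codes, shape ``(n_individuals, n_snps)``.
    sexes
        Optional per-individual sex codes ("1" male, "2" female, "0"
        unknown, PLINK convention). Informational only.
    """

    individual_ids: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray
    sexes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individual_ids), len(self.snps)):
            raise PanelError(
                f"calls matrix shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snps)} SNPs"
            )
        if self.calls.size and (
            self.calls.min() < HOM_A or self.calls.max() > MISSING
        ):
            raise PanelError("calls matrix contains codes outside {0,1,2,3}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise PanelError("duplicate individual identifiers")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            raise PanelError(f"duplicate snp_id values: {dupes[:5]}")
        if not self.sexes:
            self.sexes = ["0"] * len(self.individual_ids)
        self._check_sorted()

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_unsorted(
        cls,
        individual_ids: list[str],
        snps: list[SnpRecord],
        calls: np.ndarray,
        sexes: list[str] | None = None,
    ) -> "GenotypePanel":
        """Build a panel from arbitrarily ordered markers.

        Markers are sorted by (chromosome, position, snp_id) — the snp_id
        tie-break makes the sort deterministic for duplicated positions —
        and the calls matrix columns are permuted to match. Chromosomes
        are ordered numerically when their labels are integers, otherwise
        lexicographically after all numeric labels.
        """
        order = sorted(
            range(len(snps)),
            key=lambda i: (
                _chrom_sort_key(snps[i].chromosome),
                snps[i].position_bp,
                snps[i].snp_id,
            ),
        )
        calls = np.asarray(calls, dtype=np.int8)
        return cls(
            individual_ids=list(individual_ids),
            snps=[snps[i] for i in order],
            calls=calls[:, order] if calls.size else calls.reshape(len(individual_ids), 0),
            sexes=list(sexes) if sexes else [],
        )

    def _check_sorted(self) -> None:
        prev_chrom: str | None = None
        prev_pos = -1
        seen: set[str] = set()
        for s in self.snps:
            if s.chromosome != prev_chrom:
                if s.chromosome in seen:
                    raise PanelError(
                        f"chromosome {s.chromosome!r} appears in non-contiguous blocks"
                    )
                seen.add(s.chromosome)
                prev_chrom = s.chromosome
                prev_pos = -1
            if s.position_bp < prev_pos:
                raise PanelError(
                    f"SNPs not sorted by position within chromosome {s.chromosome!r} "
                    f"(position {s.position_bp} after {prev_pos})"
                )
            prev_pos = s.position_bp

    # ------------------------------------------------------------------
    # basic properties
    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in panel order (one entry per block)."""
        out: list[str] = []
        for s in self.snps:
            if not out or out[-1] != s.chromosome:
                out.append(s.chromosome)
        return out

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position_bp for s in self.snps], dtype=np.int64)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def snp_chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps], dtype=object)

    def snp_table(self) -> pd.DataFrame:
        """Marker metadata as a DataFrame (snp_id, chromosome, position_bp, alleles)."""
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chromosome": self.snp_chromosomes,
                "position_bp": self.positions,
                "allele_a": [s.allele_a for s in self.snps],
                "allele_b": [s.allele_b for s in self.snps],
            }
        )

    def chromosome_slices(self) -> dict[str, slice]:
        """Column slice of the calls matrix for each chromosome block."""
        out: dict[str, slice] = {}
        start = 0
        chroms = self.snp_chromosomes
        for i in range(1, self.n_snps + 1):
            if i == self.n_snps or chroms[i] != chroms[start]:
                out[str(chroms[start])] = slice(start, i)
                start = i
        return out

    # ------------------------------------------------------------------
    # per-marker / per-individual statistics used by QC and F_HOM
    # ------------------------------------------------------------------
    def snp_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return 1.0 - (self.calls == MISSING).mean(axis=0)

    def individual_missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per individual."""
        return (self.calls == MISSING).mean(axis=1)

    def allele_b_frequency(self) -> np.ndarray:
        """Sample frequency of allele B per SNP, from non-missing calls.

        SNPs with no non-missing calls get NaN.
        """
        het = (self.calls == HET).sum(axis=0)
        hom_b = (self.calls == HOM_B).sum(axis=0)
        n_obs = (self.calls != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, (2.0 * hom_b + het) / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP; always in [0, 0.5] (NaN if all missing)."""
        p = self.allele_b_frequency()
        return np.minimum(p, 1.0 - p)

    # ------------------------------------------------------------------
    # subsetting
    # ------------------------------------------------------------------
    def subset(
        self,
        individual_mask: np.ndarray | None = None,
        snp_mask: np.ndarray | None = None,
    ) -> "GenotypePanel":
        """Return a new panel restricted to the masked rows/columns."""
        imask = (
            np.ones(self.n_individuals, dtype=bool)
            if individual_mask is None
            else np.asarray(individual_mask, dtype=bool)
        )
        smask = (
            np.ones(self.n_snps, dtype=bool)
            if snp_mask is None
            else np.asarray(snp_mask, dtype=bool)
        )
        return GenotypePanel(
            individual_ids=[x for x, k in zip(self.individual_ids, imask) if k],
            snps=[s for s, k in zip(self.snps, smask) if k],
            calls=self.calls[np.ix_(imask, smask)],
            sexes=[x for x, k in zip(self.sexes, imask) if k],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.snps == other.snps
            and np.array_equal(self.calls, other.calls)
        )


def _chrom_sort_key(label: str) -> tuple[int, float, str]:
    """Sort numeric chromosome labels numerically, then others lexically."""
    try:
        return (0, float(int(label)), "")
    except (TypeError, ValueError):
        return (1, 0.0, str(label))


def default_autosome_labels(n: int = 29) -> set[str]:
    """Numeric autosome labels "1".."n" (goat has 29 autosomes)."""
    return {str(i) for i in range(1, n + 1)}
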