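"""Phased haplotype panels: I/O, genotype derivation, allele frequencies and LD.

The central container is :class:`HaplotypePanel`, a binary matrix of phased
haplotypes (two consecutive rows per individual) with per-variant metadata.
Allele coding is panel-relative: 1 is always the *minor* allele (frequency
< 0.5 in the full panel; ties at 0.5 code the ALT allele as minor), so that
genotypes 0/1/2 count minor alleles uniformly downstream.

Genotype triples and genotype-frequency vectors throughout the package are
ordered by minor-allele count: index 0 = homozygous major, 1 = heterozygous,
2 = homozygous minor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypePanel",
    "GenotypeTable",
    "LDStats",
    "JointGenotypeFreq",
    "read_vcf",
    "write_vcf",
    "read_hapmatrix",
    "write_hapmatrix",
    "ld_stats",
    "joint_genotype_freq",
    "ld_summary",
]


class PanelFormatError(ValueError):
    """Raised for malformed or unsupported panel input (unphased, missing GT, ...)."""


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes for a gene region.

    Parameters
    ----------
    haplotypes
        ``(2N, M)`` int8 matrix, one row per haplotype; rows ``2i`` and
        ``2i+1`` belong to individual ``i``.  Entries are 0 (major allele)
        or 1 (minor allele).
    variant_meta
        One row per variant with columns ``id``, ``pos``, ``ref``, ``alt``,
        ``maf`` (and optionally ``minor_is_alt``), ordered by position.
    """

    haplotypes: np.ndarray
    variant_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype row count must be even (two per individual)")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 or 1")
        if len(self.variant_meta) != self.haplotypes.shape[1]:
            raise ValueError("variant_meta length does not match haplotype columns")
        maf = self.maf()
        if (maf <= 0).any():
            bad = list(self.variant_meta["id"][maf <= 0])
            raise ValueError(f"monomorphic columns are not allowed: {bad}")
        if "maf" in self.variant_meta:
            declared = np.asarray(self.variant_meta["maf"], dtype=float)
            if not np.allclose(declared, maf, atol=1e-12, rtol=0.0):
                raise ValueError("variant_meta MAF disagrees with haplotype matrix")
        else:
            self.variant_meta = self.variant_meta.assign(maf=maf)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant, recomputed from the matrix."""
        return self.haplotypes.mean(axis=0)

    def genotypes(self) -> np.ndarray:
        """``(N, M)`` minor-allele counts per individual."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def genotype_table(self, label: str) -> "GenotypeTable":
        """View the panel as a labelled genotype table (phase retained)."""
        n = self.n_individuals
        return GenotypeTable(
            genotypes=self.genotypes(),
            labels=np.full(n, label),
            haplotypes=self.haplotypes,
        )

    def take_individuals(self, indices: np.ndarray) -> np.ndarray:
        """Haplotype rows for the given individual indices (pairs kept together)."""
        rows = np.empty(2 * len(indices), dtype=np.intp)
        rows[0::2] = 2 * np.asarray(indices)
        rows[1::2] = rows[0::2] + 1
        return self.haplotypes[rows]


@dataclass
class GenotypeTable:
    """Genotypes (0/1/2 minor-allele counts) with case/control labels.

    ``haplotypes`` is carried along whenever the table was derived from phased
    data; the model search needs it for virtual-variant collapsing and for the
    rare-homozygote haplotype-pairing fallback.
    """

    genotypes: np.ndarray
    labels: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        self.labels = np.asarray(self.labels)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must be 0, 1 or 2")
        if len(self.labels) != self.genotypes.shape[0]:
            raise ValueError("labels length does not match individuals")
        if self.haplotypes is not None:
            derived = self.haplotypes[0::2] + self.haplotypes[1::2]
            if not np.array_equal(derived, self.genotypes):
                raise ValueError("genotypes do not equal the sum of haplotype pairs")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class LDStats:
    """Pairwise linkage-disequilibrium summary between two variants."""

    D: float
    D_prime: float
    r2: float
    maf_i: float
    maf_j: float


@dataclass(frozen=True)
class JointGenotypeFreq:
    """Empirical 3x3 table ``P(G_i = a, D_j = b)`` of genotype co-occurrence.

    Rows index the candidate-variant genotype ``a``, columns the disease-variant
    genotype ``b`` (both 0/1/2 minor-allele counts).
    """

    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (3, 3):
            raise ValueError("joint genotype table must be 3x3")
        if not np.isclose(t.sum(), 1.0, atol=1e-9):
            raise ValueError("joint genotype table must sum to 1")
        object.__setattr__(self, "table", t)

    @property
    def candidate_margin(self) -> np.ndarray:
        return self.table.sum(axis=1)

    @property
    def disease_margin(self) -> np.ndarray:
        return self.table.sum(axis=0)


# ---------------------------------------------------------------------------
# VCF input / output


def read_vcf(path: str, maf_min: float = 0.001) -> HaplotypePanel:
    """Read phased biallelic SNVs from a VCF into a :class:`HaplotypePanel`.

    Multi-allelic records and variants with MAF <= ``maf_min`` are excluded
    (counts logged).  Unphased or missing genotype calls are hard errors: the
    downstream frequency algebra assumes complete phased genotypes and no
    imputation is attempted.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    columns: list[np.ndarray] = []
    meta_rows: list[dict] = []
    n_multi = n_rare = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        alleles = np.empty(2 * len(var.genotypes), dtype=np.int8)
        for s, gt in enumerate(var.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise PanelFormatError(
                    f"missing genotype at {var.CHROM}:{var.POS} sample index {s}"
                )
            if not phased:
                raise PanelFormatError(
                    f"unphased genotype at {var.CHROM}:{var.POS} sample index {s}"
                )
            alleles[2 * s] = a
            alleles[2 * s + 1] = b
        alt_freq = alleles.mean()
        minor_is_alt = alt_freq <= 0.5  # tie at 0.5 -> ALT is "minor"
        col = alleles if minor_is_alt else (1 - alleles)
        maf = col.mean()
        if maf <= maf_min:
            n_rare += 1
            continue
        columns.append(col)
        meta_rows.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "maf": maf,
                "minor_is_alt": minor_is_alt,
            }
        )
    if n_multi or n_rare:
        logger.info(
            "read_vcf excluded %d multi-allelic and %d MAF<=%g records",
            n_multi,
            n_rare,
            maf_min,
        )
    if not columns:
        raise PanelFormatError(f"no usable phased biallelic variants in {path}")
    order = np.argsort([r["pos"] for r in meta_rows], kind="stable")
    hap = np.column_stack([columns[k] for k in order])
    meta = pd.DataFrame([meta_rows[k] for k in order])
    return HaplotypePanel(haplotypes=hap, variant_meta=meta)


def write_vcf(panel: HaplotypePanel, path: str, chrom: str = "19") -> None:
    """Write the panel as a minimal phased VCF 4.2 text file.

    The 1-coded (minor) allele is written as ALT when the panel was built with
    ALT minor, otherwise REF/ALT are swapped back per ``minor_is_alt``.
    """
    meta = panel.variant_meta
    n = panel.n_individuals
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"I{i}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for v in range(panel.n_variants):
            row = meta.iloc[v]
            minor_is_alt = bool(row.get("minor_is_alt", True))
            col = panel.haplotypes[:, v] if minor_is_alt else 1 - panel.haplotypes[:, v]
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n))
            fh.write(
                f"{chrom}\t{row['pos']}\t{row['id']}\t{row.get('ref', 'A')}\t"
                f"{row.get('alt', 'T')}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Haplotype-matrix CSV (header of variant ids; one row of 0/1 per haplotype;
# consecutive row pairs are individuals)


def write_hapmatrix(panel: HaplotypePanel, path: str) -> None:
    ids = list(panel.variant_meta["id"])
    with open(path, "w") as fh:
        fh.write(",".join(str(i) for i in ids) + "\n")
        np.savetxt(fh, panel.haplotypes, fmt="%d", delimiter=",")


def read_hapmatrix(path: str, positions: np.ndarray | None = None) -> HaplotypePanel:
    with open(path) as fh:
        header = fh.readline().strip()
        ids = header.split(",")
        hap = np.loadtxt(fh, dtype=np.int8, delimiter=",", ndmin=2)
    if positions is None:
        positions = np.arange(1, len(ids) + 1)
    meta = pd.DataFrame({"id": ids, "pos": positions, "ref": "A", "alt": "T"})
    return HaplotypePanel(haplotypes=hap, variant_meta=meta)


# ---------------------------------------------------------------------------
# LD statistics


def ld_stats(panel: HaplotypePanel, i: int, j: int) -> LDStats:
    """D, D' and r^2 between variants ``i`` and ``j`` from haplotype counts.

    Frequencies are of the 1-coded (minor) alleles; ``D = p_ij - p_i p_j``
    with ``p_ij`` the frequency of haplotypes carrying both minor alleles.
    """
    if i == j:
        raise ValueError("ld_stats requires two distinct variants")
    a = panel.haplotypes[:, i].astype(float)
    b = panel.haplotypes[:, j].astype(float)
    p_i = a.mean()
    p_j = b.mean()
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        raise ValueError("r^2 undefined for a monomorphic column")
    p_ij = (a * b).mean()
    D = p_ij - p_i * p_j
    if D >= 0:
        d_max = min(p_i * (1 - p_j), (1 - p_i) * p_j)
    else:
        d_max = min(p_i * p_j, (1 - p_i) * (1 - p_j))
    d_prime = D / d_max if d_max > 0 else 0.0
    r2 = D * D / (p_i * (1 - p_i) * p_j * (1 - p_j))
    return LDStats(D=D, D_prime=d_prime, r2=r2, maf_i=p_i, maf_j=p_j)


def joint_genotype_freq(g_i: np.ndarray, d_j: np.ndarray) -> JointGenotypeFreq:
    """Empirical joint genotype-frequency table between two genotype vectors."""
    g = np.asarray(g_i)
    d = np.asarray(d_j)
    if g.size == 0 or d.size == 0:
        raise ValueError("empty genotype vector")
    if g.shape != d.shape:
        raise ValueError("genotype vectors must have equal length")
    if not (np.isin(g, (0, 1, 2)).all() and np.isin(d, (0, 1, 2)).all()):
        raise ValueError("genotypes must be 0, 1 or 2")
    counts = np.bincount(3 * g.astype(np.intp) + d.astype(np.intp), minlength=9)
    return JointGenotypeFreq(table=counts.reshape(3, 3) / g.size)


def ld_summary(panel: HaplotypePanel) -> pd.DataFrame:
    """All-pairs LD table (one row per unordered variant pair)."""
    ids = list(panel.variant_meta["id"])
    rows = []
    for i in range(panel.n_variants):
        for j in range(i + 1, panel.n_variants):
            s = ld_stats(panel, i, j)
            rows.append(
                {
                    "id_i": ids[i],
                    "id_j": ids[j],
                    "maf_i": s.maf_i,
                    "maf_j": s.maf_j,
                    "D": s.D,
                    "D_prime": s.D_prime,
                    "r2": s.r2,
                }
            )
    return pd.DataFrame(rows)
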