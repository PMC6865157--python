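"""Collapse a set of putative disease variants into one virtual variant.

All member variants are assumed to damage the gene in the same way, so a
haplotype is a *disease haplotype* as soon as it carries a minor allele at
any member (two disease alleles on one haplotype still count once).  The
collapse is defined on haplotypes; individual genotypes (0/1/2 disease
haplotypes) are derived from the haplotype pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_io import HaplotypePanel

__all__ = ["VirtualVariant", "collapse"]


@dataclass(frozen=True)
class VirtualVariant:
    """The composite disease variant for a member set."""

    member_indices: tuple
    hap_alleles: np.ndarray  # (2N,) 1 = disease haplotype
    genotypes: np.ndarray  # (N,) disease-haplotype count per individual

    @property
    def allele_freq(self) -> float:
        return float(self.hap_alleles.mean())

    def genotype_freqs(self) -> np.ndarray:
        """Observed genotype triple (dd, Dd, DD) over the individuals."""
        return np.bincount(self.genotypes, minlength=3)[:3] / len(self.genotypes)


def collapse(panel: HaplotypePanel | np.ndarray, member_indices) -> VirtualVariant:
    """Build the virtual disease variant for ``member_indices``.

    ``panel`` may be a :class:`HaplotypePanel` or a raw ``(2N, M)`` phased
    0/1 haplotype matrix.  Order and multiplicity of the indices are
    irrelevant; the empty set is rejected.
    """
    hap = panel.haplotypes if isinstance(panel, HaplotypePanel) else np.asarray(panel)
    idx = tuple(sorted(set(int(i) for i in np.atleast_1d(np.asarray(member_indices)))))
    if not idx:
        raise ValueError("member_indices must be non-empty")
    if min(idx) < 0 or max(idx) >= hap.shape[1]:
        raise IndexError(f"variant index out of range for panel with {hap.shape[1]} columns")
    alleles = hap[:, idx].max(axis=1).astype(np.int8)
    genotypes = (alleles[0::2] + alleles[1::2]).astype(np.int8)
    return VirtualVariant(member_indices=idx, hap_alleles=alleles, genotypes=genotypes)
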