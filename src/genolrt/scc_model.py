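"""Sufficient-causal-component (SCC) disease-model calculus.

Under the SCC view a complex disease occurs when any one *sufficient cause*
is completed; the studied gene is a single component of one such cause (a
gene-gene or gene-environment mechanism).  Let ``y`` be the proportion of the
population lifetime incidence (PLI) attributable to that focal cause.  In the
case population the disease genotypes of the gene gain a total probability
mass ``y`` (split in proportion to their shares in the population), while
normal genotypes are scaled by ``1 - y``.  Because the PLI is small (~1%),
control genotype frequencies are taken equal to population frequencies.

Genotype triples are ordered by disease-allele count: index 0 = dd
(homozygous normal), 1 = Dd, 2 = DD.  "Dominant" means {Dd, DD} are disease
genotypes; "recessive" means {DD} only.  The odds ratio is the *allelic* odds
ratio between case and control disease-allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiseaseModel",
    "DiseaseGenotypeFreqs",
    "InfeasibleModelError",
    "case_genotype_freqs",
    "or_from_y",
    "y_from_or",
    "max_dominant_or",
    "penetrance",
    "allele_freq",
    "hwe_freqs",
]

MODES = ("dominant", "recessive")


class InfeasibleModelError(ValueError):
    """The requested effect size cannot be produced by any y in [0, 1]."""


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _check_triple(freqs) -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if f.shape != (3,):
        raise ValueError("genotype frequencies must be a length-3 triple (dd, Dd, DD)")
    if (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("genotype frequencies must be a simplex")
    return np.clip(f, 0.0, None)


def _disease_mask(mode: str) -> np.ndarray:
    _check_mode(mode)
    if mode == "dominant":
        return np.array([False, True, True])
    return np.array([False, False, True])


def allele_freq(freqs) -> float:
    """Disease-allele frequency implied by a genotype triple (dd, Dd, DD)."""
    f = _check_triple(freqs)
    return float(f[1] / 2 + f[2])


def hwe_freqs(q: float) -> np.ndarray:
    """Hardy-Weinberg genotype triple (dd, Dd, DD) at disease-allele frequency q."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


@dataclass(frozen=True)
class DiseaseGenotypeFreqs:
    """Control- and case-side genotype triples for a disease variant."""

    control: np.ndarray
    case: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "control", _check_triple(self.control))
        object.__setattr__(self, "case", _check_triple(self.case))


@dataclass(frozen=True)
class DiseaseModel:
    """A candidate disease-variant model: member variants, mode, effect size.

    Exactly one of ``odds_ratio`` (allelic OR) or ``y`` (proportion of the
    focal sufficient cause in the PLI) must be given.  ``pli`` is the
    population lifetime incidence.
    """

    variant_indices: tuple
    mode: str
    odds_ratio: float | None = None
    y: float | None = None
    pli: float = 0.01

    def __post_init__(self) -> None:
        _check_mode(self.mode)
        idx = tuple(sorted(set(int(i) for i in np.atleast_1d(self.variant_indices))))
        if not idx:
            raise ValueError("variant_indices must be non-empty")
        object.__setattr__(self, "variant_indices", idx)
        if (self.odds_ratio is None) == (self.y is None):
            raise ValueError("specify exactly one of odds_ratio or y")
        if self.y is not None and not 0.0 <= self.y <= 1.0:
            raise ValueError("y must be in [0, 1]")
        if self.odds_ratio is not None and self.odds_ratio < 1.0:
            raise ValueError("odds_ratio must be >= 1")
        if not 0.0 < self.pli < 1.0:
            raise ValueError("pli must be in (0, 1)")

    def proportion(self, control_freqs) -> float:
        """The proportion y, converting from the odds ratio when necessary."""
        if self.y is not None:
            return float(self.y)
        return y_from_or(control_freqs, self.odds_ratio, self.mode)


def case_genotype_freqs(control_freqs, y: float, mode: str) -> np.ndarray:
    """Case genotype triple implied by control frequencies and proportion y.

    Disease genotypes gain mass ``y`` apportioned by their control-population
    shares within the disease-genotype class; normal genotypes are scaled by
    ``1 - y``.
    """
    f = _check_triple(control_freqs)
    if not 0.0 <= y <= 1.0:
        raise ValueError("y must be in [0, 1]")
    mask = _disease_mask(mode)
    m = f[mask].sum()
    if y > 0 and m == 0:
        raise InfeasibleModelError(
            "disease-genotype mass is zero in controls; no y > 0 is satisfiable"
        )
    out = f * (1.0 - y)
    if m > 0:
        out[mask] += y * f[mask] / m
    return out


def or_from_y(control_freqs, y: float, mode: str) -> float:
    """Allelic odds ratio implied by proportion y."""
    f = _check_triple(control_freqs)
    p = allele_freq(f)
    if p in (0.0, 1.0):
        raise ValueError("allelic odds undefined for a monomorphic disease allele")
    p_case = allele_freq(case_genotype_freqs(f, y, mode))
    if p_case == 1.0:
        return float("inf")
    return (p_case / (1 - p_case)) / (p / (1 - p))


def max_dominant_or(control_freqs) -> float:
    """Feasibility bound for dominant variants: ``2(1 - P_DD)/P_Dd - 1``.

    Dominant mixing can raise the case disease-allele frequency at most to
    its share within the carrier class (reached at y = 1); odds ratios above
    the bound are unattainable for the given genotype frequencies.
    """
    f = _check_triple(control_freqs)
    p_dd_hom, p_het = f[2], f[1]
    if p_het == 0:
        raise ValueError("bound undefined when the heterozygote frequency is zero")
    return 2.0 * (1.0 - p_dd_hom) / p_het - 1.0


def y_from_or(control_freqs, odds_ratio: float, mode: str) -> float:
    """Proportion y implied by an allelic odds ratio (inverse of or_from_y).

    The case allele frequency is linear in y: ``p' = (1 - y) p + y c`` where
    ``c`` is the disease-allele frequency within the disease-genotype class
    (c = 1 for recessive).  Solving the allelic-odds identity for y is exact.
    """
    f = _check_triple(control_freqs)
    _check_mode(mode)
    if odds_ratio < 1.0:
        raise ValueError("odds_ratio must be >= 1")
    p = allele_freq(f)
    if p in (0.0, 1.0):
        raise ValueError("allelic odds undefined for a monomorphic disease allele")
    mask = _disease_mask(mode)
    m = f[mask].sum()
    if m == 0:
        raise InfeasibleModelError("disease-genotype mass is zero in controls")
    if mode == "dominant":
        c = (f[1] / 2 + f[2]) / m
    else:
        c = 1.0
    odds_case = odds_ratio * p / (1 - p)
    p_case = odds_case / (1 + odds_case)
    if c <= p:
        raise InfeasibleModelError("no y can raise the allele frequency (c <= p)")
    y = (p_case - p) / (c - p)
    if y > 1.0 + 1e-9:
        bound = max_dominant_or(f) if mode == "dominant" else float("inf")
        raise InfeasibleModelError(
            f"odds ratio {odds_ratio} infeasible for these genotype frequencies "
            f"(maximum attainable OR is {bound:.6g})"
        )
    return float(min(max(y, 0.0), 1.0))


def penetrance(control_freqs, y: float, pli: float, mode: str) -> float:
    """P(disease | disease genotype) under the SCC model.

    The focal sufficient cause completes with probability ``y * pli / m``
    for a carrier of a disease genotype (``m`` = disease-genotype mass);
    background causes strike independently with probability ``(1 - y) * pli``.
    """
    f = _check_triple(control_freqs)
    if not 0.0 < pli < 1.0:
        raise ValueError("pli must be in (0, 1)")
    if not 0.0 <= y <= 1.0:
        raise ValueError("y must be in [0, 1]")
    mask = _disease_mask(mode)
    m = f[mask].sum()
    if m == 0:
        raise InfeasibleModelError("disease-genotype mass is zero")
    focal = y * pli / m
    if focal > 1.0:
        raise InfeasibleModelError(
            "y * pli exceeds the disease-genotype mass; penetrance > 1 is impossible"
        )
    background = (1.0 - y) * pli
    return focal + background - focal * background
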