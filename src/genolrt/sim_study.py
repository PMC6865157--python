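"""Case-control simulation from a haplotype panel and error-rate estimation.

The panel plays the role of the reference population.  Controls are sampled
directly from its individuals; cases are built by drawing disease-variant
genotype counts from the multinomial implied by the SCC model and sampling
individuals conditioned on that genotype, so every case carries a full,
phased, LD-consistent genotype vector.  When a required rare homozygote
class is absent from the panel, the individual is constructed by pairing two
independently sampled disease haplotypes.

Type I error is the probability of rejecting the true model; Type II error
the probability that the exhaustive search fails to return exactly the true
member set, with partial identifications (a proper non-empty subset) and
wrong identifications (a non-member accepted) tallied separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_search import identify, test_model
from .panel_io import GenotypeTable, HaplotypePanel
from .scc_model import DiseaseModel, case_genotype_freqs
from .virtual_variant import collapse

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "ErrorRates",
    "generate_case_control",
    "type1_error",
    "type2_error",
]


@dataclass
class SimulationConfig:
    """One simulation scenario: panel, true model, sample sizes, level."""

    panel: HaplotypePanel
    model: DiseaseModel
    n_cases: int = 500
    n_controls: int = 500
    n_sims: int = 1000
    alpha: float = 0.05
    reps: int = 1000
    enrich: float = 0.2
    max_model_size: int = 1
    seed: int | None = None
    controls_with_replacement: bool = True

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1 or self.n_sims < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ErrorRates:
    """Estimated error rates with exact (Clopper-Pearson) 95% intervals."""

    type1: float | None = None
    type1_ci: tuple | None = None
    type2: float | None = None
    type2_ci: tuple | None = None
    partial_id: float | None = None
    partial_id_ci: tuple | None = None
    wrong_id: float | None = None
    wrong_id_ci: tuple | None = None
    n_sims: int = 0
    accepted_models: tuple = ()


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple:
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a, k + 1, n - k))
    return lo, hi


def population_disease_freqs(panel: HaplotypePanel, model: DiseaseModel) -> np.ndarray:
    """Panel genotype triple of the model's virtual variant (dd, Dd, DD).

    Genotype classes unobserved in the panel (rare homozygotes) receive their
    random-union-of-gametes expectation so that the SCC mixing has a nonzero
    class to load; the triple is renormalized.
    """
    virt = collapse(panel, model.variant_indices)
    freqs = np.bincount(virt.genotypes, minlength=3)[:3] / panel.n_individuals
    q = virt.allele_freq
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    missing = freqs == 0
    if missing.any():
        logger.info(
            "panel lacks virtual-variant genotype classes %s; filling with "
            "random-mating expectation", np.flatnonzero(missing).tolist(),
        )
        freqs = freqs.copy()
        freqs[missing] = expected[missing]
        freqs /= freqs.sum()
    return freqs


def _pair_haplotypes(panel: HaplotypePanel, disease_mask: np.ndarray,
                     j: int, count: int, rng: np.random.Generator) -> np.ndarray:
    """Construct ``count`` individuals with j disease haplotypes by sampling
    haplotypes independently from the panel's disease / normal pools."""
    dis_rows = np.flatnonzero(disease_mask)
    nor_rows = np.flatnonzero(~disease_mask)
    hap = np.empty((2 * count, panel.n_variants), dtype=np.int8)
    first = dis_rows if j >= 1 else nor_rows
    second = dis_rows if j == 2 else nor_rows
    hap[0::2] = panel.haplotypes[rng.choice(first, size=count)]
    hap[1::2] = panel.haplotypes[rng.choice(second, size=count)]
    return hap


def generate_case_control(
    panel: HaplotypePanel,
    model: DiseaseModel,
    n_cases: int = 500,
    n_controls: int = 500,
    seed=None,
    controls_with_replacement: bool = True,
) -> tuple[GenotypeTable, GenotypeTable]:
    """Draw a case sample and a control sample from the panel under the model.

    Controls are sampled from panel individuals (with replacement by
    default).  Case disease-genotype counts follow the multinomial with the
    SCC case triple; each case is a panel individual sampled conditioned on
    that virtual genotype, falling back to pairing two sampled disease
    haplotypes when the class is absent from the panel.  Deterministic given
    the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    virt = collapse(panel, model.variant_indices)
    ctrl_freqs = population_disease_freqs(panel, model)
    y = model.proportion(ctrl_freqs)
    case_freqs = case_genotype_freqs(ctrl_freqs, y, model.mode)

    counts = rng.multinomial(n_cases, case_freqs)
    strata = [np.flatnonzero(virt.genotypes == j) for j in range(3)]
    disease_mask = virt.hap_alleles.astype(bool)
    blocks = []
    n_paired = 0
    for j in range(3):
        if counts[j] == 0:
            continue
        if strata[j].size > 0:
            idx = rng.choice(strata[j], size=counts[j])
            blocks.append(panel.take_individuals(idx))
        else:
            blocks.append(_pair_haplotypes(panel, disease_mask, j, counts[j], rng))
            n_paired += counts[j]
    if n_paired:
        logger.info("constructed %d cases by haplotype pairing", n_paired)
    case_hap = np.vstack(blocks)
    perm = rng.permutation(n_cases)
    rows = np.empty(2 * n_cases, dtype=np.intp)
    rows[0::2] = 2 * perm
    rows[1::2] = rows[0::2] + 1
    case_hap = case_hap[rows]

    if controls_with_replacement:
        ctrl_idx = rng.choice(panel.n_individuals, size=n_controls)
    else:
        if n_controls > panel.n_individuals:
            raise ValueError("n_controls exceeds panel size without replacement")
        ctrl_idx = rng.choice(panel.n_individuals, size=n_controls, replace=False)
    ctrl_hap = panel.take_individuals(ctrl_idx)

    cases = GenotypeTable(
        genotypes=case_hap[0::2] + case_hap[1::2],
        labels=np.full(n_cases, "case"),
        haplotypes=case_hap,
    )
    controls = GenotypeTable(
        genotypes=ctrl_hap[0::2] + ctrl_hap[1::2],
        labels=np.full(n_controls, "control"),
        haplotypes=ctrl_hap,
    )
    return cases, controls


def type1_error(config: SimulationConfig) -> ErrorRates:
    """Rejection rate of the TRUE model over simulated replicates."""
    rng = np.random.default_rng(config.seed)
    rejections = 0
    for _ in range(config.n_sims):
        cases, controls = generate_case_control(
            config.panel, config.model, config.n_cases, config.n_controls,
            seed=rng, controls_with_replacement=config.controls_with_replacement,
        )
        res = test_model(
            cases, controls, config.model.variant_indices,
            reps=config.reps, enrich=config.enrich, seed=rng, alpha=config.alpha,
        )
        rejections += int(res.p_lower >= 1.0 - config.alpha)
    return ErrorRates(
        type1=rejections / config.n_sims,
        type1_ci=_clopper_pearson(rejections, config.n_sims),
        n_sims=config.n_sims,
    )


def null_statistics(config: SimulationConfig) -> pd.DataFrame:
    """Total statistic / df / p_lower of the true model per replicate.

    Shares the machinery of :func:`type1_error`; used to examine the
    chi-square calibration of the summed statistic.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for _ in range(config.n_sims):
        cases, controls = generate_case_control(
            config.panel, config.model, config.n_cases, config.n_controls,
            seed=rng, controls_with_replacement=config.controls_with_replacement,
        )
        res = test_model(
            cases, controls, config.model.variant_indices,
            reps=config.reps, enrich=config.enrich, seed=rng, alpha=config.alpha,
        )
        rows.append(
            {
                "total_statistic": res.total_statistic,
                "total_df": res.total_df,
                "p_lower": res.p_lower,
            }
        )
    return pd.DataFrame(rows)


def type2_error(config: SimulationConfig) -> ErrorRates:
    """Failure rate of the exhaustive search to recover the exact true set."""
    rng = np.random.default_rng(config.seed)
    true_set = tuple(sorted(config.model.variant_indices))
    failures = partial = wrong = 0
    accepted_models: list = []
    for _ in range(config.n_sims):
        cases, controls = generate_case_control(
            config.panel, config.model, config.n_cases, config.n_controls,
            seed=rng, controls_with_replacement=config.controls_with_replacement,
        )
        res = identify(
            cases, controls, max_model_size=config.max_model_size,
            alpha=config.alpha, reps=config.reps, enrich=config.enrich,
            seed=int(rng.integers(2**31 - 1)),
        )
        accepted = res.accepted_model
        accepted_models.append(accepted)
        if accepted == true_set:
            continue
        failures += 1
        if accepted is not None:
            acc = set(accepted)
            if acc and acc < set(true_set):
                partial += 1
            if acc - set(true_set):
                wrong += 1
    n = config.n_sims
    return ErrorRates(
        type2=failures / n,
        type2_ci=_clopper_pearson(failures, n),
        partial_id=partial / n,
        partial_id_ci=_clopper_pearson(partial, n),
        wrong_id=wrong / n,
        wrong_id_ci=_clopper_pearson(wrong, n),
        n_sims=n,
        accepted_models=tuple(accepted_models),
    )
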