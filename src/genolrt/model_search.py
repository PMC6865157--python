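"""Exhaustive disease-variant model search over a gene region.

A *model* is a candidate set of disease variants.  Testing a model collapses
its members into one virtual disease variant, estimates the case-side
disease genotype triple P(D') from the case sample, predicts every candidate
variant's case genotype frequencies through genotype-level LD with the
virtual variant, and sums the variance-corrected likelihood-ratio statistics
over all candidate variants in the region.  Under the true model the total
statistic follows chi-square with the summed degrees of freedom, so a model
is *accepted* when its lower-tail chi-square probability p_lower is below
1 - alpha (i.e. the statistic is not in the upper alpha tail); a wrong model
drives some candidate's observed frequencies far from their LD prediction
and p_lower toward 1.

The search tests all 1-variant models, then all 2-variant models, and so on,
stopping at the first size with any accepted model and returning the one
with the smallest p_lower (ties broken by lexicographically smallest index
set).  The test itself is independent of the dominance mode: it conditions
only on genotype frequencies, so mode enters the simulation machinery, not
the search.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotypic_lrt import (
    LRTResult,
    _multinomial_g,
    calibrated_statistic,
    candidate_conditionals,
    genotype_class_groups,
    group_counts,
    multinomial_covariance,
)
from .panel_io import GenotypeTable
from .virtual_variant import VirtualVariant, collapse

logger = logging.getLogger(__name__)

__all__ = ["ModelTestResult", "SearchResult", "test_model", "identify"]


@dataclass(frozen=True)
class ModelTestResult:
    """Per-model summed LRT over all candidate variants in the region."""

    model: tuple
    total_statistic: float
    total_df: int
    p_lower: float
    accepted: bool
    per_variant: tuple = ()
    skipped_variants: tuple = ()
    pairing_fallbacks: int = 0


@dataclass(frozen=True)
class SearchResult:
    """Outcome of the exhaustive search plus its audit trail."""

    accepted_model: tuple | None
    all_results: tuple
    models_tested: int
    alpha: float

    def results_for_size(self, size: int) -> list[ModelTestResult]:
        return [r for r in self.all_results if len(r.model) == size]


def _require_phased(table: GenotypeTable, what: str) -> np.ndarray:
    if table.haplotypes is None:
        raise ValueError(
            f"{what} must carry phased haplotypes (virtual-variant collapse "
            "and the rare-homozygote fallback are haplotype-level operations)"
        )
    return table.haplotypes


def _value_counts(codes: np.ndarray, n_values: int) -> np.ndarray:
    """Occurrence counts of each code value along axis 1 of (reps, n, M)."""
    out = np.empty((codes.shape[0], n_values) + codes.shape[2:], dtype=np.int64)
    for v in range(n_values):
        out[:, v] = (codes == v).sum(axis=1)
    return out


def _region_null_resample(
    ctrl_geno: np.ndarray,
    case_geno: np.ndarray,
    d_ctrl: np.ndarray,
    d_case_geno: np.ndarray,
    d_case: np.ndarray,
    d_counts: np.ndarray,
    reps: int,
    enrich: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint resampling of the whole region under the tested model.

    If the tested model is true, a case individual and a control individual
    with the same disease-variant genotype are exchangeable: both are draws
    from the population conditional on that genotype.  Each replicate
    therefore re-partitions the combined individuals of every
    disease-genotype stratum at random into a pseudo control set (the
    observed per-stratum control count) and a pseudo case set (the observed
    per-stratum case count), and the test statistics are recomputed on the
    pseudo data.  Whole individuals are exchanged, so every candidate
    variant's statistic is evaluated on the same pseudo sample and the
    correlation between candidates' statistics -- they share individuals
    and LD -- is preserved in the resampled totals.

    Returns ``(case_counts, ctrl_counts)``: pseudo-case genotype-class
    counts of shape (reps, 3, M) and per-stratum pseudo-control class
    counts of shape (reps, 3, 3, M) indexed (replicate, stratum, class,
    candidate).
    """
    n_ctrl, m = ctrl_geno.shape
    case_counts = np.zeros((reps, 3, m), dtype=np.int64)
    ctrl_counts = np.zeros((reps, 3, 3, m), dtype=np.int64)
    for j in range(3):
        if d_case[j] == 0.0:
            continue
        ctrl_members = ctrl_geno[d_ctrl == j]
        case_members = case_geno[d_case_geno == j]
        pool = np.vstack([ctrl_members, case_members])
        n_c = ctrl_members.shape[0]
        n_j = int(d_counts[j])
        # random re-partition of the stratum into control and case roles
        order = np.argsort(rng.random((reps, pool.shape[0])), axis=1)
        if n_c:
            ctrl_counts[:, j] = _value_counts(pool[order[:, :n_c]], 3)
        if n_j:
            case_counts += _value_counts(pool[order[:, n_c:]], 3)
    return case_counts, ctrl_counts


def test_model(
    cases: GenotypeTable,
    controls: GenotypeTable,
    model,
    reps: int = 1000,
    enrich: float = 0.2,
    seed=None,
    alpha: float = 0.05,
) -> ModelTestResult:
    """Test one disease-variant model against the full region.

    P(D') is estimated from the case sample's virtual-variant genotype
    frequencies (the test conditions on them rather than assuming an effect
    size).  Every candidate variant's observed statistic is referred to the
    joint resampling null (:func:`_region_null_resample`): the per-variant
    statistics are mapped onto the chi-square scale through their marginal
    resampled ranks, and the summed statistic's probability ``p_lower`` is
    the rank of the observed total among the resampled totals, so the
    acceptance rule operates at its nominal level even though candidate
    statistics are correlated through LD.  Candidate variants monomorphic
    in the control sample contribute no term (no LD expectation can be
    formed without control carriers) and are reported in
    ``skipped_variants``.
    """
    case_hap = _require_phased(cases, "cases")
    ctrl_hap = _require_phased(controls, "controls")
    if cases.n_variants != controls.n_variants:
        raise ValueError("cases and controls must share variant columns")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = tuple(sorted(set(int(i) for i in np.atleast_1d(np.asarray(model)))))

    virt_ctrl = collapse(ctrl_hap, model)
    if virt_ctrl.hap_alleles.min() == virt_ctrl.hap_alleles.max():
        raise ValueError("virtual disease variant is monomorphic in controls")
    virt_case = collapse(case_hap, model)
    # the conditional genotype tables are estimated within disease-genotype
    # strata; a homozygote stratum with fewer than 5 control individuals
    # cannot support that estimate, so it is analysed jointly with the
    # heterozygote (carrier) stratum
    d_ctrl_geno = virt_ctrl.genotypes
    d_case_geno = virt_case.genotypes
    if np.bincount(d_ctrl_geno, minlength=3)[2] < 5:
        d_ctrl_geno = np.minimum(d_ctrl_geno, 1)
        d_case_geno = np.minimum(d_case_geno, 1)
    d_counts_case = np.bincount(d_case_geno, minlength=3)[:3]
    n_cases = cases.n_individuals
    d_case = d_counts_case / n_cases
    virt_ctrl = VirtualVariant(
        member_indices=virt_ctrl.member_indices,
        hap_alleles=virt_ctrl.hap_alleles,
        genotypes=d_ctrl_geno,
    )

    ctrl_geno = controls.genotypes
    case_geno = cases.genotypes
    m = cases.n_variants

    # observed per-candidate ingredients
    cand_rows = []
    skipped: list[int] = []
    fallbacks = 0
    for cand in range(m):
        col = ctrl_geno[:, cand]
        if col.min() == col.max():
            skipped.append(cand)
            continue
        carriers = int((col > 0).sum() + (case_geno[:, cand] > 0).sum())
        non_carriers = int((col < 2).sum() + (case_geno[:, cand] < 2).sum())
        if min(carriers, non_carriers) < 8:
            # too few exchangeable carriers to anchor a resampling null
            skipped.append(cand)
            continue
        cond, fb = candidate_conditionals(
            ctrl_hap, virt_ctrl, cand, require=d_case > 0
        )
        fallbacks += int(fb)
        pi = cond.T @ d_case
        groups = genotype_class_groups(pi, n_cases)
        if len(groups) < 2:
            skipped.append(cand)
            continue
        obs = group_counts(np.bincount(case_geno[:, cand], minlength=3)[:3], groups)
        pig = group_counts(pi, groups)
        g_obs = float(_multinomial_g(obs[None, :], n_cases * pig[None, :])[0])
        sigma_model = multinomial_covariance(pi, n_cases)
        det_model = float(np.linalg.det(sigma_model)) if sigma_model.size else 1.0
        cand_rows.append({"cand": cand, "groups": groups, "g_obs": g_obs,
                          "det_model": det_model})
    if not cand_rows:
        raise ValueError("no testable candidate variants in the region")

    case_counts, ctrl_counts = _region_null_resample(
        ctrl_geno, case_geno, d_ctrl_geno, d_case_geno, d_case,
        d_counts_case, reps, enrich, rng,
    )
    stratum_sizes = ctrl_counts.sum(axis=2)  # (reps, 3, M)

    per_variant: list[LRTResult] = []
    t_obs_list = []
    t_star = np.zeros((reps, 0))
    total_stat = 0.0
    total_df = 0
    for row in cand_rows:
        cand = row["cand"]
        groups = row["groups"]
        df_cand = len(groups) - 1
        joint = ctrl_counts[:, :, :, cand]  # (reps, D, G)
        sizes = stratum_sizes[:, :, cand]
        with np.errstate(invalid="ignore", divide="ignore"):
            cond_star = np.where(sizes[:, :, None] > 0, joint / np.maximum(sizes, 1)[:, :, None], 0.0)
        pi_star = np.einsum("j,rjg->rg", d_case, cond_star)
        pig_star = group_counts(pi_star, groups)
        xg_star = group_counts(case_counts[:, :, cand], groups)
        # a pseudo-control set stranded without a genotype class yields an
        # effectively infinite pseudo statistic; the floor keeps it finite
        # and rank-equivalent
        pig_star = np.maximum(pig_star, 1e-12)
        g_star = _multinomial_g(xg_star, n_cases * pig_star)
        if g_star.max() - g_star.min() < 1e-12:
            # no resampling variability: the candidate is determined by the
            # disease variant (e.g. the model's own member); not testable
            skipped.append(cand)
            continue
        # marginal chi-square-scale calibration of the observed statistic
        statistic, p_cand = calibrated_statistic(row["g_obs"], g_star, df_cand)
        # and of each resampled statistic (its own rank within the null)
        ranks = stats.rankdata(g_star, method="average")
        t_star_cand = stats.chi2.ppf(ranks / (reps + 1.0), df_cand)
        t_star = np.column_stack([t_star, t_star_cand])
        det_sim = float(np.var(g_star))  # bookkeeping: spread of the null statistics
        res = LRTResult(
            statistic=statistic, df=df_cand, det_sigma_model=row["det_model"],
            det_sigma_sim=det_sim, p_lower=p_cand, raw_statistic=row["g_obs"],
            low_precision=reps < 30,
        )
        per_variant.append(res)
        t_obs_list.append(statistic)
        total_stat += statistic
        total_df += df_cand

    if total_df == 0:
        raise ValueError("no testable candidate variants in the region")
    totals_star = t_star.sum(axis=1)
    r = float((totals_star < total_stat).sum() + 0.5 * (totals_star == total_stat).sum())
    p_lower = (r + 0.5) / (reps + 1.0)
    return ModelTestResult(
        model=model,
        total_statistic=total_stat,
        total_df=total_df,
        p_lower=float(p_lower),
        accepted=p_lower < 1.0 - alpha,
        per_variant=tuple(per_variant),
        skipped_variants=tuple(sorted(skipped)),
        pairing_fallbacks=fallbacks,
    )


def identify(
    cases: GenotypeTable,
    controls: GenotypeTable,
    max_model_size: int = 1,
    alpha: float = 0.05,
    reps: int = 1000,
    enrich: float = 0.2,
    seed: int | None = None,
) -> SearchResult:
    """Exhaustively search disease-variant models of growing size.

    For each size s = 1..max_model_size all C(M, s) member sets are tested;
    at the first size with any accepted model the accepted model with the
    smallest p_lower is returned (ties broken by lexicographic order of the
    index set, logged).  Per-model randomness is keyed on (seed, model), so
    results do not depend on enumeration order.
    """
    if max_model_size < 1:
        raise ValueError("max_model_size must be >= 1")
    m = cases.n_variants
    all_results: list[ModelTestResult] = []
    accepted_model: tuple | None = None
    for size in range(1, max_model_size + 1):
        accepted_here: list[ModelTestResult] = []
        for model in itertools.combinations(range(m), size):
            child = np.random.default_rng(
                np.random.SeedSequence([0 if seed is None else int(seed), *model])
            )
            try:
                res = test_model(
                    cases, controls, model, reps=reps, enrich=enrich,
                    seed=child, alpha=alpha,
                )
            except ValueError as exc:
                # e.g. the model's virtual variant is monomorphic in this
                # control sample: the model cannot be evaluated, hence never
                # accepted
                logger.debug("model %s untestable: %s", model, exc)
                continue
            all_results.append(res)
            if res.accepted:
                accepted_here.append(res)
        if accepted_here:
            best = min(accepted_here, key=lambda r: (r.p_lower, r.model))
            ties = [r for r in accepted_here if r.p_lower == best.p_lower]
            if len(ties) > 1:
                logger.info(
                    "p_lower tie among %s; choosing lexicographically smallest %s",
                    [r.model for r in ties],
                    best.model,
                )
            accepted_model = best.model
            break
    return SearchResult(
        accepted_model=accepted_model,
        all_results=tuple(all_results),
        models_tested=len(all_results),
        alpha=alpha,
    )
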