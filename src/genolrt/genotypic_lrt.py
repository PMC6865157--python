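"""Variance-corrected multinomial likelihood-ratio test on genotype frequencies.

For a candidate variant with genotypes G and a (virtual) disease variant D,
the expected case genotype frequencies are obtained through genotype-level
LD with the disease variant,

    pi_i = sum_j  P(G_i D_j) / P(D_j) * P(D_j'),

where unprimed frequencies come from the control sample and P(D_j') is the
case-side disease-variant genotype triple.  Working with genotype-level joint
frequencies (not allele-level LD under HWE) carries the panel's natural
deviations from Hardy-Weinberg equilibrium into the expectation.

The test statistic is the multinomial log-likelihood ratio of the observed
case genotype counts against pi, rescaled by a variance correction: |Sigma|
is the determinant of the model-based multinomial covariance of the first
k-1 genotype counts, |sigma| the determinant of the covariance observed when
pseudo-case samples are repeatedly reconstructed from the finite control
sample.  The corrected statistic

    T = 2 * sum_i o_i log(o_i / (n pi_i)) * (|Sigma| / |sigma|)^(1/(k-1))

is referred to chi-square(k-1); the correction deflates (or inflates) the
statistic by the geometric-mean per-dimension variance ratio and equals 1
when |sigma| = |Sigma|.

In the model search the correction is applied on the likelihood scale: the
resampler replays the whole pipeline (case reconstruction from controls,
re-estimation of the conditional table from a bootstrap control sample) and
evaluates the statistic on every pseudo-sample; the observed G is referred
to that resampled null distribution and mapped onto the chi-square(k-1)
scale through its rank (:func:`calibrated_statistic`).  When the resampled
counts are plain multinomial this reduces to the determinant-ratio
rescaling above; in sparse genotype classes it additionally absorbs the
finite-sample shape of the log-likelihood ratio, which a scalar variance
ratio cannot.  The chi-square calibration of the true-model null
distribution is the property that pins this transcription down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel_io import JointGenotypeFreq
from .virtual_variant import VirtualVariant

__all__ = [
    "CaseExpectation",
    "LRTResult",
    "SimulatedVariance",
    "expected_case_freqs",
    "candidate_conditionals",
    "multinomial_covariance",
    "simulated_variance",
    "lrt_statistic",
    "genotype_class_groups",
    "group_counts",
    "calibrated_statistic",
]


@dataclass(frozen=True)
class CaseExpectation:
    """Expected case genotype frequencies for one candidate variant."""

    pi: np.ndarray
    disease_case_freqs: np.ndarray
    joint: JointGenotypeFreq | None = None


@dataclass(frozen=True)
class LRTResult:
    """One corrected likelihood-ratio statistic and its bookkeeping."""

    statistic: float
    df: int
    det_sigma_model: float
    det_sigma_sim: float
    p_lower: float
    raw_statistic: float = float("nan")
    low_precision: bool = False


@dataclass(frozen=True)
class SimulatedVariance:
    """Resampling summary of pseudo-case genotype counts.

    ``det`` is the determinant |sigma| of the empirical covariance of the
    pseudo-case count deviations (first k-1 categories); ``statistics`` the
    resampled null distribution of the log-likelihood-ratio statistic, which
    carries the same variance-ratio information as the determinant (its mean
    is ``(k-1) * (|sigma|/|Sigma|)^(1/(k-1))`` to first order for
    multinomial pseudo-counts) while also reflecting the statistic's own
    finite-sample shape in sparse genotype classes.
    """

    det: float
    cov: np.ndarray
    kept: np.ndarray
    statistics: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mean_statistic: float = float("nan")
    low_precision: bool = False
    pairing_fallback: bool = False


def expected_case_freqs(
    joint: JointGenotypeFreq, disease_case_freqs
) -> CaseExpectation:
    """Expected case genotype frequencies of a candidate through genotype LD."""
    d_case = np.asarray(disease_case_freqs, dtype=float)
    if d_case.shape != (3,) or abs(d_case.sum() - 1.0) > 1e-9 or (d_case < 0).any():
        raise ValueError("disease_case_freqs must be a genotype simplex")
    d_ctrl = joint.disease_margin
    pi = np.zeros(3)
    for j in range(3):
        if d_case[j] == 0.0:
            continue
        if d_ctrl[j] == 0.0:
            raise ValueError(
                f"disease genotype {j} has case mass but zero control mass; "
                "the case genotype class is unreachable from the controls"
            )
        pi += joint.table[:, j] / d_ctrl[j] * d_case[j]
    return CaseExpectation(pi=pi, disease_case_freqs=d_case, joint=joint)


def candidate_conditionals(
    control_haplotypes: np.ndarray,
    virtual: VirtualVariant,
    candidate: int,
    require: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Conditional table C[j, a] = P(G_candidate = a | D = j) from controls.

    Observed disease-genotype classes use the empirical genotype conditional.
    Classes absent from the control sample (typically rare homozygotes) but
    required by ``require`` (a mask of classes with case mass) are filled by
    the haplotype-pairing rule: an individual with j disease haplotypes is a
    random union of j disease and 2 - j normal haplotypes, each contributing
    the candidate allele with its class-conditional frequency.  Returns the
    3x3 table and a flag telling whether the fallback was used.
    """
    genotypes = control_haplotypes[0::2] + control_haplotypes[1::2]
    g = genotypes[:, candidate]
    d = virtual.genotypes
    counts = np.bincount(3 * d.astype(np.intp) + g.astype(np.intp), minlength=9).reshape(3, 3)
    totals = counts.sum(axis=1)
    cond = np.zeros((3, 3))
    fallback = False
    need = np.ones(3, dtype=bool) if require is None else np.asarray(require, dtype=bool)
    for j in range(3):
        if totals[j] > 0:
            cond[j] = counts[j] / totals[j]
        elif need[j]:
            fallback = True
            disease_hap = virtual.hap_alleles.astype(bool)
            n_dis = disease_hap.sum()
            n_nor = disease_hap.size - n_dis
            if (j > 0 and n_dis == 0) or (j < 2 and n_nor == 0):
                raise ValueError(
                    "virtual variant monomorphic in controls; cannot form "
                    "the haplotype-pairing fallback"
                )
            p_dis = control_haplotypes[disease_hap, candidate].mean() if j > 0 else 0.0
            p_nor = control_haplotypes[~disease_hap, candidate].mean() if j < 2 else 0.0
            # genotype = sum of j Bernoulli(p_dis) + (2-j) Bernoulli(p_nor)
            dist = np.zeros(3)
            probs = [p_dis] * j + [p_nor] * (2 - j)
            for a0 in (0, 1):
                for a1 in (0, 1):
                    w = (probs[0] if a0 else 1 - probs[0]) * (
                        probs[1] if a1 else 1 - probs[1]
                    )
                    dist[a0 + a1] += w
            cond[j] = dist
    return cond, fallback


def multinomial_covariance(pi, n: int) -> np.ndarray:
    """Multinomial covariance of the first k-1 genotype count categories.

    Categories with zero expected frequency are dropped (reducing k); the
    last remaining category is the omitted, linearly dependent one.
    """
    p = np.asarray(pi, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("pi must be a simplex")
    if n < 1:
        raise ValueError("n must be >= 1")
    kept = np.flatnonzero(p > 0)
    if kept.size < 2:
        return np.zeros((0, 0))
    q = p[kept[:-1]]
    return n * (np.diag(q) - np.outer(q, q))


def _multinomial_g(counts, pi_or_expected, n=None):
    """Row-wise multinomial G statistic of count vectors against expectations.

    ``pi_or_expected`` is either a frequency vector (with ``n`` given) or an
    array of expected counts broadcastable against ``counts``.
    """
    from scipy.special import xlogy

    expected = pi_or_expected if n is None else n * np.asarray(pi_or_expected)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = xlogy(counts, counts) - xlogy(counts, expected)
    t = np.where(counts > 0, t, 0.0)
    return 2.0 * t.sum(axis=-1)


def genotype_class_groups(pi, n: int, min_expected: float = 5.0) -> list:
    """Partition genotype classes into test categories.

    Classes with zero expected frequency are left out; classes whose
    expected case count ``n * pi`` falls below ``min_expected`` (the classic
    minimum expected cell count of 5) are pooled with the nearest retained
    class, so a rare homozygote is analysed as a carrier -- the reduction of
    rare biallelic variants to two genotype categories.  Returns a list of index arrays; fewer than two
    groups means the candidate carries no testable information.
    """
    p = np.asarray(pi, dtype=float)
    groups = {int(c): [int(c)] for c in np.flatnonzero(p > 0)}
    while len(groups) > 2:
        keys = sorted(groups)
        masses = {c: p[groups[c]].sum() for c in keys}
        small = [c for c in keys if n * masses[c] < min_expected]
        if not small:
            break
        c = small[0]
        others = [k for k in keys if k != c]
        tgt = min(others, key=lambda k: abs(k - c))
        groups[tgt].extend(groups[c])
        del groups[c]
    return [np.array(sorted(v)) for _, v in sorted(groups.items())]


def group_counts(vec, groups) -> np.ndarray:
    """Aggregate a genotype-class vector (or row-wise matrix) over groups,
    assigning any leftover classes with mass to the nearest group."""
    v = np.asarray(vec, dtype=float)
    flat = np.concatenate(groups) if groups else np.array([], dtype=int)
    out = np.stack([v[..., g].sum(axis=-1) for g in groups], axis=-1)
    for c in range(v.shape[-1]):
        if c in flat:
            continue
        extra = v[..., c]
        if np.any(extra > 0):
            gi = min(range(len(groups)), key=lambda k: np.min(np.abs(groups[k] - c)))
            out[..., gi] += extra
    return out


def simulated_variance(
    control_haplotypes: np.ndarray,
    virtual: VirtualVariant,
    disease_case_freqs,
    candidate: int,
    n_cases: int,
    reps: int = 1000,
    enrich: float = 0.2,
    seed=None,
    d_counts: np.ndarray | None = None,
    conditionals: np.ndarray | None = None,
    case_conditionals: np.ndarray | None = None,
    class_groups: list | None = None,
    min_expected: float = 5.0,
) -> SimulatedVariance:
    """Resampling-based null variability of the candidate's genotype counts.

    Each replicate replays the whole test pipeline under the hypothesis that
    the tested model is true: disease-variant genotype counts for ``n_cases``
    are realized (drawn from the multinomial with the case-side triple P(D'),
    or held at the observed case counts ``d_counts`` when the test conditions
    on them); each pseudo-case's candidate genotype is that of a randomly
    sampled individual with the corresponding disease genotype; and the
    control-side conditional genotype table -- the ingredient of the Eq.-1
    expectation -- is itself re-estimated from a bootstrap control sample,
    because the observed controls are only one draw from the reference
    population.  The pseudo-case pool mixes in a fraction ``enrich`` of case
    individuals with the same disease genotype (``case_conditionals``): for
    rare variants the controls may lack genotype classes that the cases
    carry, and the case sample keeps the null variability from collapsing
    onto an atypically thin control realization.

    Returns the determinant |sigma| of the empirical covariance of the
    pseudo-case deviations (first k-1 categories) together with the full
    resampled distribution of the log-likelihood-ratio statistic, which the
    model search uses to calibrate the observed statistic.  Deterministic
    given the seed.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not 0.0 <= enrich <= 1.0:
        raise ValueError("enrich must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d_case = np.asarray(disease_case_freqs, dtype=float)
    if conditionals is None:
        cond, fallback = candidate_conditionals(
            control_haplotypes, virtual, candidate, require=d_case > 0
        )
    else:
        cond, fallback = np.asarray(conditionals), False
    stratum_n = np.bincount(virtual.genotypes, minlength=3)[:3]
    if case_conditionals is not None and enrich > 0.0:
        c0 = (1.0 - enrich) * cond + enrich * np.asarray(case_conditionals)
    else:
        c0 = cond

    pi = cond.T @ d_case
    groups = (
        class_groups
        if class_groups is not None
        else genotype_class_groups(pi, n_cases, min_expected)
    )
    low_precision = reps < 30
    if len(groups) < 2:
        return SimulatedVariance(
            det=1.0, cov=np.zeros((0, 0)), kept=np.array([], dtype=int),
            statistics=np.zeros(reps), mean_statistic=0.0,
            low_precision=low_precision, pairing_fallback=fallback,
        )

    if d_counts is None:
        d_arr = rng.multinomial(n_cases, d_case, size=reps)
    else:
        d_arr = np.broadcast_to(np.asarray(d_counts, dtype=np.int64), (reps, 3))
    active = [j for j in range(3) if d_case[j] > 0]

    def draw_pi_star(size: int) -> np.ndarray:
        out = np.zeros((size, 3))
        for j in active:
            if stratum_n[j] > 0:
                comp = rng.multinomial(stratum_n[j], c0[j], size=size) / stratum_n[j]
            else:
                comp = np.broadcast_to(c0[j], (size, 3))
            out += d_case[j] * comp
        return out

    x = np.zeros((reps, 3))
    for j in active:
        x += rng.multinomial(d_arr[:, j], c0[j])
    pi_star = draw_pi_star(reps)
    xg = group_counts(x, groups)
    pig = group_counts(pi_star, groups)
    # a pseudo-control sample missing a whole category cannot enter the test
    # (the real pipeline skips such candidates); redraw those compositions
    for _ in range(30):
        bad = (pig <= 0).any(axis=1)
        if not bad.any():
            break
        pig[bad] = group_counts(draw_pi_star(int(bad.sum())), groups)
    pig = np.maximum(pig, 1e-12)

    statistics = _multinomial_g(xg, n_cases * pig)
    dev = xg[:, :-1] - n_cases * pig[:, :-1]
    cov = np.atleast_2d(np.cov(dev, rowvar=False)) if len(groups) > 1 else np.zeros((0, 0))
    det = float(np.linalg.det(cov)) if cov.size else 0.0
    return SimulatedVariance(
        det=det, cov=cov, kept=np.concatenate(groups),
        statistics=statistics, mean_statistic=float(statistics.mean()),
        low_precision=low_precision, pairing_fallback=fallback,
    )


def calibrated_statistic(g_obs: float, resampled: np.ndarray, df: int) -> tuple:
    """Map an observed G onto the chi-square(df) scale via its resampled null.

    The observed statistic's mid-rank among the resampled statistics is a
    probability-integral transform of the resampling null; the matching
    chi-square quantile is returned together with its lower-tail
    probability.  This realizes the variance correction exactly: when the
    resampled distribution already is chi-square(df), the statistic is
    returned unchanged (up to resampling granularity).
    """
    r = float((resampled < g_obs).sum() + 0.5 * (resampled == g_obs).sum())
    p_lower = (r + 0.5) / (len(resampled) + 1.0)
    return float(stats.chi2.ppf(p_lower, df)), float(p_lower)


def lrt_statistic(
    observed_case_counts,
    pi,
    det_model: float,
    det_sim: float,
    low_precision: bool = False,
) -> LRTResult:
    """Corrected multinomial likelihood-ratio statistic for one candidate.

    Genotype categories with zero expected frequency are dropped from k; a
    nonzero observed count in such a category rejects the model outright
    (infinite-statistic sentinel) rather than being smoothed away.
    """
    o = np.asarray(observed_case_counts, dtype=float)
    p = np.asarray(pi, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed counts and pi must align")
    if (o < 0).any() or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("invalid counts or expectation")
    n = o.sum()
    if n < 1:
        raise ValueError("no observed cases")
    impossible = (p == 0) & (o > 0)
    if impossible.any():
        return LRTResult(
            statistic=float("inf"), df=max(int((p > 0).sum()) - 1, 1),
            det_sigma_model=det_model, det_sigma_sim=det_sim, p_lower=1.0,
            raw_statistic=float("inf"), low_precision=low_precision,
        )
    keep = p > 0
    k = int(keep.sum())
    df = k - 1
    if df == 0:
        return LRTResult(
            statistic=0.0, df=0, det_sigma_model=det_model,
            det_sigma_sim=det_sim, p_lower=0.0, raw_statistic=0.0,
            low_precision=low_precision,
        )
    ok = keep & (o > 0)
    g = 2.0 * float(np.sum(o[ok] * np.log(o[ok] / (n * p[ok]))))
    g = max(g, 0.0)
    if det_sim <= 0 or det_model <= 0:
        correction = 1.0
    else:
        correction = (det_model / det_sim) ** (1.0 / df)
    statistic = g * correction
    p_lower = float(stats.chi2.cdf(statistic, df))
    return LRTResult(
        statistic=statistic, df=df, det_sigma_model=float(det_model),
        det_sigma_sim=float(det_sim), p_lower=p_lower, raw_statistic=g,
        low_precision=low_precision,
    )
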