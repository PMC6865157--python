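"""Synthetic haplotype panels with controlled MAF spectra and pairwise LD.

LD is encoded by explicit pools of haplotype classes with population
frequencies, organized in independent LD blocks, so target allele
frequencies and r^2 values are analytic properties of the pool
(:func:`pool_maf`/:func:`pool_ld`) and sampled panels converge to them.

The built-in :func:`apoe_like_config` fixture emulates the LD architecture
of the APOE gene region in a large reference sequencing panel: 33 biallelic
variants with minor-allele frequencies spanning ~0.001 to ~0.51, common
variants in strong mutual LD (r^2 of roughly 0.41-0.77) and rare variants
riding on common haplotype backgrounds (D' = 1 with low r^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import HaplotypePanel

__all__ = ["PanelConfig", "synth_panel", "apoe_like_config", "pool_maf", "pool_ld"]


@dataclass
class PanelConfig:
    """Haplotype pools plus sampling parameters.

    ``blocks`` is a list of ``(pool, frequencies)`` pairs; each pool is a
    ``(K_b, M_b)`` 0/1 matrix of distinct haplotype classes for one LD block
    and the frequencies sum to 1 within the block.  Blocks are in linkage
    equilibrium with each other.  A single-block config may be given via the
    ``haplotype_pool``/``frequencies`` convenience arguments.
    """

    blocks: list = field(default_factory=list)
    n_individuals: int = 1000
    seed: int | None = None
    variant_ids: list[str] = field(default_factory=list)
    positions: np.ndarray | None = None
    haplotype_pool: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    column_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.haplotype_pool is not None:
            if self.blocks:
                raise ValueError("give either blocks or haplotype_pool, not both")
            self.blocks = [(self.haplotype_pool, self.frequencies)]
        if not self.blocks:
            raise ValueError("at least one haplotype-pool block is required")
        norm = []
        for pool, freq in self.blocks:
            pool = np.ascontiguousarray(pool, dtype=np.int8)
            freq = np.asarray(freq, dtype=float)
            if pool.ndim != 2 or not np.isin(pool, (0, 1)).all():
                raise ValueError("pool haplotypes must be a 2-D 0/1 matrix")
            if len(freq) != pool.shape[0]:
                raise ValueError("frequencies length must match pool rows")
            if (freq < 0).any() or abs(freq.sum() - 1.0) > 1e-9:
                raise ValueError("pool frequencies must be a simplex")
            keep = freq > 0
            pool, freq = pool[keep], freq[keep]
            if pool.shape[0] < 2:
                raise ValueError("each block needs at least 2 distinct haplotypes")
            maf = freq @ pool
            if ((maf <= 0) | (maf >= 1)).any():
                raise ValueError("pool implies monomorphic variants; remove them")
            norm.append((pool, freq))
        self.blocks = norm
        self.haplotype_pool = None
        self.frequencies = None
        m = self.n_variants
        if not self.variant_ids:
            self.variant_ids = [f"v{k}" for k in range(m)]
        if len(self.variant_ids) != m:
            raise ValueError("variant_ids length must match total pool columns")
        if self.positions is None:
            self.positions = np.arange(1, m + 1) * 100
        if self.column_order is None:
            self.column_order = np.arange(m)
        else:
            self.column_order = np.asarray(self.column_order)
            if sorted(self.column_order) != list(range(m)):
                raise ValueError("column_order must be a permutation of the columns")

    @property
    def n_variants(self) -> int:
        return sum(pool.shape[1] for pool, _ in self.blocks)

    def block_of(self, index: int) -> tuple[int, int]:
        """(block index, column within block) for a global (output) variant index."""
        raw = int(self.column_order[index])
        off = 0
        for b, (pool, _) in enumerate(self.blocks):
            if raw < off + pool.shape[1]:
                return b, raw - off
            off += pool.shape[1]
        raise IndexError(index)


def pool_maf(config: PanelConfig) -> np.ndarray:
    """Exact pool-implied frequency of the 1-coded allele per variant."""
    raw = np.concatenate([freq @ pool for pool, freq in config.blocks])
    return raw[config.column_order]


def pool_ld(config: PanelConfig, i: int, j: int) -> tuple[float, float, float]:
    """Exact pool-implied (D, D', r^2) between two variants.

    Variants in different blocks are in linkage equilibrium by construction
    (D = 0 exactly).
    """
    bi, ci = config.block_of(i)
    bj, cj = config.block_of(j)
    maf = pool_maf(config)
    p_i, p_j = float(maf[i]), float(maf[j])
    if bi != bj:
        p_ij = p_i * p_j
    else:
        pool, freq = config.blocks[bi]
        p_ij = float(freq @ (pool[:, ci] * pool[:, cj]))
    D = p_ij - p_i * p_j
    if D >= 0:
        d_max = min(p_i * (1 - p_j), (1 - p_i) * p_j)
    else:
        d_max = min(p_i * p_j, (1 - p_i) * (1 - p_j))
    d_prime = D / d_max if d_max > 0 else 0.0
    r2 = D * D / (p_i * (1 - p_i) * p_j * (1 - p_j))
    return D, d_prime, r2


def synth_panel(
    config: PanelConfig,
    seed: int | None = None,
    on_monomorphic: str = "redraw",
) -> HaplotypePanel:
    """Sample a phased panel of ``n_individuals`` from the haplotype pools.

    2N haplotypes are drawn multinomially from each block's pool and paired
    at random into individuals, so observed genotype frequencies carry the
    natural random-union-of-gametes deviations from Hardy-Weinberg
    equilibrium that the genotypic test is designed around.  Deterministic
    given the seed.

    Very rare variants can come out monomorphic in a finite draw;
    ``on_monomorphic`` selects between redrawing the panel from the same
    stream (``"redraw"``, the default, keeps the full variant set) and
    excluding the affected columns (``"drop"``, mirroring how monomorphic
    sites are filtered from real sequencing panels -- the only option that
    terminates for small cohorts).
    """
    if config.n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if on_monomorphic not in ("redraw", "drop"):
        raise ValueError("on_monomorphic must be 'redraw' or 'drop'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_hap = 2 * config.n_individuals
    attempts = 100 if on_monomorphic == "redraw" else 1
    for _ in range(attempts):
        segments = []
        for pool, freq in config.blocks:
            counts = rng.multinomial(n_hap, freq)
            seg = np.repeat(pool, counts, axis=0)
            rng.shuffle(seg, axis=0)
            segments.append(seg)
        hap = np.hstack(segments)[:, config.column_order]
        maf = hap.mean(axis=0)
        polymorphic = (maf > 0) & (maf < 1)
        if polymorphic.all():
            break
    else:
        if on_monomorphic == "redraw":
            raise RuntimeError("could not draw a polymorphic panel in 100 attempts")
    meta = pd.DataFrame(
        {
            "id": config.variant_ids,
            "pos": np.asarray(config.positions),
            "ref": "A",
            "alt": "T",
        }
    )
    if not polymorphic.all():
        hap = hap[:, polymorphic]
        meta = meta[polymorphic].reset_index(drop=True)
    return HaplotypePanel(haplotypes=hap, variant_meta=meta)


def _pair_block(p1: float, p2: float, r2: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-variant block hitting the target r^2 via positive D."""
    D = np.sqrt(r2 * p1 * (1 - p1) * p2 * (1 - p2))
    p11 = D + p1 * p2
    freq = np.array([p11, p1 - p11, p2 - p11, 1 - p1 - p2 + p11])
    if (freq < -1e-12).any():
        raise ValueError("target r^2 infeasible for these frequencies")
    return (
        np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8),
        np.clip(freq, 0.0, None),
    )


def _background_block(q_bg: float, q_rares: list[float]) -> tuple[np.ndarray, np.ndarray]:
    """Rare variants on disjoint sub-backgrounds of one common variant (D' = 1)."""
    m = len(q_rares) + 1
    classes = []
    freqs = []
    for k, q in enumerate(q_rares):
        row = np.zeros(m, dtype=np.int8)
        row[k] = 1
        row[-1] = 1  # rides on the background
        classes.append(row)
        freqs.append(q)
    bg_only = np.zeros(m, dtype=np.int8)
    bg_only[-1] = 1
    classes.append(bg_only)
    freqs.append(q_bg - sum(q_rares))
    classes.append(np.zeros(m, dtype=np.int8))
    freqs.append(1 - q_bg)
    if min(freqs) < 0:
        raise ValueError("background frequency too small for its rare variants")
    return np.array(classes, dtype=np.int8), np.array(freqs)


def _single_block(q: float) -> tuple[np.ndarray, np.ndarray]:
    return np.array([[1], [0]], dtype=np.int8), np.array([q, 1 - q])


def apoe_like_config(n_individuals: int = 1092, seed: int | None = 0) -> PanelConfig:
    """Built-in 33-variant fixture emulating the APOE-region LD structure.

    Variant tags follow the region's conventional numbering (no1..no33).
    Pool-implied targets include the benchmark allele frequencies 0.00412
    (no16), 0.00592 (no22), 0.00870 (no10), 0.082 (no15), 0.149 (no23),
    0.325 (no18) and 0.510 (no7), and the designated LD pairs r^2 ~ 0.768
    (no22-no2), ~0.446 (no18-no7), ~0.502 (no15-no23) and ~0.410
    (no15-no33).  The remaining variants fill out a realistic spectrum:
    rare alleles (MAF 0.001-0.01) on common haplotype backgrounds with
    D' = 1 and low r^2, moderately correlated common pairs, and independent
    variants across the frequency range.
    """
    blocks: list[tuple[np.ndarray, np.ndarray]] = []
    ids: list[str] = []

    def add(block, names):
        blocks.append(block)
        ids.extend(names)

    # no22 (0.00592) nested in no2 carriers: D' = 1, r^2 ~ 0.768
    q22 = 0.00592
    q2 = q22 / (0.768 * (1 - q22) + q22)
    add(
        (
            np.array([[1, 1], [0, 1], [0, 0]], dtype=np.int8),
            np.array([q22, q2 - q22, 1 - q2]),
        ),
        ["no22", "no2"],
    )

    # no18 (0.325) / no7 (0.510): r^2 ~ 0.446 via near-complete D'
    add(_pair_block(0.325, 0.510, 0.446), ["no18", "no7"])

    # no15 (0.082) / no23 (0.149) / no33 (0.17): r^2(15,23) ~ 0.502,
    # r^2(15,33) ~ 0.410; no23/no33 near-independent off the no15 background.
    pA, pB, pC = 0.082, 0.149, 0.17
    dAB = np.sqrt(0.502 * pA * (1 - pA) * pB * (1 - pB))
    dAC = np.sqrt(0.410 * pA * (1 - pA) * pC * (1 - pC))
    pAB = dAB + pA * pB
    pAC = dAC + pA * pC
    pABC = pAC  # carriers of no15 & no33 all carry no23
    b_no_a = pB - pAB
    c_no_a = pC - pAC
    bc_no_a = b_no_a * c_no_a / (1 - pA)
    classes = np.array(
        [[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 1, 1], [0, 1, 0], [0, 0, 1], [0, 0, 0]],
        dtype=np.int8,
    )
    freqs = np.array(
        [
            pABC,
            pAB - pABC,
            pA - pAB - pAC + pABC,
            bc_no_a,
            b_no_a - bc_no_a,
            c_no_a - bc_no_a,
            0.0,
        ]
    )
    freqs[-1] = 1 - freqs[:-1].sum()
    add((classes, freqs), ["no15", "no23", "no33"])

    # rare-on-common backgrounds (D' = 1, low r^2)
    add(_background_block(0.30, [0.00412, 0.00870]), ["no16", "no10", "no27"])
    add(_background_block(0.45, [0.0055]), ["no25", "no5"])
    add(_background_block(0.22, [0.0015, 0.0031, 0.0067]), ["no1", "no4", "no6", "no3"])
    add(_background_block(0.38, [0.0023, 0.0093]), ["no8", "no11", "no9"])
    add(_background_block(0.41, [0.0012, 0.0044]), ["no26", "no29", "no28"])

    # moderately correlated common pair
    add(_pair_block(0.26, 0.31, 0.25), ["no13", "no14"])

    # independent variants across the frequency spectrum
    for name, q in [
        ("no12", 0.065),
        ("no30", 0.02),
        ("no17", 0.035),
        ("no19", 0.12),
        ("no20", 0.052),
        ("no21", 0.014),
        ("no24", 0.09),
        ("no31", 0.063),
        ("no32", 0.028),
    ]:
        add(_single_block(q), [name])

    # order columns by the region numbering (proxy for genomic position)
    order = np.argsort([int(v[2:]) for v in ids], kind="stable")
    ordered_ids = [ids[k] for k in order]
    positions = np.array([int(v[2:]) * 100 for v in ordered_ids])
    return PanelConfig(
        blocks=blocks,
        n_individuals=n_individuals,
        seed=seed,
        variant_ids=ordered_ids,
        positions=positions,
        column_order=order,
    )
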