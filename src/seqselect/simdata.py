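"""Synthetic sequence data for a pedigreed cattle-style population.

The generator mimics a large dairy-cattle sequencing project at desk
scale: founder chromosomes are mosaics of a small ancestral haplotype
pool (which creates adjacent-marker linkage disequilibrium), descendants
receive recombinant gametes dropped through an actual pedigree, nested
"array" subsets thin the sequence variants the way 600k/60k/12k chips
would, and each trait is controlled by a modest number of QTL whose
substitution effects follow the heavy-tailed transform

    alpha = q * base^(|q| - 2),   q ~ N(0, 1),  base = 2.7 by default,

so that a few QTL carry most of the additive variance 2p(1-p)alpha^2.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np

from .containers import MISSING, GenotypeMatrix, Pedigree, QTLArchitecture, TraitPhenotypes, VariantCatalog

logger = logging.getLogger(__name__)


def stage_rng(seed: int, *stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one master seed."""
    keys = [zlib.crc32(s.encode()) for s in stage]
    return np.random.default_rng([int(seed)] + keys)


# ---------------------------------------------------------------------------
# Catalog and pedigree generation


def build_catalog(
    n_chromosomes: int,
    variants_per_chromosome: int,
    chromosome_length_bp: int = 100_000_000,
    seed: int = 0,
) -> VariantCatalog:
    """Random biallelic variant sites, uniform positions and frequencies.

    Founder alternate-allele frequencies are uniform on [0.01, 0.99].
    """
    rng = stage_rng(seed, "catalog")
    chroms, positions = [], []
    for c in range(1, n_chromosomes + 1):
        pos = np.sort(
            rng.choice(chromosome_length_bp, size=variants_per_chromosome, replace=False)
        ) + 1
        chroms.append(np.full(variants_per_chromosome, c))
        positions.append(pos)
    m = n_chromosomes * variants_per_chromosome
    bases = np.array(list("ACGT"), dtype=object)
    ref = bases[rng.integers(0, 4, m)]
    alt = bases[(np.searchsorted(bases, ref) + rng.integers(1, 4, m)) % 4]
    return VariantCatalog(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(positions),
        ref=ref,
        alt=alt,
        freq=rng.uniform(0.01, 0.99, m),
    )


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    per_generation: int,
    n_sires: int = 25,
    seed: int = 0,
) -> Pedigree:
    """Discrete-generation pedigree with heavy sire usage.

    Each generation draws ``n_sires`` sires from the previous generation
    (mimicking intense selection of bulls) and samples dams from the
    remainder, so half-sib families are large as in dairy populations.
    """
    rng = stage_rng(seed, "pedigree")
    ids = [f"G0_{i:05d}" for i in range(n_founders)]
    sire = [MISSING] * n_founders
    dam = [MISSING] * n_founders
    prev = np.arange(n_founders)
    for g in range(1, n_generations + 1):
        k = min(n_sires, max(1, len(prev) // 2))
        perm = rng.permutation(prev)
        sires, dams = perm[:k], perm[k:]
        if len(dams) == 0:
            sires, dams = perm[: max(1, k // 2)], perm[max(1, k // 2):]
        start = len(ids)
        for i in range(per_generation):
            ids.append(f"G{g}_{i:05d}")
            sire.append(int(rng.choice(sires)))
            dam.append(int(rng.choice(dams)))
        prev = np.arange(start, len(ids))
    return Pedigree(np.array(ids, dtype=object), np.array(sire), np.array(dam))


# ---------------------------------------------------------------------------
# Founder haplotypes and gene drop


def simulate_founder_haplotypes(
    n_founders: int,
    catalog: VariantCatalog,
    ld_param: float,
    seed: int,
    pool_size: int = 4,
    founder_ids=None,
) -> GenotypeMatrix:
    """Founder haplotypes as mosaics of a small ancestral pool.

    Per chromosome, ``pool_size`` ancestral haplotypes are drawn with
    allele probabilities equal to the catalog frequencies.  Each founder
    haplotype copies one pool member and switches to a random pool member
    with probability ``1 - ld_param`` at every variant, so adjacent-variant
    LD rises monotonically with ``ld_param`` while marginal allele
    frequencies match the catalog in expectation.
    """
    if n_founders < 1:
        raise ValueError("need at least one founder")
    if catalog.n == 0:
        raise ValueError("empty variant catalog")
    if not 0.0 <= ld_param <= 1.0:
        raise ValueError("ld_param must be in [0, 1]")
    rng = stage_rng(seed, "founders")
    n_hap = 2 * n_founders
    haps = np.empty((n_hap, catalog.n), dtype=np.int8)
    switch_p = 1.0 - ld_param
    for c in np.unique(catalog.chrom):
        cols = np.flatnonzero(catalog.chrom == c)
        m = len(cols)
        pool = (rng.random((pool_size, m)) < catalog.freq[cols]).astype(np.int8)
        col_idx = np.arange(m)
        for h in range(n_hap):
            k = rng.binomial(m - 1, switch_p) if m > 1 else 0
            if k > 0:
                sw = np.sort(rng.choice(np.arange(1, m), size=k, replace=False))
            else:
                sw = np.empty(0, dtype=np.int64)
            bounds = np.concatenate(([0], sw, [m]))
            picks = rng.integers(0, pool_size, size=len(bounds) - 1)
            lineage = np.repeat(picks, np.diff(bounds))
            haps[h, cols] = pool[lineage, col_idx]
    if founder_ids is None:
        founder_ids = np.array([f"F{i:05d}" for i in range(n_founders)], dtype=object)
    return GenotypeMatrix.from_haplotypes(
        founder_ids, catalog.ids, haps.reshape(n_founders, 2, catalog.n)
    )


def _chromosome_blocks(catalog: VariantCatalog):
    """Per-chromosome (slice, positions) pairs; catalog is position-sorted."""
    blocks = []
    for c in np.unique(catalog.chrom):
        cols = np.flatnonzero(catalog.chrom == c)
        if len(cols) != cols[-1] - cols[0] + 1:
            raise ValueError("chromosome columns must be contiguous")
        sl = slice(int(cols[0]), int(cols[-1]) + 1)
        blocks.append((sl, catalog.pos[sl]))
    return blocks


def _gamete_into(out, parent_haps, blocks, chrom_length_morgans,
                 chrom_length_bp, rng):
    total_cross = 0
    for sl, pos in blocks:
        k = rng.poisson(chrom_length_morgans)
        total_cross += k
        xpos = np.sort(rng.uniform(0, chrom_length_bp, size=k))
        n_before = np.searchsorted(xpos, pos, side="left")
        phase = (rng.integers(0, 2) + n_before) % 2
        seg = parent_haps[:, sl]
        out[sl] = np.where(phase == 0, seg[0], seg[1])
    return total_cross


def simulate_gamete(
    parent_haps: np.ndarray,
    catalog: VariantCatalog,
    chrom_length_morgans: float,
    chrom_length_bp: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """One recombinant gamete from a parent's haplotype pair.

    Crossover counts are Poisson(``chrom_length_morgans``) per chromosome
    with uniform positions and no interference.  Returns the gamete and
    the total crossover count (useful for calibration checks).
    """
    gamete = np.empty(catalog.n, dtype=np.int8)
    total = _gamete_into(
        gamete, parent_haps, _chromosome_blocks(catalog),
        chrom_length_morgans, chrom_length_bp, rng,
    )
    return gamete, total


def drop_through_pedigree(
    founders: GenotypeMatrix,
    pedigree: Pedigree,
    chrom_length_morgans: float,
    seed: int,
    catalog: VariantCatalog,
    chrom_length_bp: int = 100_000_000,
) -> GenotypeMatrix:
    """Gene-drop founder haplotypes through a pedigree with recombination.

    Each non-founder receives one recombinant gamete per parent.  An
    animal with an unknown parent on one side receives that gamete from a
    randomly chosen founder (a fresh recombinant of the founder's pair).
    """
    if founders.haplotypes is None:
        raise ValueError("founders must be phased")
    rng = stage_rng(seed, "genedrop")
    fmap = {a: i for i, a in enumerate(founders.animal_ids)}
    n, m = pedigree.n, catalog.n
    blocks = _chromosome_blocks(catalog)
    haps = np.empty((n, 2, m), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == MISSING and d == MISSING:
            if pedigree.ids[i] not in fmap:
                raise ValueError(f"founder {pedigree.ids[i]!r} has no simulated haplotypes")
            haps[i] = founders.haplotypes[fmap[pedigree.ids[i]]]
            continue
        for g, parent in enumerate((s, d)):
            if parent == MISSING:
                src = founders.haplotypes[rng.integers(0, founders.n_animals)]
            else:
                src = haps[parent]
            _gamete_into(
                haps[i, g], src, blocks, chrom_length_morgans,
                chrom_length_bp, rng,
            )
    return GenotypeMatrix.from_haplotypes(pedigree.ids, catalog.ids, haps)


# ---------------------------------------------------------------------------
# Array tiers


def assign_array_subsets(catalog: VariantCatalog, tier_sizes) -> VariantCatalog:
    """Flag nested, evenly spaced array tiers (600k/60k/12k analogues).

    Each tier is an evenly spaced (stride-based) subset of the tier above,
    mirroring chips that were designed as subsets of the previous chip.
    """
    tier_sizes = list(tier_sizes)
    if any(a < b for a, b in zip(tier_sizes, tier_sizes[1:])):
        raise ValueError("tier sizes must be descending")
    if tier_sizes and tier_sizes[0] > catalog.n:
        raise ValueError("tier larger than the sequence catalog")
    parent = np.arange(catalog.n)
    flags = []
    for size in tier_sizes:
        if size > len(parent):
            raise ValueError("tier larger than parent tier")
        stride = len(parent) // size
        idx = parent[::stride][:size]
        mask = np.zeros(catalog.n, dtype=bool)
        mask[idx] = True
        flags.append(mask)
        parent = idx
    names = ["in_600k", "in_60k", "in_12k"]
    out = {nm: catalog.to_frame()[nm].to_numpy() for nm in names}
    for nm, mask in zip(names, flags):
        out[nm] = mask
    return catalog.replace(in_sequence=np.ones(catalog.n, bool), **out)


# ---------------------------------------------------------------------------
# QTL effects, breeding values, phenotypes


def heavy_tail_effect(q, base: float = 2.7) -> np.ndarray:
    """Substitution effect alpha = q * base^(|q| - 2)."""
    q = np.asarray(q, dtype=np.float64)
    return q * base ** (np.abs(q) - 2.0)


def simulate_qtl_effects(
    n_qtl: int,
    catalog: VariantCatalog,
    base: float = 2.7,
    seed: int = 0,
    n_traits: int = 1,
) -> QTLArchitecture:
    """Place QTL uniformly at random and draw heavy-tailed effects.

    QTL locations are shared across traits; only the effects differ, so
    the traits are independent but not true replicates.
    """
    if n_qtl <= 0:
        raise ValueError("n_qtl must be positive")
    if n_qtl > catalog.n:
        raise ValueError("more QTL than catalog variants")
    if base <= 1:
        raise ValueError("heavy-tail base must exceed 1")
    rng = stage_rng(seed, "qtl")
    indices = np.sort(rng.choice(catalog.n, size=n_qtl, replace=False))
    q = rng.standard_normal((n_traits, n_qtl))
    alpha = heavy_tail_effect(q, base)
    p = catalog.freq[indices]
    v = 2.0 * p * (1.0 - p) * alpha**2
    return QTLArchitecture(indices=indices, q=q, alpha=alpha, v=v, base=base)


def variance_concentration(arch: QTLArchitecture, k: int) -> float:
    """Percent of additive variance carried by the k largest-variance QTL.

    For a multi-trait architecture the per-trait percentages are averaged.
    """
    if not 1 <= k <= arch.n_qtl:
        raise ValueError("k must be in [1, n_qtl]")
    totals = arch.v.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all per-locus variances are zero")
    v_sorted = np.sort(arch.v, axis=1)[:, ::-1]
    return float(np.mean(100.0 * v_sorted[:, :k].sum(axis=1) / totals))


def compute_tbv(genotypes: GenotypeMatrix, arch: QTLArchitecture) -> np.ndarray:
    """True breeding values: TBV_i = sum_j dosage_ij * alpha_j, (n, traits)."""
    d = genotypes.dosages[:, arch.indices]
    if (d == MISSING).any():
        raise ValueError("missing QTL dosages; TBV undefined")
    return d.astype(np.float64) @ arch.alpha.T


def simulate_phenotypes(
    tbv: np.ndarray, reliabilities: np.ndarray, seed: int = 0
) -> TraitPhenotypes:
    """Pseudo-phenotypes y = TBV + e with per-animal reliability R.

    The noise variance sigma_g^2 (1-R)/R makes var(TBV)/var(y) -> R, the
    reliability of a deregressed evaluation.  A trait with zero TBV
    variance gets y = TBV with a logged warning.
    """
    tbv = np.asarray(tbv, dtype=np.float64)
    if tbv.ndim == 1:
        tbv = tbv[:, None]
    reliabilities = np.broadcast_to(
        np.asarray(reliabilities, dtype=np.float64), (tbv.shape[0],)
    )
    if (reliabilities <= 0).any() or (reliabilities > 1).any():
        raise ValueError("reliabilities must be in (0, 1]")
    rng = stage_rng(seed, "phenotypes")
    y = np.empty_like(tbv)
    for t in range(tbv.shape[1]):
        sigma_g = tbv[:, t].var()
        if sigma_g == 0:
            logger.warning("trait %d has zero TBV variance; y set to TBV", t)
            y[:, t] = tbv[:, t]
            continue
        sd = np.sqrt(sigma_g * (1.0 - reliabilities) / reliabilities)
        y[:, t] = tbv[:, t] + rng.standard_normal(tbv.shape[0]) * sd
    return TraitPhenotypes(tbv=tbv, y=y, reliability=reliabilities.copy())
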