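"""Variant- and genotype-level edits applied before imputation.

The edits mirror routine practice for merging array and sequence
genotypes: drop rare variants (MAF), prune near-duplicate variants in
high LD with a kept neighbour, protect array and genic variants from
removal, mask unreliable calls (genotype probability), drop variants
with excessive missingness or excess heterozygosity, reconcile allele
orientation between chip and sequence data, and blank Mendelian
conflicts between parents and progeny.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import MISSING, GenotypeMatrix, Pedigree, VariantCatalog

logger = logging.getLogger(__name__)


@dataclass
class EditConfig:
    """Thresholds for every edit rule (defaults follow routine practice)."""

    maf_min: float = 0.01
    ld_rmax: float = 0.95
    ld_window: int = 350
    ld_window_mode: str = "kept"  # or "raw"
    genic_distance: int = 2500
    gprob_threshold: float = 0.98
    miss_max_low: float = 0.05
    miss_maf_cut: float = 0.10
    het_excess_factor: float = 1.5
    orientation_rmin: float = 0.95

    def __post_init__(self) -> None:
        for name in (
            "maf_min", "ld_rmax", "gprob_threshold",
            "miss_max_low", "miss_maf_cut", "orientation_rmin",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.het_excess_factor < 1.0:
            raise ValueError("het_excess_factor must be >= 1")
        if self.ld_window_mode not in ("kept", "raw"):
            raise ValueError("ld_window_mode must be 'kept' or 'raw'")


# ---------------------------------------------------------------------------
# Frequency-level filters


def maf_filter(catalog: VariantCatalog, maf_min: float = 0.01) -> np.ndarray:
    """Keep mask: MAF >= maf_min; strictly-lower variants removed.

    Protected variants are always kept.
    """
    return (catalog.maf >= maf_min) | catalog.protected


def missingness_filter(genotypes: GenotypeMatrix, cfg: EditConfig) -> np.ndarray:
    """Keep mask by missing-call fraction, with a MAF-dependent limit.

    Low-frequency variants (MAF < ``miss_maf_cut``) tolerate at most
    ``miss_max_low`` missing; commoner variants tolerate at most MAF/2.
    """
    p = genotypes.allele_frequencies()
    maf = np.minimum(p, 1 - p)
    miss = genotypes.missing_mask.mean(axis=0)
    limit = np.where(maf < cfg.miss_maf_cut, cfg.miss_max_low, maf / 2.0)
    return miss <= limit


def hwe_excess_het_filter(genotypes: GenotypeMatrix, factor: float = 1.5) -> np.ndarray:
    """Keep mask: drop variants with > factor x 2p(1-p) heterozygotes."""
    d = genotypes.dosages
    called = d != MISSING
    n_called = np.maximum(called.sum(axis=0), 1)
    p = genotypes.allele_frequencies()
    het = ((d == 1) & called).sum(axis=0) / n_called
    return het <= factor * 2.0 * p * (1.0 - p)


# ---------------------------------------------------------------------------
# Genotype-probability masking


def gprob_filter(calls: GenotypeMatrix, threshold: float = 0.98) -> GenotypeMatrix:
    """Set dosages missing where no genotype probability exceeds threshold."""
    if calls.call_probs is None:
        raise ValueError("genotype probabilities required for gprob_filter")
    out = calls.copy()
    low = calls.call_probs.max(axis=2) <= threshold
    out.dosages[low] = MISSING
    return out


# ---------------------------------------------------------------------------
# Genic retention


def genic_retain(
    catalog: VariantCatalog, regions, distance: int = 2500
) -> np.ndarray:
    """Protected mask: variants within ``distance`` bp of any region.

    Regions are (chrom, start, end) 1-based inclusive intervals; a QTL is
    a width-1 interval.  Array-tier variants are also protected, since
    previously used chip SNPs must survive editing for imputation.
    """
    protected = catalog.in_600k.copy()
    for region in regions:
        chrom, start, end = int(region[0]), int(region[1]), int(region[2])
        if end < start:
            raise ValueError(f"malformed interval {region!r}")
        on = catalog.chrom == chrom
        pos = catalog.pos
        hit = on & (pos >= start - distance) & (pos <= end + distance)
        protected |= hit
    return protected


def annotate_genic(
    catalog: VariantCatalog, regions, distance: int = 2500
) -> VariantCatalog:
    """Catalog with genic (distance rule only) and protected flags set."""
    plain = catalog.replace(in_600k=np.zeros(catalog.n, bool),
                            in_60k=np.zeros(catalog.n, bool),
                            in_12k=np.zeros(catalog.n, bool))
    genic = genic_retain(plain, regions, distance)
    protected = genic | catalog.in_600k
    return catalog.replace(genic=genic, protected=catalog.protected | protected)


# ---------------------------------------------------------------------------
# LD pruning


@njit(cache=True)
def _pair_r(D, i, j):
    """Correlation of dosage rows i and j over animals called in both."""
    n = D.shape[1]
    cnt = 0
    sx = 0.0
    sy = 0.0
    sxx = 0.0
    syy = 0.0
    sxy = 0.0
    for a in range(n):
        x = D[i, a]
        y = D[j, a]
        if x < 0 or y < 0:
            continue
        cnt += 1
        sx += x
        sy += y
        sxx += x * x
        syy += y * y
        sxy += x * y
    if cnt < 2:
        return 0.0
    vx = sxx - sx * sx / cnt
    vy = syy - sy * sy / cnt
    if vx <= 0.0 or vy <= 0.0:
        return 0.0
    return (sxy - sx * sy / cnt) / np.sqrt(vx * vy)


@njit(cache=True, inline="always")
def _pair_r_fast(D, i, j, sums, sumsqs, n):
    """Correlation when neither variant has missing calls (branch-free)."""
    dot = 0
    for a in range(n):
        dot += np.int64(D[i, a]) * np.int64(D[j, a])
    vx = sumsqs[i] - sums[i] * sums[i] / n
    vy = sumsqs[j] - sums[j] * sums[j] / n
    if vx <= 0.0 or vy <= 0.0:
        return 0.0
    return (dot - sums[i] * sums[j] / n) / np.sqrt(vx * vy)


@njit(cache=True)
def _ld_prune_kernel(D, chrom, protected, window, rmax, raw_window):
    m, n = D.shape
    sums = np.zeros(m)
    sumsqs = np.zeros(m)
    clean = np.ones(m, np.bool_)
    for i in range(m):
        for a in range(n):
            x = D[i, a]
            if x < 0:
                clean[i] = False
            else:
                sums[i] += x
                sumsqs[i] += x * x
    keep = np.zeros(m, np.bool_)
    kept_idx = np.empty(m, np.int64)
    nk = 0
    for i in range(m):
        removed = False
        if not protected[i]:
            checked = 0
            for t in range(nk - 1, -1, -1):
                j = kept_idx[t]
                if chrom[j] != chrom[i]:
                    break
                if raw_window:
                    if j < i - window:
                        break
                else:
                    if checked >= window:
                        break
                    checked += 1
                if clean[i] and clean[j]:
                    r = _pair_r_fast(D, i, j, sums, sumsqs, n)
                else:
                    r = _pair_r(D, i, j)
                if abs(r) > rmax:
                    removed = True
                    break
            if not removed:
                # a protected variant ahead also evicts an unprotected
                # duplicate: protected markers win regardless of scan order
                stop = min(i + window + 1, m)
                for j in range(i + 1, stop):
                    if chrom[j] != chrom[i]:
                        break
                    if not protected[j]:
                        continue
                    if clean[i] and clean[j]:
                        r = _pair_r_fast(D, i, j, sums, sumsqs, n)
                    else:
                        r = _pair_r(D, i, j)
                    if abs(r) > rmax:
                        removed = True
                        break
        if not removed:
            keep[i] = True
            kept_idx[nk] = i
            nk += 1
    return keep


def ld_prune(
    genotypes: GenotypeMatrix,
    window: int = 350,
    rmax: float = 0.95,
    protected=None,
    chrom=None,
    window_mode: str = "kept",
) -> np.ndarray:
    """Greedy LD pruning scan in ascending position order.

    A variant is removed iff |r| > ``rmax`` with an already-kept variant
    among the previous ``window`` kept variants on the same chromosome
    (``window_mode='raw'`` counts raw positions instead), or with a
    protected variant among the next ``window`` raw positions — protected
    markers always win over unprotected duplicates regardless of scan
    order.  Protected variants are never removed.  Other ties are
    resolved by the scan itself: the earlier variant is kept.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    m = genotypes.n_variants
    if protected is None:
        protected = np.zeros(m, dtype=bool)
    if chrom is None:
        chrom = np.zeros(m, dtype=np.int64)
    D = np.ascontiguousarray(genotypes.dosages.T)
    keep = _ld_prune_kernel(
        D,
        np.asarray(chrom, dtype=np.int64),
        np.asarray(protected, dtype=np.bool_),
        int(window),
        float(rmax),
        window_mode == "raw",
    )
    return keep


class LDPruner(TransformerMixin, BaseEstimator):
    """Scikit-learn style wrapper around the LD pruning scan.

    ``fit`` computes ``keep_mask_`` from a dosage matrix (animals x
    variants); ``transform`` subsets columns accordingly.
    """

    def __init__(self, window=350, rmax=0.95, window_mode="kept",
                 chrom=None, protected=None):
        self.window = window
        self.rmax = rmax
        self.window_mode = window_mode
        self.chrom = chrom
        self.protected = protected

    def fit(self, X, y=None):
        X = np.asarray(X)
        gm = GenotypeMatrix(
            animal_ids=np.arange(X.shape[0]),
            variant_ids=np.arange(X.shape[1]),
            dosages=X,
        )
        self.keep_mask_ = ld_prune(
            gm, self.window, self.rmax, self.protected, self.chrom, self.window_mode
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.keep_mask_]


# ---------------------------------------------------------------------------
# Orientation reconciliation


def reconcile_orientation(
    chip: GenotypeMatrix,
    seq: GenotypeMatrix,
    shared_animals,
    rmin: float = 0.95,
) -> pd.DataFrame:
    """Per-variant action for variants present in both chip and sequence.

    Correlation of dosages over the shared animals decides: r >= +rmin
    keep, r <= -rmin flip (chip dosage <- 2 - dosage), otherwise drop.
    Zero-variance vectors cannot be oriented and are dropped with a
    logged reason.  Returns a frame (variant_id, r, action).
    """
    shared_animals = list(shared_animals)
    chip_rows = {a: i for i, a in enumerate(chip.animal_ids)}
    seq_rows = {a: i for i, a in enumerate(seq.animal_ids)}
    ai = np.array([chip_rows[a] for a in shared_animals])
    aj = np.array([seq_rows[a] for a in shared_animals])
    seq_cols = {v: k for k, v in enumerate(seq.variant_ids)}
    records = []
    for ci, vid in enumerate(chip.variant_ids):
        if vid not in seq_cols:
            continue
        x = chip.dosages[ai, ci].astype(float)
        y = seq.dosages[aj, seq_cols[vid]].astype(float)
        ok = (x != MISSING) & (y != MISSING)
        if ok.sum() < 2:
            raise ValueError(f"fewer than 2 shared calls for variant {vid}")
        x, y = x[ok], y[ok]
        if x.std() == 0 or y.std() == 0:
            logger.info("variant %s dropped: zero-variance dosages", vid)
            records.append((vid, np.nan, "drop"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        action = "keep" if r >= rmin else ("flip" if r <= -rmin else "drop")
        records.append((vid, r, action))
    return pd.DataFrame(records, columns=["variant_id", "r", "action"])


def apply_orientation(chip: GenotypeMatrix, actions: pd.DataFrame) -> GenotypeMatrix:
    """Flip flagged chip variants in place (2 - dosage); an involution."""
    out = chip.copy()
    flip_ids = set(actions.loc[actions["action"] == "flip", "variant_id"])
    for ci, vid in enumerate(out.variant_ids):
        if vid in flip_ids:
            col = out.dosages[:, ci]
            called = col != MISSING
            col[called] = 2 - col[called]
    return out


def merge_chip_and_sequence(
    chip: GenotypeMatrix, seq: GenotypeMatrix, actions: pd.DataFrame
) -> GenotypeMatrix:
    """Combine oriented chip calls with sequence calls; sequence wins.

    Output covers sequence variants; for an animal present in both
    sources the sequence dosage is used wherever it is called.
    """
    oriented = apply_orientation(chip, actions)
    drop = set(actions.loc[actions["action"] == "drop", "variant_id"])
    animals = list(dict.fromkeys(list(seq.animal_ids) + list(chip.animal_ids)))
    m = seq.n_variants
    D = np.full((len(animals), m), MISSING, dtype=np.int8)
    arow = {a: i for i, a in enumerate(animals)}
    chip_col = {v: k for k, v in enumerate(oriented.variant_ids)}
    chip_dest = np.array([arow[a] for a in oriented.animal_ids])
    for k, vid in enumerate(seq.variant_ids):
        if vid in chip_col and vid not in drop:
            D[chip_dest, k] = oriented.dosages[:, chip_col[vid]]
    # sequence calls overwrite chip calls
    for i, a in enumerate(seq.animal_ids):
        row = seq.dosages[i]
        called = row != MISSING
        D[arow[a], called] = row[called]
    return GenotypeMatrix(
        animal_ids=np.array(animals, dtype=object),
        variant_ids=seq.variant_ids,
        dosages=D,
    )


# ---------------------------------------------------------------------------
# Mendelian conflicts


def set_mendelian_conflicts_missing(
    genotypes: GenotypeMatrix, pedigree: Pedigree, both_sides: bool = False
) -> tuple[GenotypeMatrix, float]:
    """Blank opposite-homozygote parent/progeny calls; return altered rate.

    By default only the offspring call is set missing; ``both_sides``
    masks the parent call too.  The rate is the fraction of all genotype
    cells altered.
    """
    out = genotypes.copy()
    rows = {a: i for i, a in enumerate(genotypes.animal_ids)}
    altered = np.zeros(out.dosages.shape, dtype=bool)
    for i, animal in enumerate(pedigree.ids):
        if animal not in rows:
            continue
        oi = rows[animal]
        for parent_idx in (pedigree.sire[i], pedigree.dam[i]):
            if parent_idx == MISSING:
                continue
            parent = pedigree.ids[parent_idx]
            if parent not in rows:
                continue
            pi = rows[parent]
            off, par = genotypes.dosages[oi], genotypes.dosages[pi]
            conflict = ((off == 0) & (par == 2)) | ((off == 2) & (par == 0))
            altered[oi] |= conflict
            if both_sides:
                altered[pi] |= conflict
    out.dosages[altered] = MISSING
    rate = float(altered.sum()) / altered.size
    return out, rate


# ---------------------------------------------------------------------------
# Composition


def apply_variant_edits(
    genotypes: GenotypeMatrix,
    catalog: VariantCatalog,
    cfg: EditConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """MAF then LD edits in sequence; returns keep mask and a stage report.

    MAF is taken from observed genotypes (recomputed after any upstream
    genotype-level edits); the report mirrors a per-stage edit table
    (stage, variants_in, removed, kept).
    """
    p = genotypes.allele_frequencies()
    cat = catalog.replace(freq=p)
    stages = []
    keep = maf_filter(cat, cfg.maf_min)
    stages.append(("maf<%g" % cfg.maf_min, cat.n, int((~keep).sum()), int(keep.sum())))

    sub = genotypes.subset_variants(keep)
    keep_ld = ld_prune(
        sub,
        window=cfg.ld_window,
        rmax=cfg.ld_rmax,
        protected=catalog.protected[keep],
        chrom=catalog.chrom[keep],
        window_mode=cfg.ld_window_mode,
    )
    stages.append(
        ("ld>%g" % cfg.ld_rmax, int(keep.sum()), int((~keep_ld).sum()), int(keep_ld.sum()))
    )
    final = keep.copy()
    final[np.flatnonzero(keep)] = keep_ld
    report = pd.DataFrame(stages, columns=["stage", "variants_in", "removed", "kept"])
    for _, row in report.iterrows():
        logger.info(
            "edit %s: %d in, %d removed, %d kept",
            row["stage"], row["variants_in"], row["removed"], row["kept"],
        )
    return final, report
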