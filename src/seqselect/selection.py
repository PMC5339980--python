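"""Ranking and selection of variant subsets for arrays and prediction.

Three selection statistics are supported: genome-wide association
significance from a single-marker mixed model with a pedigree polygenic
term, absolute estimated substitution effect |alpha|, and the variance
contributed by the locus, 2p(1-p)alpha^2.  Per-trait top lists are
merged with duplicates removed, and a window pruner thins selected
variants that tag the same region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GWA scan


def gwa_scan(
    genotypes,
    y: np.ndarray,
    pedigree: Pedigree | None = None,
    polygenic_h2: float = 0.10,
    ped_index=None,
) -> pd.DataFrame:
    """Single-marker mixed-model scan: y = mu + x beta + u + e.

    The polygenic term u has covariance A sigma_a^2 with sigma_a^2 equal
    to ``polygenic_h2`` of the total variance (pedigree A by the tabular
    method).  The GLS system is solved exactly by rotating through the
    Cholesky factor of V = h2 A + (1 - h2) I, after which each variant is
    an ordinary regression with a t-test on n - 2 df; with
    ``polygenic_h2 = 0`` the scan reduces to plain OLS t-tests.
    Monomorphic variants get p = 1 with a logged skip.

    Returns a frame with columns beta, se, t, p.
    """
    X = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else genotypes
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, m = X.shape
    if not 0.0 <= polygenic_h2 < 1.0:
        raise ValueError("polygenic_h2 must be in [0, 1)")
    if polygenic_h2 > 0:
        if pedigree is None:
            raise ValueError("pedigree required when polygenic_h2 > 0")
        A = pedigree.a_matrix()
        if ped_index is not None:
            idx = np.asarray(ped_index, dtype=np.int64)
            A = A[np.ix_(idx, idx)]
        if A.shape[0] != n:
            raise ValueError("relationship matrix does not match observations")
        V = polygenic_h2 * A + (1.0 - polygenic_h2) * np.eye(n)
        L = linalg.cholesky(V, lower=True)
        Xt = linalg.solve_triangular(L, X, lower=True)
        yt = linalg.solve_triangular(L, y, lower=True)
        ones = linalg.solve_triangular(L, np.ones(n), lower=True)
    else:
        Xt, yt, ones = X, y, np.ones(n)

    a11 = ones @ ones
    a12 = ones @ Xt
    a22 = np.einsum("ij,ij->j", Xt, Xt)
    b1 = ones @ yt
    b2 = yt @ Xt
    yty = yt @ yt
    det = a11 * a22 - a12**2
    ok = det > 1e-10 * np.maximum(a11 * a22, 1e-300)
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    tstat = np.zeros(m)
    pval = np.ones(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta[ok] = (a11 * b2[ok] - a12[ok] * b1) / det[ok]
        mu = (a22[ok] * b1 - a12[ok] * b2[ok]) / det[ok]
        rss = np.maximum(yty - mu * b1 - beta[ok] * b2[ok], 0.0)
        sigma2 = rss / max(n - 2, 1)
        se[ok] = np.sqrt(sigma2 * a11 / det[ok])
        # a zero-residual fit is infinitely significant, not monomorphic
        tstat[ok] = np.where(
            se[ok] > 0,
            beta[ok] / np.where(se[ok] > 0, se[ok], 1.0),
            np.where(beta[ok] != 0, np.inf * np.sign(beta[ok]), 0.0),
        )
        pval[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df=n - 2)
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("gwa_scan: %d monomorphic variants skipped (p = 1)", n_skip)
    return pd.DataFrame({"beta": beta, "se": se, "t": tstat, "p": pval})


def combine_trait_significance(pvalues: np.ndarray) -> np.ndarray:
    """Fisher's combined statistic -2 sum_t log p_t per variant.

    ``pvalues`` is (n_traits, n_variants); larger scores are more
    significant.  Zero p-values are clamped to the smallest positive
    double with a warning.
    """
    P = np.atleast_2d(np.asarray(pvalues, dtype=np.float64))
    if (P == 0).any():
        logger.warning("p = 0 clamped to the smallest positive double")
        P = np.maximum(P, np.finfo(float).tiny)
    if ((P < 0) | (P > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return -2.0 * np.log(P).sum(axis=0)


# ---------------------------------------------------------------------------
# Effect-based rankings


def effect_variance_scores(alpha: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Per-locus variance 2p(1-p)alpha^2."""
    alpha = np.asarray(alpha, dtype=np.float64)
    p = np.asarray(freqs, dtype=np.float64)
    return 2.0 * p * (1.0 - p) * alpha**2


def rank_by_effect_variance(alpha: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Variant indices ranked by descending 2p(1-p)alpha^2 (stable)."""
    return rank_descending(effect_variance_scores(alpha, freqs))


def rank_by_effect_size(alpha: np.ndarray) -> np.ndarray:
    """Variant indices ranked by descending |alpha| (stable)."""
    return rank_descending(np.abs(np.asarray(alpha, dtype=np.float64)))


def rank_descending(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return np.argsort(-scores, kind="stable")


# ---------------------------------------------------------------------------
# Merging per-trait selections


@dataclass
class SelectionResult:
    """Selected variant indices with per-variant scores and provenance."""

    method: str
    scores: np.ndarray            # (n_traits, n_variants) or (n_variants,)
    selected: np.ndarray          # sorted unique variant indices
    per_trait_top: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=np.int64)
        if len(np.unique(self.selected)) != len(self.selected):
            raise ValueError("selected set contains duplicates")


def select_top_per_trait_and_merge(
    scores_by_trait: np.ndarray, k: int, method: str = "effect_size"
) -> SelectionResult:
    """Union of the top-k variants of each trait, duplicates removed."""
    S = np.atleast_2d(np.asarray(scores_by_trait, dtype=np.float64))
    if k > S.shape[1]:
        raise ValueError("k exceeds the ranking length")
    tops = [rank_descending(S[t])[:k] for t in range(S.shape[0])]
    merged = np.unique(np.concatenate(tops))
    return SelectionResult(method=method, scores=S, selected=merged,
                           per_trait_top=tops)


def select_top_average_across_traits(
    scores_by_trait: np.ndarray, k: int, method: str = "effect_variance_avg"
) -> SelectionResult:
    """Top-k by the mean score across traits (index-selection mimic)."""
    S = np.atleast_2d(np.asarray(scores_by_trait, dtype=np.float64))
    mean_scores = S.mean(axis=0)
    sel = rank_descending(mean_scores)[:k]
    return SelectionResult(method=method, scores=S,
                           selected=np.sort(sel), per_trait_top=[sel])


# ---------------------------------------------------------------------------
# Window pruning for array design


def window_prune_for_array(
    selected: np.ndarray,
    scores: np.ndarray,
    positions: np.ndarray,
    chrom: np.ndarray,
    window: int,
) -> np.ndarray:
    """Greedy window thinning: keep the top variant, suppress neighbours.

    Variants are visited in descending score order; one is kept unless an
    already-kept variant lies within ``window`` bp on the same
    chromosome.  Returns the kept subset of ``selected`` (sorted).
    """
    selected = np.asarray(selected, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    order = selected[rank_descending(scores[selected])]
    kept: dict = {}
    import bisect

    out = []
    for i in order:
        c, p = chrom[i], positions[i]
        lst = kept.setdefault(c, [])
        j = bisect.bisect_left(lst, p)
        near = (j > 0 and p - lst[j - 1] <= window) or (
            j < len(lst) and lst[j] - p <= window
        )
        if near:
            continue
        bisect.insort(lst, p)
        out.append(i)
    return np.sort(np.array(out, dtype=np.int64))


def conditional_rescan(
    X: np.ndarray,
    y: np.ndarray,
    candidates: np.ndarray,
    positions: np.ndarray,
    chrom: np.ndarray,
    window: int = 1_000_000,
) -> np.ndarray:
    """Re-test candidates conditional on selected neighbours (optional pass).

    Each candidate is re-fit by OLS with the other already-accepted
    candidates within ``window`` bp on the same chromosome as fixed
    covariates; its conditional p-value is returned.  Candidates are
    processed in input order.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(y)
    accepted: list[int] = []
    pvals = np.ones(len(candidates))
    for ci, i in enumerate(candidates):
        near = [
            j for j in accepted
            if chrom[j] == chrom[i] and abs(int(positions[j]) - int(positions[i])) <= window
        ]
        design = np.column_stack([np.ones(n), X[:, near], X[:, i]])
        coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        df = n - design.shape[1]
        if df <= 0 or rank < design.shape[1]:
            pvals[ci] = 1.0
            continue
        resid = y - design @ coef
        sigma2 = resid @ resid / df
        xtx_inv = np.linalg.pinv(design.T @ design)
        se = np.sqrt(sigma2 * xtx_inv[-1, -1])
        t = coef[-1] / se if se > 0 else 0.0
        pvals[ci] = 2.0 * stats.t.sf(abs(t), df=df)
        accepted.append(i)
    return pvals
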