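"""Haplotype-library imputation from mixed-density genotypes.

Reference animals with phased sequence-density haplotypes populate a
library of distinct window haplotypes (long windows first, then a
half-length fallback level).  Each target animal's genotype in a window
is matched to the library haplotype pair with the fewest mismatches on
its observed dosages; missing dosages are filled from the assigned pair.
This is a greedy minimum-mismatch implementation of the
haplotype-library matching idea used by pedigree-aware imputation
programs in livestock genetics; it is not a port of any of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class LibraryWindow:
    cols: np.ndarray       # contiguous variant column indices
    haps: np.ndarray       # (H, W) distinct haplotypes, alleles 0/1
    counts: np.ndarray     # population count of each haplotype
    inverse: np.ndarray = None  # reference gamete -> haplotype index
    chrom: int = 0


@dataclass
class HaplotypeLibrary:
    """Deduplicated window haplotypes at one or more window lengths."""

    levels: list  # list of lists of LibraryWindow, longest windows first
    n_variants: int

    def window_count(self, level: int = 0) -> int:
        return len(self.levels[level])


def _tile(chrom: np.ndarray, width: int):
    """Yield (chrom, block) contiguous blocks of ``width`` per chromosome."""
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        for start in range(0, len(cols), width):
            yield c, cols[start : start + width]


def build_haplotype_library(
    reference: GenotypeMatrix,
    window_sizes=(500, 250),
    chrom: np.ndarray | None = None,
) -> HaplotypeLibrary:
    """Tile chromosomes into windows and tally distinct reference haplotypes.

    ``window_sizes`` must be descending; each level tiles independently.
    Haplotypes are deduplicated with population counts; listing order is
    the lexicographic order from ``np.unique`` and is deterministic.
    """
    if reference.haplotypes is None:
        raise ValueError("reference must be phased to build a haplotype library")
    sizes = list(window_sizes)
    if not sizes or any(a < b for a, b in zip(sizes, sizes[1:])):
        raise ValueError("window sizes must be non-empty and descending")
    if chrom is None:
        chrom = np.zeros(reference.n_variants, dtype=np.int64)
    H = reference.haplotypes.reshape(-1, reference.n_variants)
    levels = []
    for width in sizes:
        windows = []
        for c, cols in _tile(chrom, width):
            block = np.ascontiguousarray(H[:, cols])
            haps, inverse, counts = np.unique(
                block, axis=0, return_inverse=True, return_counts=True
            )
            windows.append(
                LibraryWindow(cols=cols, haps=haps, counts=counts,
                              inverse=inverse.ravel(), chrom=int(c))
            )
        levels.append(windows)
    return HaplotypeLibrary(levels=levels, n_variants=reference.n_variants)


@njit(cache=True, inline="always")
def _pair_mismatch(Dw, L, t, ha, hb):
    mm = 0
    for w in range(Dw.shape[1]):
        d = Dw[t, w]
        if d >= 0 and L[ha, w] + L[hb, w] != d:
            mm += 1
    return mm


@njit(cache=True)
def _match_window(Dw, S, L, counts, sire_pos, dam_pos, pref_cand,
                  allowed_rate, top_c):
    """Assign the best library pair per animal; fill missing dosages.

    ``S`` holds precomputed homozygote-incompatibility scores (animal x
    library haplotype).  Candidates per animal are the ``top_c``
    haplotypes with the lowest scores, plus two kinds of tie-preferred
    candidates: the window haplotypes already assigned to the animal's
    parents (rows are in pedigree order, and a gamete is a recombinant
    of one parent's pair; ``sire_pos``/``dam_pos`` index parent rows) and
    the continuation candidates in ``pref_cand`` (haplotypes extending
    the animal's previous-window choice — inheritance switches only at
    crossovers).  The pair is found by alternating conditional search:
    fix one member, exactly optimise the other over all candidates, and
    repeat.  Ties prefer a preferred candidate, then higher population
    count, then listing order.  Observed cells are never altered.
    Returns the filled block and the (T, 2) chosen haplotype indices.
    """
    T, W = Dw.shape
    Hn = L.shape[0]
    P = pref_cand.shape[1]
    out = Dw.copy()
    choice = np.full((T, 2), -1, np.int64)
    C = min(top_c, Hn)
    max_cnt = 0
    for h in range(Hn):
        if counts[h] > max_cnt:
            max_cnt = counts[h]
    span = np.int64(Hn) * np.int64(max_cnt + 1)
    for t in range(T):
        has_missing = False
        n_obs = 0
        for w in range(W):
            if Dw[t, w] < 0:
                has_missing = True
            else:
                n_obs += 1
        # top-C candidates by (score, -count, order) via one sortable key
        key = np.empty(Hn, np.int64)
        for h in range(Hn):
            key[h] = (
                np.int64(S[t, h]) * span
                + (max_cnt - counts[h]) * np.int64(Hn)
                + h
            )
        order = np.argsort(key)
        n_cand = C
        cand = np.empty(C + 4 + P, np.int64)
        cand[:C] = order[:C]
        preferred = np.zeros(C + 4 + P, np.bool_)
        n_pref = 4 + P
        pref_list = np.empty(n_pref, np.int64)
        np_i = 0
        for parent in (sire_pos[t], dam_pos[t]):
            if 0 <= parent < t:
                for g in range(2):
                    pref_list[np_i] = choice[parent, g]
                    np_i += 1
        for k in range(P):
            pref_list[np_i] = pref_cand[t, k]
            np_i += 1
        for k in range(np_i):
            h = pref_list[k]
            if h < 0:
                continue
            found = False
            for q in range(n_cand):
                if cand[q] == h:
                    preferred[q] = True
                    found = True
                    break
            if not found:
                cand[n_cand] = h
                preferred[n_cand] = True
                n_cand += 1
        h1 = cand[0]
        h2 = -1
        best_mm = -1
        for _ in range(2):
            # optimise h2 given h1, then h1 given h2, exactly over cand;
            # ties prefer a preferred (parental or continuation)
            # haplotype, then higher count, then order
            for fixed_first in (True, False):
                other = h1 if fixed_first else h2
                bsel = -1
                bmm = -1
                bcnt = -1
                bpar = False
                for k in range(n_cand):
                    h = cand[k]
                    mm = _pair_mismatch(Dw, L, t, other, h)
                    better = False
                    if bsel < 0 or mm < bmm:
                        better = True
                    elif mm == bmm:
                        if preferred[k] and not bpar:
                            better = True
                        elif preferred[k] == bpar and counts[h] > bcnt:
                            better = True
                    if better:
                        bsel = h
                        bmm = mm
                        bcnt = counts[h]
                        bpar = preferred[k]
                if fixed_first:
                    h2 = bsel
                else:
                    h1 = bsel
                best_mm = bmm
        choice[t, 0] = h1
        choice[t, 1] = h2
        if has_missing and best_mm >= 0 and best_mm <= allowed_rate * n_obs:
            for w in range(W):
                if Dw[t, w] < 0:
                    out[t, w] = L[h1, w] + L[h2, w]
    return out, choice


def impute(
    target: GenotypeMatrix,
    library: HaplotypeLibrary,
    max_mismatch_per_100: float = 2.0,
    top_candidates: int = 30,
    best_effort_final_level: bool = True,
    parent_rows: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Fill missing dosages window by window, longest level first.

    A window match is accepted when the best pair mismatches at most
    ``max_mismatch_per_100`` per 100 observed dosages; otherwise the
    shorter-window level retries.  At the final level the best available
    pair is accepted regardless (the reference library is never a
    complete sample of population haplotypes), unless
    ``best_effort_final_level`` is disabled, in which case unresolved
    cells stay missing.  Observed dosages are never altered.

    ``parent_rows`` (n_animals x 2, -1 for unknown) adds pedigree
    guidance: target rows must then be in pedigree order, and each
    animal's candidate set includes the window haplotypes assigned to
    its parents, which sharply improves accuracy in deep pedigrees.
    """
    if not library.levels or all(len(lv) == 0 for lv in library.levels):
        raise ValueError("empty haplotype library")
    if target.n_variants != library.n_variants:
        raise ValueError("target variants must align with library variants")
    n = target.n_animals
    if parent_rows is None:
        sire_row = np.full(n, -1, dtype=np.int64)
        dam_row = np.full(n, -1, dtype=np.int64)
        use_pedigree = False
    else:
        parent_rows = np.asarray(parent_rows, dtype=np.int64)
        if parent_rows.shape != (n, 2):
            raise ValueError("parent_rows must be (n_animals, 2)")
        sire_row, dam_row = parent_rows[:, 0].copy(), parent_rows[:, 1].copy()
        use_pedigree = True
    out = target.copy()
    D = out.dosages
    n_levels = len(library.levels)
    for li, level in enumerate(library.levels):
        if not D.min() < 0:
            break
        final = li == n_levels - 1 and best_effort_final_level
        rate = np.inf if final else max_mismatch_per_100 / 100.0
        prev_win = None
        prev_choice = None  # (n, 2) over all target rows
        for win in level:
            sub = D[:, win.cols]
            miss_rows = np.flatnonzero((sub == MISSING).any(axis=1))
            if len(miss_rows) == 0:
                prev_win = None
                continue
            haps = np.ascontiguousarray(win.haps)
            counts = win.counts.astype(np.int64)
            if use_pedigree:
                # match animals with missing cells plus their ancestor
                # closure (descendants inherit parental choices)
                active_mask = np.zeros(n, dtype=np.bool_)
                active_mask[miss_rows] = True
                _ancestor_closure(active_mask, sire_row, dam_row)
                active = np.flatnonzero(active_mask)
                pos_of = np.full(n, -1, dtype=np.int64)
                pos_of[active] = np.arange(len(active))
                sire_pos = np.where(
                    sire_row[active] >= 0,
                    pos_of[np.maximum(sire_row[active], 0)], -1,
                )
                dam_pos = np.where(
                    dam_row[active] >= 0,
                    pos_of[np.maximum(dam_row[active], 0)], -1,
                )
                # continuation candidates: haplotypes of the reference
                # gametes carrying each animal's previous-window choice
                pref = np.full((len(active), 4), -1, dtype=np.int64)
                if prev_win is not None and prev_win.chrom == win.chrom:
                    trans = _transition_map(prev_win, win)
                    pc = prev_choice[active]
                    for s in (0, 1):
                        ok = pc[:, s] >= 0
                        pref[ok, 2 * s : 2 * s + 2] = trans[pc[ok, s]]
                Dw = np.ascontiguousarray(sub[active])
                filled, choice = _match_window(
                    Dw, _hom_incompat_scores(Dw, haps), haps, counts,
                    sire_pos, dam_pos, pref, rate, int(top_candidates),
                )
                block = D[:, win.cols]
                block[active] = filled
                D[:, win.cols] = block
                prev_choice = np.full((n, 2), -1, dtype=np.int64)
                prev_choice[active] = choice
                prev_win = win
            else:
                none = np.full(len(miss_rows), -1, dtype=np.int64)
                no_pref = np.full((len(miss_rows), 1), -1, dtype=np.int64)
                Dw = np.ascontiguousarray(sub[miss_rows])
                filled, _ = _match_window(
                    Dw, _hom_incompat_scores(Dw, haps), haps, counts,
                    none, none, no_pref, rate, int(top_candidates),
                )
                block = D[:, win.cols]
                block[miss_rows] = filled
                D[:, win.cols] = block
    out.haplotypes = None  # phase is not tracked through dosage filling
    return out


def _hom_incompat_scores(Dw: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Homozygote-incompatibility counts (animal x haplotype) via BLAS."""
    hom0 = (Dw == 0).astype(np.float32)
    hom2 = (Dw == 2).astype(np.float32)
    alt = (L == 1).astype(np.float32)
    return hom0 @ alt.T + hom2 @ (1.0 - alt).T


@njit(cache=True)
def _ancestor_closure(mask, sire_row, dam_row):
    """Extend an animal mask to include all ancestors (rows in pedigree
    order, parents before offspring)."""
    for t in range(len(mask) - 1, -1, -1):
        if mask[t]:
            s = sire_row[t]
            if s >= 0:
                mask[s] = True
            d = dam_row[t]
            if d >= 0:
                mask[d] = True


def _transition_map(prev_win: LibraryWindow, win: LibraryWindow) -> np.ndarray:
    """For each previous-window haplotype, its two most common successors.

    Successors are the current-window haplotypes of the reference gametes
    that carried the previous haplotype; -1 pads when there are fewer.
    """
    h_prev = prev_win.haps.shape[0]
    trans = np.full((h_prev, 2), -1, dtype=np.int64)
    inv_prev, inv_now = prev_win.inverse, win.inverse
    order = np.lexsort((inv_now, inv_prev))
    ip, iw = inv_prev[order], inv_now[order]
    start = 0
    n = len(ip)
    while start < n:
        end = start
        while end < n and ip[end] == ip[start]:
            end += 1
        # successors of haplotype ip[start], already sorted by inv_now
        best = (-1, -1)
        second = (-1, -1)
        run_start = start
        for k in range(start, end + 1):
            if k == end or (k > run_start and iw[k] != iw[run_start]):
                run_len = k - run_start
                if run_len > best[0]:
                    second = best
                    best = (run_len, iw[run_start])
                elif run_len > second[0]:
                    second = (run_len, iw[run_start])
                run_start = k
        trans[ip[start], 0] = best[1]
        trans[ip[start], 1] = second[1]
        start = end
    return trans


class HaplotypeImputer(TransformerMixin, BaseEstimator):
    """Estimator facade: fit on a phased reference, transform targets.

    ``fit`` expects a phased :class:`GenotypeMatrix`; ``transform``
    accepts a GenotypeMatrix or a raw dosage matrix aligned to the
    reference variants and returns the same type with missing filled.
    """

    def __init__(self, window_sizes=(500, 250, 125, 62), max_mismatch_per_100=2.0,
                 top_candidates=30, chrom=None):
        self.window_sizes = window_sizes
        self.max_mismatch_per_100 = max_mismatch_per_100
        self.top_candidates = top_candidates
        self.chrom = chrom

    def fit(self, X: GenotypeMatrix, y=None):
        self.library_ = build_haplotype_library(X, self.window_sizes, self.chrom)
        self.n_features_in_ = X.n_variants
        return self

    def transform(self, X, parent_rows=None):
        if isinstance(X, GenotypeMatrix):
            return impute(X, self.library_, self.max_mismatch_per_100,
                          self.top_candidates, parent_rows=parent_rows)
        X = np.asarray(X, dtype=np.int8)
        gm = GenotypeMatrix(
            animal_ids=np.arange(X.shape[0]),
            variant_ids=np.arange(X.shape[1]),
            dosages=X,
        )
        return impute(gm, self.library_, self.max_mismatch_per_100,
                      self.top_candidates, parent_rows=parent_rows).dosages


def fill_residual_missing_with_frequency(
    genotypes: GenotypeMatrix, freqs: np.ndarray
) -> np.ndarray:
    """Continuous dosage matrix with missing cells replaced by 2p."""
    freqs = np.asarray(freqs, dtype=np.float64)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies must be in [0, 1]")
    D = genotypes.dosages.astype(np.float64)
    miss = genotypes.missing_mask
    D[miss] = np.broadcast_to(2.0 * freqs, D.shape)[miss]
    return D


# ---------------------------------------------------------------------------
# Mask-and-restore accuracy harness


@dataclass
class ImputationReport:
    """Concordance of imputed vs true dosages among masked cells."""

    percent_correct: float
    n_masked: int
    n_unresolved: int
    per_chromosome: pd.DataFrame | None = None


def hwe_random_fill_baseline(freqs: np.ndarray) -> float:
    """Expected percent concordance of a random Hardy-Weinberg fill.

    If truth and fill are independent HWE draws at frequency p, the match
    probability is sum of squared genotype frequencies; averaged over
    variants and scaled to percent.
    """
    p = np.asarray(freqs, dtype=np.float64)
    f = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    return float(100.0 * (f**2).sum(axis=0).mean())


def evaluate_imputation(
    full: GenotypeMatrix,
    reference_ids,
    test_ids,
    visible_variants: np.ndarray,
    seed: int = 0,
    window_sizes=(500, 250),
    max_mismatch_per_100: float = 2.0,
    chrom: np.ndarray | None = None,
    unit: str = "genotype",
) -> ImputationReport:
    """Mask test animals outside the visible set, impute, score concordance.

    ``visible_variants`` is a boolean mask or index array over the full
    variant set (the array subset a lower-density chip would observe).
    Cells unresolved after imputation count as incorrect.  ``unit``
    'genotype' scores exact dosage matches; 'allele' scores matched
    alleles out of two per cell.
    """
    test_ids = list(test_ids)
    reference_ids = list(reference_ids)
    if not test_ids:
        raise ValueError("empty test set")
    if set(test_ids) & set(reference_ids):
        raise ValueError("test animals must be disjoint from the reference")
    rows = {a: i for i, a in enumerate(full.animal_ids)}
    ref_rows = np.array([rows[a] for a in reference_ids])
    test_rows = np.array([rows[a] for a in test_ids])

    visible = np.zeros(full.n_variants, dtype=bool)
    visible[np.asarray(visible_variants)] = True

    reference = full.subset_animals(ref_rows)
    library = build_haplotype_library(reference, window_sizes, chrom)

    truth = full.dosages[test_rows]
    masked = np.full(truth.shape, MISSING, dtype=np.int8)
    masked[:, visible] = truth[:, visible]
    target = GenotypeMatrix(
        animal_ids=full.animal_ids[test_rows],
        variant_ids=full.variant_ids,
        dosages=masked,
    )
    imputed = impute(target, library, max_mismatch_per_100)

    eval_mask = np.zeros(truth.shape, dtype=bool)
    eval_mask[:, ~visible] = truth[:, ~visible] != MISSING
    imp = imputed.dosages
    if unit == "allele":
        diff = np.abs(imp.astype(np.int16) - truth)
        score = np.where(imp == MISSING, 0.0, (2.0 - np.minimum(diff, 2)) / 2.0)
        correct = score[eval_mask].sum()
    elif unit == "genotype":
        correct = ((imp == truth) & eval_mask).sum()
    else:
        raise ValueError("unit must be 'genotype' or 'allele'")
    n_masked = int(eval_mask.sum())
    n_unresolved = int(((imp == MISSING) & eval_mask).sum())
    # nothing masked: vacuously perfect restoration
    percent = 100.0 if n_masked == 0 else 100.0 * float(correct) / n_masked

    per_chrom = None
    if chrom is not None:
        recs = []
        for c in pd.unique(chrom):
            cm = eval_mask & (chrom == c)[None, :]
            nc = int(cm.sum())
            ok = int(((imp == truth) & cm).sum())
            recs.append((c, nc, 100.0 * ok / max(nc, 1)))
        per_chrom = pd.DataFrame(
            recs, columns=["chromosome", "n_masked", "percent_correct"]
        )
    logger.info(
        "imputation accuracy %.2f%% over %d masked cells (%d unresolved)",
        percent, n_masked, n_unresolved,
    )
    return ImputationReport(
        percent_correct=percent,
        n_masked=n_masked,
        n_unresolved=n_unresolved,
        per_chromosome=per_chrom,
    )
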