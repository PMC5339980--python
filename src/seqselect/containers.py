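"""Shared domain containers for the variant-selection pipeline.

The pipeline moves four kinds of data between stages: a pedigree (who
descends from whom), a variant catalog (where the variants are and which
array tiers carry them), genotypes (dosages, optionally phased haplotypes
and per-call probabilities), and the simulated trait architecture (QTL
positions, substitution effects, per-locus variances).  Everything is
numpy-backed; pandas frames are used only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse

MISSING = -1  # dosage code for a missing genotype call


# ---------------------------------------------------------------------------
# Pedigree


@dataclass
class Pedigree:
    """Pedigree in generation order.

    ``sire`` and ``dam`` hold row indices into ``ids`` (-1 for an unknown
    parent).  Construction enforces that ids are unique and that every
    known parent appears before its offspring, which also rules out an
    animal being its own ancestor.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("pedigree ids are not unique")
        for parents in (self.sire, self.dam):
            if parents.shape != (n,):
                raise ValueError("parent index arrays must match ids")
            bad = (parents >= np.arange(n)) & (parents != MISSING)
            if bad.any():
                raise ValueError(
                    "pedigree is not in generation order: parent at or after "
                    f"offspring for rows {np.nonzero(bad)[0][:5]}"
                )
            if (parents < MISSING).any():
                raise ValueError("parent indices must be >= -1")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == MISSING) & (self.dam == MISSING)

    @classmethod
    def from_records(cls, records, missing_tokens=("0", ".", "", "NA")) -> "Pedigree":
        """Build from (animal, sire, dam) id triples in generation order."""
        records = list(records)
        ids = [str(r[0]) for r in records]
        index = {a: i for i, a in enumerate(ids)}
        if len(index) != len(ids):
            raise ValueError("pedigree ids are not unique")

        def resolve(tok):
            tok = str(tok)
            if tok in missing_tokens:
                return MISSING
            if tok not in index:
                raise ValueError(f"parent {tok!r} not found among earlier animals")
            return index[tok]

        sire = np.array([resolve(r[1]) for r in records], dtype=np.int64)
        dam = np.array([resolve(r[2]) for r in records], dtype=np.int64)
        return cls(np.array(ids, dtype=object), sire, dam)

    def to_frame(self) -> pd.DataFrame:
        def tok(idx):
            return np.where(idx == MISSING, "0", self.ids[np.maximum(idx, 0)])

        return pd.DataFrame(
            {"animal": self.ids, "sire": tok(self.sire), "dam": tok(self.dam)}
        )

    # -- relationship algebra -------------------------------------------------

    def a_matrix(self) -> np.ndarray:
        """Dense additive (numerator) relationship matrix, tabular method."""
        n = self.n
        A = np.zeros((n, n))
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            if s != MISSING and d != MISSING:
                A[i, i] = 1.0 + 0.5 * A[s, d]
            else:
                A[i, i] = 1.0
            row = np.zeros(i)
            if s != MISSING:
                row += 0.5 * A[s, :i]
            if d != MISSING:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        return A

    def a_inverse(self) -> sparse.csr_matrix:
        """Sparse inverse of A by Henderson's rules (inbreeding ignored).

        The Mendelian-sampling variance is 1/2, 3/4 or 1 according to
        whether two, one or no parents are known.
        """
        rows, cols, vals = [], [], []

        def add(i, j, v):
            rows.append(i)
            cols.append(j)
            vals.append(v)

        for i in range(self.n):
            s, d = self.sire[i], self.dam[i]
            known = [p for p in (s, d) if p != MISSING]
            w = 1.0 / (1.0 - 0.25 * len(known))  # 1, 4/3 or 2
            add(i, i, w)
            for p in known:
                add(i, p, -0.5 * w)
                add(p, i, -0.5 * w)
                for p2 in known:
                    add(p, p2, 0.25 * w)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))


# ---------------------------------------------------------------------------
# Variant catalog


@dataclass
class VariantCatalog:
    """Per-variant coordinates, alleles, frequencies and membership flags.

    Tier flags model nested genotyping arrays: every 12k-analogue variant
    is on the 60k analogue, every 60k variant on the 600k analogue, and
    every array variant is a sequence variant.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    freq: np.ndarray
    in_sequence: np.ndarray = None
    in_600k: np.ndarray = None
    in_60k: np.ndarray = None
    in_12k: np.ndarray = None
    genic: np.ndarray = None
    protected: np.ndarray = None
    ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.freq = np.asarray(self.freq, dtype=np.float64)
        m = self.n
        for name, default in [
            ("in_sequence", True),
            ("in_600k", False),
            ("in_60k", False),
            ("in_12k", False),
            ("genic", False),
            ("protected", False),
        ]:
            v = getattr(self, name)
            v = np.full(m, default) if v is None else np.asarray(v, dtype=bool)
            setattr(self, name, v)
        if self.ids is None:
            self.ids = np.array(
                [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)], dtype=object
            )
        else:
            self.ids = np.asarray(self.ids, dtype=object)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.pos)

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.freq, 1.0 - self.freq)

    def validate(self) -> None:
        if ((self.freq < 0) | (self.freq > 1)).any():
            raise ValueError("frequencies must be in [0, 1]")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if (np.diff(p) <= 0).any():
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        for lower, upper in [
            (self.in_12k, self.in_60k),
            (self.in_60k, self.in_600k),
            (self.in_600k, self.in_sequence),
        ]:
            if (lower & ~upper).any():
                raise ValueError("array tiers are not nested")

    def subset(self, mask_or_index) -> "VariantCatalog":
        i = np.asarray(mask_or_index)
        return VariantCatalog(
            chrom=self.chrom[i],
            pos=self.pos[i],
            ref=self.ref[i],
            alt=self.alt[i],
            freq=self.freq[i],
            in_sequence=self.in_sequence[i],
            in_600k=self.in_600k[i],
            in_60k=self.in_60k[i],
            in_12k=self.in_12k[i],
            genic=self.genic[i],
            protected=self.protected[i],
            ids=self.ids[i],
        )

    def replace(self, **kwargs) -> "VariantCatalog":
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "freq": self.freq,
                "in_sequence": self.in_sequence,
                "in_600k": self.in_600k,
                "in_60k": self.in_60k,
                "in_12k": self.in_12k,
                "genic": self.genic,
                "protected": self.protected,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VariantCatalog":
        kw = {}
        for col in [
            "chrom", "pos", "ref", "alt", "freq",
            "in_sequence", "in_600k", "in_60k", "in_12k", "genic", "protected",
        ]:
            if col in df.columns:
                kw[col] = df[col].to_numpy()
        if "id" in df.columns:
            kw["ids"] = df["id"].to_numpy()
        return cls(**kw)


# ---------------------------------------------------------------------------
# Genotypes


@dataclass
class GenotypeMatrix:
    """Animals x variants dosage codes {0,1,2,-1} with optional extras.

    ``haplotypes`` (animals x 2 x variants, alleles 0/1) carries phase when
    the genotypes came from simulation or a phased reference; ``call_probs``
    (animals x variants x 3) carries the AA/AB/BB posterior probabilities
    used by the genotype-probability edit.
    """

    animal_ids: np.ndarray
    variant_ids: np.ndarray
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None
    call_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = len(self.animal_ids), len(self.variant_ids)
        if self.dosages.shape != (n, m):
            raise ValueError("dosage matrix shape does not match ids")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (n, 2, m):
                raise ValueError("haplotype array must be animals x 2 x variants")
        if self.call_probs is not None:
            self.call_probs = np.asarray(self.call_probs, dtype=np.float64)
            if self.call_probs.shape != (n, m, 3):
                raise ValueError("call_probs must be animals x variants x 3")

    @classmethod
    def from_haplotypes(cls, animal_ids, variant_ids, haplotypes) -> "GenotypeMatrix":
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        return cls(
            animal_ids=animal_ids,
            variant_ids=variant_ids,
            dosages=haplotypes.sum(axis=1, dtype=np.int8),
            haplotypes=haplotypes,
        )

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per variant from non-missing calls.

        Monomorphic-by-missingness columns (no calls at all) get 0.
        """
        d = self.dosages
        called = d != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), 0.0)
        return p

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            animal_ids=self.animal_ids.copy(),
            variant_ids=self.variant_ids.copy(),
            dosages=self.dosages.copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes.copy(),
            call_probs=None if self.call_probs is None else self.call_probs.copy(),
        )

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        i = np.asarray(mask_or_index)
        return GenotypeMatrix(
            animal_ids=self.animal_ids,
            variant_ids=self.variant_ids[i],
            dosages=self.dosages[:, i],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, i],
            call_probs=None if self.call_probs is None else self.call_probs[:, i, :],
        )

    def subset_animals(self, mask_or_index) -> "GenotypeMatrix":
        i = np.asarray(mask_or_index)
        return GenotypeMatrix(
            animal_ids=self.animal_ids[i],
            variant_ids=self.variant_ids,
            dosages=self.dosages[i],
            haplotypes=None if self.haplotypes is None else self.haplotypes[i],
            call_probs=None if self.call_probs is None else self.call_probs[i],
        )


# ---------------------------------------------------------------------------
# Trait architecture and phenotypes


@dataclass
class QTLArchitecture:
    """Heavy-tailed QTL effects for one or more traits at shared loci.

    ``indices`` are catalog/genotype column indices of the QTL; ``q`` the
    underlying standard-normal draws, ``alpha`` the substitution effects
    q * base^(|q|-2) and ``v`` the per-locus variances 2p(1-p)alpha^2,
    each with shape (n_traits, n_qtl).
    """

    indices: np.ndarray
    q: np.ndarray
    alpha: np.ndarray
    v: np.ndarray
    base: float = 2.7

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.q = np.atleast_2d(np.asarray(self.q, dtype=np.float64))
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=np.float64))
        self.v = np.atleast_2d(np.asarray(self.v, dtype=np.float64))
        k = len(self.indices)
        if self.q.shape[1] != k or self.alpha.shape != self.q.shape or self.v.shape != self.q.shape:
            raise ValueError("q, alpha and v must be (n_traits, n_qtl)")
        if (self.v < 0).any():
            raise ValueError("per-locus variances must be non-negative")

    @property
    def n_traits(self) -> int:
        return self.q.shape[0]

    @property
    def n_qtl(self) -> int:
        return len(self.indices)


@dataclass
class TraitPhenotypes:
    """True breeding values and noisy observations per animal per trait."""

    tbv: np.ndarray
    y: np.ndarray
    reliability: np.ndarray

    def __post_init__(self) -> None:
        self.tbv = np.atleast_2d(np.asarray(self.tbv, dtype=np.float64).T).T
        self.y = np.atleast_2d(np.asarray(self.y, dtype=np.float64).T).T
        self.reliability = np.asarray(self.reliability, dtype=np.float64)
        if self.y.shape != self.tbv.shape:
            raise ValueError("y and tbv shapes differ")
        if ((self.reliability <= 0) | (self.reliability > 1)).any():
            raise ValueError("reliabilities must be in (0, 1]")

    @property
    def n_traits(self) -> int:
        return self.tbv.shape[1]
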