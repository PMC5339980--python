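"""File formats: minimal VCF, dosage-matrix text, pedigree and catalog tables.

The VCF dialect is VCFv4.2 with GT required and GP optional; phased bar
separators are preserved through a round trip.  The dosage matrix is the
internal interchange format: a TSV with a header row of variant ids,
one row per animal, dosages in {0,1,2} and missing written as NA.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, Pedigree, VariantCatalog

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF


def read_vcf_minimal(path) -> tuple[VariantCatalog, GenotypeMatrix]:
    """Read a VCF with GT (and optional GP) into catalog + genotypes.

    Multi-allelic records are skipped with a logged count.  Positions are
    1-based as in the VCF.  Phase is kept when every call is phased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    chroms, positions, refs, alts = [], [], [], []
    dosage_rows, gp_rows, hap_rows = [], [], []
    n_multi = 0
    all_phased = True
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        chroms.append(int(str(variant.CHROM).lstrip("chr")))
        positions.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        gts = variant.genotypes  # [allele0, allele1, phased]
        d = np.empty(len(samples), dtype=np.int8)
        h = np.empty((len(samples), 2), dtype=np.int8)
        for i, (a, b, phased) in enumerate(gts):
            if a < 0 or b < 0:
                d[i] = MISSING
                h[i] = MISSING
                all_phased = False
            else:
                d[i] = a + b
                h[i, 0], h[i, 1] = a, b
                if not phased:
                    all_phased = False
        dosage_rows.append(d)
        hap_rows.append(h)
        try:
            gp = variant.format("GP")
        except KeyError:
            gp = None
        gp_rows.append(None if gp is None else np.asarray(gp, dtype=np.float64))
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    if not positions:
        raise ValueError("no usable biallelic records in VCF")
    m = len(positions)
    dosages = np.stack(dosage_rows, axis=1)
    freq = GenotypeMatrix(samples, np.arange(m), dosages).allele_frequencies()
    catalog = VariantCatalog(
        chrom=np.array(chroms),
        pos=np.array(positions),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        freq=freq,
    )
    haplotypes = None
    if all_phased:
        haplotypes = np.stack(hap_rows, axis=2)  # (n, 2, m)
    call_probs = None
    if all(g is not None for g in gp_rows):
        call_probs = np.stack(gp_rows, axis=1)
    gm = GenotypeMatrix(
        animal_ids=samples,
        variant_ids=catalog.ids,
        dosages=dosages,
        haplotypes=haplotypes,
        call_probs=call_probs,
    )
    return catalog, gm


_GT_UNPHASED = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf_minimal(
    path, catalog: VariantCatalog, genotypes: GenotypeMatrix, write_gp: bool = False
) -> None:
    """Write the minimal GT(+GP) dialect; phased calls use '|'."""
    if write_gp and genotypes.call_probs is None:
        raise ValueError("no call probabilities to write")
    fmt = "GT:GP" if write_gp else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in np.unique(catalog.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if write_gp:
            fh.write(
                '##FORMAT=<ID=GP,Number=G,Type=Float,'
                'Description="Genotype probabilities">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.animal_ids))
            + "\n"
        )
        H = genotypes.haplotypes
        for k in range(catalog.n):
            fields = [
                str(catalog.chrom[k]), str(catalog.pos[k]), str(catalog.ids[k]),
                str(catalog.ref[k]), str(catalog.alt[k]), ".", "PASS", ".", fmt,
            ]
            for i in range(genotypes.n_animals):
                if H is not None and genotypes.dosages[i, k] != MISSING:
                    gt = f"{H[i, 0, k]}|{H[i, 1, k]}"
                else:
                    gt = _GT_UNPHASED[int(genotypes.dosages[i, k])]
                if write_gp:
                    gp = genotypes.call_probs[i, k]
                    gt += ":" + ",".join(f"{x:.4f}" for x in gp)
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Dosage matrix


def write_dosage_matrix(path, genotypes: GenotypeMatrix) -> None:
    df = pd.DataFrame(
        genotypes.dosages.astype(object),
        index=pd.Index(genotypes.animal_ids, name="animal"),
        columns=genotypes.variant_ids,
    )
    df = df.where(genotypes.dosages != MISSING, "NA")
    df.to_csv(path, sep="\t")


def read_dosage_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    dosages = df.to_numpy(dtype=np.float64)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    return GenotypeMatrix(
        animal_ids=df.index.to_numpy(dtype=object),
        variant_ids=df.columns.to_numpy(dtype=object),
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# Pedigree and catalog tables


def write_pedigree(path, pedigree: Pedigree) -> None:
    pedigree.to_frame().to_csv(path, sep=" ", index=False, header=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["animal", "sire", "dam"], dtype=str)
    return Pedigree.from_records(df.itertuples(index=False))


def write_catalog(path, catalog: VariantCatalog) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_catalog(path) -> VariantCatalog:
    return VariantCatalog.from_frame(pd.read_csv(path, sep="\t"))


def read_regions(path) -> list[tuple[int, int, int]]:
    """Region file: whitespace-separated chrom start end, 1-based inclusive."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        c, s, e = line.split()[:3]
        out.append((int(c), int(s), int(e)))
    return out
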