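"""End-to-end experiment driver: simulate, edit, impute, select, predict,
validate.

The driver reproduces, at desk scale, the comparison of prediction
scenarios from nested genotyping tiers: parent average only, the base
medium-density array, the base array plus variants selected from a
denser pool by estimated effect, and the true QTL alone (the ceiling).
Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import editing, imputation, prediction, selection, simdata, validation
from .config import ExperimentConfig
from .containers import MISSING, GenotypeMatrix, Pedigree, QTLArchitecture, TraitPhenotypes, VariantCatalog

logger = logging.getLogger(__name__)

SCENARIOS = ("parent_average", "base_array", "base_plus_selected", "qtl_only")


@dataclass
class ExperimentResult:
    """Everything a downstream analysis (or test) needs from one run."""

    config: ExperimentConfig
    seed: int
    catalog: VariantCatalog
    pedigree: Pedigree
    arch: QTLArchitecture
    phenotypes: TraitPhenotypes
    edit_report: pd.DataFrame
    reliability: pd.DataFrame              # trait x scenario table
    selected_extra: np.ndarray             # selected variants beyond the base array
    working_variants: np.ndarray           # catalog indices of the imputed set
    centered: np.ndarray                   # animals x working variants, centered
    working_freq: np.ndarray
    reference_rows: np.ndarray
    validation_rows: np.ndarray
    animal_tier: np.ndarray                # per animal: 'seq','600k','60k','12k'
    marker_sets: dict = field(default_factory=dict)  # scenario -> working-set columns


def _assign_animal_tiers(n: int, scale, rng: np.random.Generator) -> np.ndarray:
    """Genotyping density per animal: oldest animals densest, the small
    low-density tier scattered among the remainder."""
    tier = np.full(n, "60k", dtype=object)
    n_seq = int(round(scale.frac_sequence * n))
    n_600 = int(round(scale.frac_600k * n))
    n_12 = int(round(scale.frac_12k * n))
    tier[:n_seq] = "seq"
    tier[n_seq : n_seq + n_600] = "600k"
    if n_12 > 0:
        rest = np.arange(n_seq + n_600, n)
        tier[rng.choice(rest, size=n_12, replace=False)] = "12k"
    return tier


def run_experiment(config: ExperimentConfig | None = None, seed: int | None = None,
                   outdir=None) -> ExperimentResult:
    """Run the full pipeline under one config and master seed."""
    cfg = config or ExperimentConfig()
    seed = cfg.seed if seed is None else int(seed)
    sc = cfg.scale

    # --- simulate -----------------------------------------------------------
    catalog = simdata.build_catalog(
        sc.n_chromosomes, sc.variants_per_chromosome, sc.chromosome_length_bp, seed
    )
    catalog = simdata.assign_array_subsets(catalog, sc.tier_sizes)
    pedigree = simdata.simulate_pedigree(
        sc.n_founders, sc.n_generations, sc.per_generation, sc.n_sires, seed
    )
    founders = simdata.simulate_founder_haplotypes(
        int(pedigree.is_founder.sum()), catalog, sc.ld_param, seed,
        pool_size=sc.pool_size,
        founder_ids=pedigree.ids[pedigree.is_founder],
    )
    geno = simdata.drop_through_pedigree(
        founders, pedigree, sc.chrom_length_morgans, seed, catalog,
        sc.chromosome_length_bp,
    )
    freq = geno.allele_frequencies()
    catalog = catalog.replace(freq=freq)
    arch = simdata.simulate_qtl_effects(
        sc.n_qtl, catalog, sc.heavy_tail_base, seed, n_traits=sc.n_traits
    )
    tbv = simdata.compute_tbv(geno, arch)
    phen = simdata.simulate_phenotypes(tbv, sc.reliability, seed)
    logger.info("simulated %d animals x %d variants, %d QTL x %d traits",
                geno.n_animals, catalog.n, arch.n_qtl, arch.n_traits)

    # --- edit ---------------------------------------------------------------
    qtl_regions = [
        (int(catalog.chrom[i]), int(catalog.pos[i]), int(catalog.pos[i]))
        for i in arch.indices
    ]
    catalog = editing.annotate_genic(catalog, qtl_regions, cfg.edits.genic_distance)
    edit_cfg = editing.EditConfig(
        maf_min=cfg.edits.maf_min, ld_rmax=cfg.edits.ld_rmax,
        ld_window=cfg.edits.ld_window, ld_window_mode=cfg.edits.ld_window_mode,
        genic_distance=cfg.edits.genic_distance,
    )
    keep, edit_report = editing.apply_variant_edits(geno, catalog, edit_cfg)

    # --- impute -------------------------------------------------------------
    # working set: everything prediction or selection may touch — the dense
    # array tier, the genic (near-QTL) sequence variants, and the QTL
    working_mask = keep & (catalog.in_600k | catalog.genic)
    working_mask[arch.indices] = True
    working = np.flatnonzero(working_mask)
    col_of = np.full(catalog.n, -1, dtype=np.int64)
    col_of[working] = np.arange(len(working))

    tier = _assign_animal_tiers(
        geno.n_animals, sc, simdata.stage_rng(seed, "tiers")
    )
    visible = {
        "seq": working_mask,
        "600k": catalog.in_600k,
        "60k": catalog.in_60k,
        "12k": catalog.in_12k,
    }
    truth_w = geno.dosages[:, working]
    observed = np.full(truth_w.shape, MISSING, dtype=np.int8)
    for name, vmask in visible.items():
        rows = np.flatnonzero(tier == name)
        cols = np.flatnonzero((vmask & working_mask)[working])
        observed[np.ix_(rows, cols)] = truth_w[np.ix_(rows, cols)]

    seq_rows = np.flatnonzero(tier == "seq")
    reference_panel = GenotypeMatrix.from_haplotypes(
        geno.animal_ids[seq_rows], catalog.ids[working],
        geno.haplotypes[np.ix_(seq_rows, [0, 1], working)],
    )
    target = GenotypeMatrix(
        animal_ids=geno.animal_ids, variant_ids=catalog.ids[working],
        dosages=observed,
    )
    imputer = imputation.HaplotypeImputer(
        window_sizes=tuple(cfg.imputation.window_sizes),
        max_mismatch_per_100=cfg.imputation.max_mismatch_per_100,
        top_candidates=cfg.imputation.top_candidates,
        chrom=catalog.chrom[working],
    ).fit(reference_panel)
    parent_rows = np.column_stack([pedigree.sire, pedigree.dam])
    imputed = imputer.transform(target, parent_rows=parent_rows)
    n_unresolved = int(imputed.missing_mask.sum())
    logger.info("imputed working set of %d variants (%d cells left missing)",
                len(working), n_unresolved)
    working_freq = freq[working]
    filled = imputation.fill_residual_missing_with_frequency(imputed, working_freq)
    centered = prediction.center_genotypes(filled, working_freq)

    # --- split and marker sets ---------------------------------------------
    n = geno.n_animals
    n_val = int(round(sc.validation_fraction * n))
    reference_rows = np.arange(n - n_val)
    validation_rows = np.arange(n - n_val, n)

    base_cols = col_of[np.flatnonzero(catalog.in_60k & working_mask)]
    pool_cols = np.arange(len(working))
    qtl_cols = col_of[arch.indices]

    # --- select -------------------------------------------------------------
    sel = cfg.selection
    Xref = centered[reference_rows]
    yref = phen.y[reference_rows]
    Rref = phen.reliability[reference_rows]
    scores = np.zeros((sc.n_traits, len(pool_cols)))
    if sel.method == "gwa":
        for t in range(sc.n_traits):
            scan = selection.gwa_scan(Xref[:, pool_cols], yref[:, t],
                                      polygenic_h2=0.0)
            scores[t] = -np.log10(np.maximum(scan["p"].to_numpy(),
                                             np.finfo(float).tiny))
    else:
        for t in range(sc.n_traits):
            eff = prediction.estimate_effects(
                Xref[:, pool_cols], yref[:, t] - yref[:, t].mean(), weights=Rref,
                mode=cfg.prediction.mode, polygenic_fraction=0.0,
                curve=cfg.prediction.curve, tol=sel.fit_tol,
                max_iter=sel.fit_max_iter, cap=cfg.prediction.cap,
            )
            if sel.method == "effect_variance":
                scores[t] = selection.effect_variance_scores(
                    eff.alpha, working_freq[pool_cols]
                )
            else:
                scores[t] = np.abs(eff.alpha)
    if sel.average_traits:
        result = selection.select_top_average_across_traits(scores, sel.top_per_trait)
    else:
        result = selection.select_top_per_trait_and_merge(
            scores, sel.top_per_trait, method=sel.method
        )
    selected_cols = pool_cols[result.selected]
    if sel.window_prune_bp > 0:
        selected_cols = selection.window_prune_for_array(
            selected_cols, scores.max(axis=0), catalog.pos[working],
            catalog.chrom[working], sel.window_prune_bp,
        )
    extra_cols = np.setdiff1d(selected_cols, base_cols)
    marker_sets = {
        "base_array": base_cols,
        "base_plus_selected": np.union1d(base_cols, extra_cols),
        "qtl_only": qtl_cols,
    }

    # --- predict + validate -------------------------------------------------
    pc = cfg.prediction
    rows = []
    val_tbv = phen.tbv[validation_rows]
    # parent average of phenotype-based evaluations; validation animals'
    # own phenotypes contribute nothing
    eval_values = np.zeros_like(phen.y)
    eval_values[reference_rows] = phen.y[reference_rows] - phen.y[reference_rows].mean(axis=0)
    pa = prediction.parent_average(pedigree, eval_values)
    for t in range(sc.n_traits):
        rows.append((f"trait{t + 1}", "parent_average",
                     validation.reliability_vs_tbv(pa[validation_rows, t], val_tbv[:, t]),
                     validation.regression_slope(val_tbv[:, t], pa[validation_rows, t])))
    for scenario in ("base_array", "base_plus_selected", "qtl_only"):
        cols = marker_sets[scenario]
        if scenario == "qtl_only":
            # ceiling run: true heavy-tail parameter, no cap, no polygenic
            est_kwargs = dict(mode="nonlinear", polygenic_fraction=0.0,
                              curve=sc.heavy_tail_base, cap=None)
        else:
            est_kwargs = dict(mode=pc.mode, polygenic_fraction=pc.polygenic_fraction,
                              curve=pc.curve, cap=pc.cap)
        for t in range(sc.n_traits):
            est = prediction.SNPEffectRegressor(
                tol=pc.tol, max_iter=pc.max_iter, **est_kwargs
            ).fit(
                centered[np.ix_(reference_rows, cols)], yref[:, t],
                reliabilities=Rref,
                pedigree=pedigree if est_kwargs["polygenic_fraction"] > 0 else None,
                ped_index=reference_rows,
            )
            gebv = est.predict(centered[np.ix_(validation_rows, cols)],
                               ped_index=validation_rows
                               if est.polygenic_ is not None else None)
            rows.append((f"trait{t + 1}", scenario,
                         validation.reliability_vs_tbv(gebv, val_tbv[:, t]),
                         validation.regression_slope(val_tbv[:, t], gebv)))
    reliability = pd.DataFrame(
        rows, columns=["trait", "scenario", "reliability", "slope"]
    )

    result_bundle = ExperimentResult(
        config=cfg, seed=seed, catalog=catalog, pedigree=pedigree, arch=arch,
        phenotypes=phen, edit_report=edit_report, reliability=reliability,
        selected_extra=working[extra_cols], working_variants=working,
        centered=centered, working_freq=working_freq,
        reference_rows=reference_rows, validation_rows=validation_rows,
        animal_tier=tier, marker_sets=marker_sets,
    )
    if outdir is not None:
        _write_reports(result_bundle, Path(outdir))
    return result_bundle


def _write_reports(res: ExperimentResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    rel = res.reliability.copy()
    rel["reliability"] = rel["reliability"].map(lambda x: fmt % x)
    rel["slope"] = rel["slope"].map(lambda x: fmt % x)
    rel.to_csv(outdir / "reliability.tsv", sep="\t", index=False)
    res.edit_report.to_csv(outdir / "edit_report.tsv", sep="\t", index=False)
    sel = res.catalog.to_frame().iloc[res.selected_extra][["id", "chrom", "pos"]]
    sel.to_csv(outdir / "selected_variants.tsv", sep="\t", index=False)
    res.config.to_yaml(outdir / "config.yaml")


def scenario_means(reliability: pd.DataFrame) -> pd.Series:
    """Mean reliability per scenario across traits."""
    return reliability.groupby("scenario")["reliability"].mean()
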