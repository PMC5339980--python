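"""Experiment configuration: validated, serialisable, no unknown keys.

Defaults define the desk-scale study: 3 chromosomes x 30,000 sequence
variants, 3,000 animals over 10 discrete generations, 500 QTL and 5
traits, with nested array analogues of 18,000 / 6,000 / 1,200 variants.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimScale(_Strict):
    n_chromosomes: int = 3
    variants_per_chromosome: int = 30_000
    chromosome_length_bp: int = 100_000_000
    chrom_length_morgans: float = 1.0
    n_founders: int = 300
    n_generations: int = 9
    per_generation: int = 300
    n_sires: int = 25
    # calibrated so founders reproduce the real-data LD summary (mean max
    # |r| with +-350 neighbours ~ 0.96) at this variant density; it is the
    # per-base-pair equivalent of 0.9998 at full sequence density
    ld_param: float = 0.9933
    pool_size: int = 4
    n_qtl: int = 500
    n_traits: int = 5
    heavy_tail_base: float = 2.7
    tier_sizes: tuple[int, int, int] = (18_000, 6_000, 1_200)
    reliability: float = 0.9
    # fractions of animals genotyped at sequence, 600k-analogue and
    # 12k-analogue density; the rest get the 60k analogue.  The real
    # population was ~3.7% sequenced / 2.9% 600k / 92% 60k / 1.3% 12k;
    # sequence and 600k tiers go to the oldest (most-used) animals while
    # the small 12k tier is scattered among the rest.  The sequence
    # fraction is higher than the real one so the desk-scale reference
    # library is not unusably thin.
    frac_sequence: float = 0.10
    frac_600k: float = 0.05
    frac_12k: float = 0.02
    validation_fraction: float = 0.20


class EditSettings(_Strict):
    maf_min: float = 0.01
    ld_rmax: float = 0.95
    ld_window: int = 350
    ld_window_mode: str = "kept"
    genic_distance: int = 2500
    gprob_threshold: float = 0.98
    miss_max_low: float = 0.05
    miss_maf_cut: float = 0.10
    het_excess_factor: float = 1.5
    orientation_rmin: float = 0.95


class ImputeSettings(_Strict):
    window_sizes: tuple[int, ...] = (500, 250, 125, 62)
    max_mismatch_per_100: float = 2.0
    top_candidates: int = 30


class SelectSettings(_Strict):
    method: str = "effect_size"  # gwa | effect_size | effect_variance
    top_per_trait: int = 400
    window_prune_bp: int = 0  # 0 disables window thinning
    average_traits: bool = False
    fit_max_iter: int = 60  # ranking fit needs fewer rounds than prediction
    fit_tol: float = 1e-4


class PredictSettings(_Strict):
    mode: str = "nonlinear"
    polygenic_fraction: float = 0.10
    curve: float = 1.12
    cap: float = 5.0
    tol: float = 1e-4
    max_iter: int = 150


class ExperimentConfig(_Strict):
    scale: SimScale = SimScale()
    edits: EditSettings = EditSettings()
    imputation: ImputeSettings = ImputeSettings()
    selection: SelectSettings = SelectSettings()
    prediction: PredictSettings = PredictSettings()
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            data = yaml.safe_load(Path(source).read_text())
        else:
            data = yaml.safe_load(str(source))
        return cls.model_validate(data or {})
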