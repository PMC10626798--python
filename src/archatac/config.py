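"""Simulation and pipeline configuration.

The default ``SimConfig`` describes a desk-scale stand-in for a haloarchaeal
genome: a main chromosome plus four plasmids at very unequal per-cell copy
numbers (the smallest plasmid at ~26 copies per chromosome, an intermediate
one at ~1.4, the two large ones at 1:1), with promoter-localised Tn5
accessibility, a unimodal ~95 bp fragment-length model, GC-dependent
insertion bias, per-condition single-molecule protection levels, and a
transcription model with promoter-proximal pausing, operon-internal
initiation and a dormant-culture single-locus ssDNA peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SimConfig:
    # --- genome topology -------------------------------------------------
    replicon_names: tuple[str, ...] = ("chr", "pHV4", "pHV3", "pHV1", "pHV2")
    replicon_lengths: tuple[int, ...] = (400_000, 150_000, 120_000, 30_000, 6_000)
    copy_numbers: tuple[float, ...] = (1.0, 1.0, 1.0, 1.4, 26.0)
    main: str = "chr"
    genome_seed: int = 20_23  # the genome itself is a fixed function of the config

    # --- gene / operon model --------------------------------------------
    n_genes: int = 200
    gene_length_log_mean: float = 6.7   # lognormal, median ~810 bp
    gene_length_log_sd: float = 0.35
    min_gene_length: int = 300
    operon_size_probs: tuple[float, ...] = (0.5, 0.2, 0.12, 0.08, 0.06, 0.04)  # sizes 1..6
    intergenic_gap_range: tuple[int, int] = (150, 500)
    operon_gap_range: tuple[int, int] = (20, 80)

    # --- GC profile ------------------------------------------------------
    gc_intergenic: float = 0.58
    gc_genic: float = 0.62
    gc_promoter: float = 0.42   # AT-rich TATA/BRE-style promoter elements
    n_gc_patches: int = 8
    gc_patch: float = 0.75
    gc_patch_length: int = 4_000

    # --- ATAC model ------------------------------------------------------
    atac_background: float = 1.0        # insertion weight per accessible bp
    atac_enrichment: float = 8.0        # promoter weight multiplier per unit accessibility
    promoter_halfwidth: int = 100       # promoter window = TSS +/- this
    accessibility_log_sd: float = 0.5   # per-gene lognormal accessibility spread
    frag_len_mode: int = 95
    frag_len_log_sd: float = 0.18
    frag_len_min: int = 30
    frag_len_max: int = 500
    gc_bias_slope: float = -3.0         # exp(slope * (local GC - genome GC))
    gc_bias_window: int = 200

    # --- protection / footprinting model --------------------------------
    # per-condition per-site accessibility (methylation) probability
    accessibility_prob: dict[str, float] = field(
        default_factory=lambda: {"exponential": 0.15, "stationary": 0.11}
    )
    footprint_window: tuple[int, int] = (-60, -10)  # relative to TSS, oriented
    footprint_occupancy: float = 0.05
    footprint_leak: float = 0.02
    molecule_promoter_fraction: float = 0.5  # molecules anchored at promoters vs uniform

    # --- transcription (KAS) model ---------------------------------------
    kas_background: float = 0.05        # per-bp baseline ssDNA weight
    kas_rate_log_sd: float = 1.0        # per-gene lognormal rate spread
    kas_pause_enrichment: float = 5.0   # promoter-proximal pause multiplier
    kas_pause_window: int = 50          # bp downstream of TSS
    kas_changed_fraction: float = 0.3   # genes with altered rate in "stationary"
    kas_change_log2fc: float = 2.0      # magnitude of the rate shift (sign random)
    internal_start_fraction: float = 0.25  # multi-gene operons with an internal TSS
    internal_start_boost: float = 5.0
    dormant_rate: float = 0.001         # residual gene rate in the dormant condition
    dormant_background: float = 0.002   # near-silent baseline in the dormant condition
    dormant_peak_weight: float = 10.0   # per-bp weight of the CRISPR-locus peak
    read_length: int = 50               # KAS read length

    # --- CRISPR-like locus -----------------------------------------------
    crispr_replicon_index: int = 1      # placed on the pHV4 analog
    crispr_repeat_length: int = 30
    crispr_spacer_length: int = 35
    crispr_n_repeats: int = 20
    crispr_peak_width: int = 500

    def __post_init__(self) -> None:
        n = len(self.replicon_names)
        if len(self.replicon_lengths) != n or len(self.copy_numbers) != n:
            raise ValueError("replicon names, lengths and copy numbers must align")
        if any(c <= 0 for c in self.copy_numbers):
            raise ValueError("copy numbers must be > 0")
        if self.main not in self.replicon_names:
            raise ValueError(f"main replicon {self.main!r} not in replicon names")
        for cond, p in self.accessibility_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accessibility probability for {cond!r} outside [0,1]")
        for p in (self.footprint_occupancy, self.footprint_leak,
                  self.molecule_promoter_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if not (self.frag_len_min <= self.frag_len_mode <= self.frag_len_max):
            raise ValueError("fragment length mode must lie within its support")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.accessibility_prob) + ("dormant",)

    # conditions that carry a KAS/ATAC signal model
    def require_condition(self, condition: str) -> None:
        if condition not in self.conditions:
            raise ValueError(
                f"unknown condition {condition!r}; configured: {self.conditions}"
            )

    @classmethod
    def small(cls, **overrides) -> "SimConfig":
        """A miniature genome for fast tests (same structure, ~20x smaller)."""
        defaults = dict(
            replicon_names=("chr", "pA", "pB"),
            replicon_lengths=(60_000, 20_000, 4_000),
            copy_numbers=(1.0, 1.4, 26.0),
            n_genes=40,
            n_gc_patches=1,
            crispr_replicon_index=1,
            crispr_n_repeats=8,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("replicon_names", "replicon_lengths", "copy_numbers",
                    "operon_size_probs", "footprint_window",
                    "intergenic_gap_range", "operon_gap_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)
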