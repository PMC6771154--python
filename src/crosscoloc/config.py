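"""Pipeline configuration: every tunable threshold with its standard default."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .enrichment import THRESHOLDS


@dataclass
class PipelineConfig:
    """All parameters of the end-to-end workflow.

    Defaults are the conventional values for this analysis: MAF > 0.01 and
    info > 0.8 variant QC; pruning at r² 0.2 in 500-kb windows stepping 20
    retained SNPs; shared regions at p < 1e-3 and distinct regions at
    p < 1e-5, chained under 100-kb gaps with >= 10 SNPs; lead pairing under
    250 kb; 1000 null replicates; colocalization priors p1 = p2 = 1e-4,
    p12 = 1e-5 with a N(0, 0.2²) effect prior.
    """

    # inputs
    trait_a: str = ""
    traits_b: list[str] = field(default_factory=list)
    ld_reference: str = ""
    tracks: list[str] = field(default_factory=list)

    # variant QC
    maf_min: float = 0.01
    info_min: float = 0.8

    # pruning
    r2_max: float = 0.2
    window_bp: int = 500_000
    step: int = 20

    # enrichment
    thresholds: tuple = THRESHOLDS
    n_sims: int = 1000

    # regions
    shared_p_max: float = 1e-3
    distinct_p_max: float = 1e-5
    gap_bp: int = 100_000
    min_snps: int = 10
    max_lead_dist_bp: int = 250_000

    # colocalization
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_prior_sd: float = 0.2
    coloc_margin_bp: int = 50_000

    # VSE
    vse_r2_tag: float = 0.8
    vse_n_sets: int = 500

    seed: int = 0

    def __post_init__(self) -> None:
        self.thresholds = tuple(self.thresholds)
        for name in (
            "maf_min", "info_min", "r2_max", "shared_p_max", "distinct_p_max",
            "gap_bp", "min_snps", "max_lead_dist_bp", "window_bp", "step",
            "n_sims", "vse_n_sets",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d
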