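"""End-to-end workflow: QC -> harmonize -> prune -> genome-wide enrichment ->
region detection, pairing and nulls -> Bayesian colocalization -> VSE."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .coloc import coloc_region_pair
from .enrichment import enrichment_report
from .ld import load_ld_reference, ld_prune
from .regions import (
    direction_of_effect,
    distinct_regions,
    pair_by_lead_distance,
    reshuffle_empirical_p,
    shared_regions,
    territory_from_positions,
)
from .sumstats import filter_variants, harmonize, read_sumstats
from .vse import build_avs, read_bed, sample_mrvs, vse_analysis

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _region_row(r, direction=None):
    row = {
        "chrom": r.chrom,
        "start_bp": r.start_bp,
        "end_bp": r.end_bp,
        "n_snps": r.n_snps,
        "lead_id": r.lead_id,
        "lead_pos": r.lead_pos,
        "lead_p": r.lead_p,
        "trait": r.trait,
    }
    if r.lead_id_b is not None:
        row.update(lead_id_b=r.lead_id_b, lead_pos_b=r.lead_pos_b, lead_p_b=r.lead_p_b)
    if direction is not None:
        row["direction"] = direction
    return row


def write_regions_bed(regions, path) -> None:
    """Regions as BED (half-open 0-based on export)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.trait}:{r.lead_id}\n")


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Run every stage for trait A against each trait B; write tabular
    reports plus a machine-readable JSON summary; return the summary."""
    os.makedirs(out_dir, exist_ok=True)
    logger.info("crosscoloc %s; parameters: %s", __version__, config.to_dict())

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc

    summary: dict = {"version": __version__, "parameters": config.to_dict(), "traits": {}}

    table_a = stage("read_trait_a", read_sumstats, config.trait_a, "trait_a")
    table_a = stage("filter_trait_a", filter_variants, table_a, config.maf_min, config.info_min)

    tracks = [stage("read_tracks", read_bed, p) for p in config.tracks]

    for k, path_b in enumerate(config.traits_b):
        name_b = f"trait_b{k}" if len(config.traits_b) > 1 else "trait_b"
        table_b = stage("read_trait_b", read_sumstats, path_b, name_b)
        table_b = stage("filter_trait_b", filter_variants, table_b, config.maf_min, config.info_min)
        paired = stage("harmonize", harmonize, table_a, table_b)
        ref = stage("load_reference", load_ld_reference, config.ld_reference, table_a)
        pruned = stage(
            "ld_prune", ld_prune, table_a, ref, config.r2_max, config.window_bp, config.step
        )

        report = stage(
            "enrichment",
            enrichment_report,
            paired,
            pruned,
            n_sims=config.n_sims,
            seed=config.seed,
            thresholds=config.thresholds,
        )
        report.to_frame().to_csv(
            os.path.join(out_dir, f"enrichment_{name_b}.tsv"), sep="\t", index=False
        )

        shared = stage(
            "shared_regions", shared_regions, paired,
            config.shared_p_max, config.gap_bp, config.min_snps,
        )
        directions = [direction_of_effect(r, paired) for r in shared]
        pd.DataFrame([_region_row(r, d) for r, d in zip(shared, directions)]).to_csv(
            os.path.join(out_dir, f"shared_regions_{name_b}.tsv"), sep="\t", index=False
        )
        write_regions_bed(shared, os.path.join(out_dir, f"shared_regions_{name_b}.bed"))

        dist_a = stage(
            "distinct_regions_a", distinct_regions, table_a,
            config.distinct_p_max, config.gap_bp, config.min_snps,
        )
        dist_b = stage(
            "distinct_regions_b", distinct_regions, table_b,
            config.distinct_p_max, config.gap_bp, config.min_snps,
        )
        pairs = stage(
            "pair_regions", pair_by_lead_distance, dist_a, dist_b, ref, config.max_lead_dist_bp
        )
        pd.DataFrame(
            [
                {
                    "chrom": p.region_a.chrom,
                    "lead_a": p.region_a.lead_id,
                    "lead_a_pos": p.region_a.lead_pos,
                    "lead_a_p": p.region_a.lead_p,
                    "lead_b": p.region_b.lead_id,
                    "lead_b_pos": p.region_b.lead_pos,
                    "lead_b_p": p.region_b.lead_p,
                    "distance_bp": p.lead_distance_bp,
                    "dprime": p.dprime,
                    "r2": p.r2,
                }
                for p in pairs
            ]
        ).to_csv(os.path.join(out_dir, f"region_pairs_{name_b}.tsv"), sep="\t", index=False)

        territory = territory_from_positions(paired.df)
        reshuffle_p = None
        if dist_a and dist_b:
            reshuffle_p = stage(
                "reshuffle_null",
                reshuffle_empirical_p,
                dist_a, dist_b, territory,
                n_sims=config.n_sims,
                seed=config.seed,
                max_dist_bp=config.max_lead_dist_bp,
            )

        coloc_rows = []
        for p in pairs:
            res = stage(
                "coloc", coloc_region_pair, paired, p.region_a, p.region_b,
                margin_bp=config.coloc_margin_bp,
                prior_sd=config.coloc_prior_sd,
                p1=config.coloc_p1, p2=config.coloc_p2, p12=config.coloc_p12,
            )
            coloc_rows.append(
                {
                    "chrom": p.region_a.chrom,
                    "lead_a": p.region_a.lead_id,
                    "lead_a_p": p.region_a.lead_p,
                    "lead_b": p.region_b.lead_id,
                    "lead_b_p": p.region_b.lead_p,
                    "PP0": res["PP0"], "PP1": res["PP1"], "PP2": res["PP2"],
                    "PP3": res["PP3"], "PP4": res["PP4"],
                    "n_snps": res.n_snps,
                }
            )
        pd.DataFrame(coloc_rows).to_csv(
            os.path.join(out_dir, f"coloc_{name_b}.tsv"), sep="\t", index=False
        )

        vse_rows = []
        if tracks and shared:
            tags = sorted({vid for r in shared for vid in r.member_ids})
            avs = stage("build_avs", build_avs, tags, table_a, ref, config.vse_r2_tag)
            mrvs = stage(
                "sample_mrvs", sample_mrvs, avs, table_a, ref,
                n_sets=config.vse_n_sets, seed=config.seed,
            )
            for res in stage("vse", vse_analysis, avs, mrvs, tracks):
                vse_rows.append(
                    {
                        "track": res.track,
                        "observed": res.observed,
                        "empirical_p": res.empirical_p,
                        "bonferroni_p": res.bonferroni_p,
                        "z_score": res.z_score,
                    }
                )
            pd.DataFrame(vse_rows).to_csv(
                os.path.join(out_dir, f"vse_{name_b}.tsv"), sep="\t", index=False
            )

        summary["traits"][name_b] = {
            "n_paired": len(paired),
            "n_ambiguous": paired.n_ambiguous,
            "n_pruned": len(pruned),
            "enrichment": report.to_frame().to_dict(orient="records"),
            "shared_regions": [_region_row(r, d) for r, d in zip(shared, directions)],
            "n_distinct_a": len(dist_a),
            "n_distinct_b": len(dist_b),
            "region_pairs": [
                {
                    "lead_a": p.region_a.lead_id,
                    "lead_b": p.region_b.lead_id,
                    "distance_bp": p.lead_distance_bp,
                    "dprime": p.dprime,
                    "r2": p.r2,
                }
                for p in pairs
            ],
            "reshuffle_empirical_p": reshuffle_p,
            "coloc": coloc_rows,
            "vse": vse_rows,
        }

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
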