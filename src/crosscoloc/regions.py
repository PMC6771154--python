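"""Associated-region detection, pairing and empirical colocalization nulls.

Two region flavours mirror two hypotheses about a locus shared by two
traits:

* *shared* regions — clusters of SNPs associated with BOTH traits at
  ``p < 1e-3``, evidence for one signal hitting both;
* *distinct* regions — per-trait clusters at ``p < 1e-5`` whose lead SNPs in
  the two traits fall within 250 kb of each other, evidence for two nearby
  but different signals.

Clustering is single-linkage chaining: qualifying SNPs on one chromosome are
chained while the gap between ADJACENT members stays under 100 kb, and a
chain must hold at least 10 qualifying SNPs.  (The chain's total span may
far exceed 100 kb.)  Significance of the observed pairing is assessed by
relocating the trait-A regions uniformly over the SNP-covered territory,
keeping each region's size fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LDError, LDReference, pairwise_dprime, pairwise_r2
from .sumstats import PairedTable, SumStatsTable

logger = logging.getLogger(__name__)


@dataclass
class Region:
    """A chained cluster of qualifying SNPs with its lead (minimum-p) SNP.

    For shared regions (``trait == "both"``) the primary lead fields refer to
    trait A and ``lead_id_b``/... to trait B.
    """

    chrom: str
    start_bp: int
    end_bp: int
    member_ids: list[str]
    lead_id: str
    lead_pos: int
    lead_p: float
    trait: str
    lead_id_b: str | None = None
    lead_pos_b: int | None = None
    lead_p_b: float | None = None

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_snps(self) -> int:
        return len(self.member_ids)


@dataclass
class RegionPair:
    """Two per-trait regions whose lead SNPs are close on the same chromosome."""

    region_a: Region
    region_b: Region
    lead_distance_bp: int
    dprime: float | None = None
    r2: float | None = None


def _lead(sub: pd.DataFrame, p_col: str, pos_col: str = "pos") -> tuple[str, int, float]:
    """Minimum-p member; ties broken toward the smaller position."""
    best = sub.sort_values([p_col, pos_col], kind="mergesort").iloc[0]
    return str(best["variant_id"]), int(best[pos_col]), float(best[p_col])


def _chain(qual: pd.DataFrame, gap_bp: int, min_snps: int) -> list[pd.DataFrame]:
    """Single-linkage chains of qualifying SNPs per chromosome: a chain breaks
    wherever the adjacent gap reaches ``gap_bp``."""
    clusters = []
    for _, sub in qual.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= gap_bp)
        start = 0
        for b in list(breaks) + [len(pos) - 1]:
            chunk = sub.iloc[start : b + 1]
            if len(chunk) >= min_snps:
                clusters.append(chunk)
            start = b + 1
    return clusters


def shared_regions(
    paired: PairedTable,
    p_max: float = 1e-3,
    gap_bp: int = 100_000,
    min_snps: int = 10,
) -> list[Region]:
    """Regions of at least ``min_snps`` SNPs associated with both traits at
    ``p < p_max``, chained with adjacent gaps under ``gap_bp``."""
    df = paired.df
    qual = df[(df["p_a"] < p_max) & (df["p_b"] < p_max)]
    out = []
    for chunk in _chain(qual, gap_bp, min_snps):
        lead_a = _lead(chunk, "p_a")
        lead_b = _lead(chunk, "p_b")
        out.append(
            Region(
                chrom=str(chunk["chrom"].iloc[0]),
                start_bp=int(chunk["pos"].min()),
                end_bp=int(chunk["pos"].max()),
                member_ids=chunk["variant_id"].tolist(),
                lead_id=lead_a[0],
                lead_pos=lead_a[1],
                lead_p=lead_a[2],
                trait="both",
                lead_id_b=lead_b[0],
                lead_pos_b=lead_b[1],
                lead_p_b=lead_b[2],
            )
        )
    return out


def distinct_regions(
    table: SumStatsTable,
    p_max: float = 1e-5,
    gap_bp: int = 100_000,
    min_snps: int = 10,
) -> list[Region]:
    """Per-trait candidate regions: at least ``min_snps`` SNPs at
    ``p < p_max`` for this trait alone, chained as in :func:`shared_regions`."""
    df = table.df.rename(columns={"pvalue": "p"})
    qual = df[df["p"] < p_max]
    out = []
    for chunk in _chain(qual, gap_bp, min_snps):
        lead = _lead(chunk, "p")
        out.append(
            Region(
                chrom=str(chunk["chrom"].iloc[0]),
                start_bp=int(chunk["pos"].min()),
                end_bp=int(chunk["pos"].max()),
                member_ids=chunk["variant_id"].tolist(),
                lead_id=lead[0],
                lead_pos=lead[1],
                lead_p=lead[2],
                trait=table.trait_name,
            )
        )
    return out


def direction_of_effect(region: Region, paired: PairedTable) -> str:
    """Sign concordance of harmonized effects over the region's members:
    ``same`` if every sign product is positive, ``opposite`` if every product
    is negative, ``mixed`` otherwise.  Members with a zero effect estimate
    carry no direction and are excluded with a warning."""
    df = paired.df[paired.df["variant_id"].isin(set(region.member_ids))]
    prod = np.sign(df["beta_a"].to_numpy()) * np.sign(df["beta_b"].to_numpy())
    zero = prod == 0
    if zero.any():
        logger.warning(
            "direction_of_effect: excluding %d member(s) with beta == 0", int(zero.sum())
        )
        prod = prod[~zero]
    if prod.size == 0:
        return "mixed"
    if (prod > 0).all():
        return "same"
    if (prod < 0).all():
        return "opposite"
    return "mixed"


def pair_by_lead_distance(
    regions_a: list[Region],
    regions_b: list[Region],
    ref: LDReference | None = None,
    max_dist_bp: int = 250_000,
) -> list[RegionPair]:
    """All cross-trait region pairs on the same chromosome whose lead SNPs
    are strictly less than ``max_dist_bp`` apart, annotated with D' and r²
    between the two leads where the reference allows it."""
    pairs = []
    for ra in regions_a:
        for rb in regions_b:
            if ra.chrom != rb.chrom:
                continue
            dist = abs(ra.lead_pos - rb.lead_pos)
            if dist >= max_dist_bp:
                continue
            dprime = r2 = None
            if ref is not None and ra.lead_id in ref and rb.lead_id in ref:
                try:
                    dprime = pairwise_dprime(ref, ra.lead_id, rb.lead_id)
                    r2 = pairwise_r2(ref, ra.lead_id, rb.lead_id)
                except LDError:
                    dprime = r2 = None
            pairs.append(RegionPair(ra, rb, int(dist), dprime=dprime, r2=r2))
    return pairs


def count_close_pairs(
    regions_a: list[Region], regions_b: list[Region], max_dist_bp: int = 250_000
) -> int:
    return len(pair_by_lead_distance(regions_a, regions_b, ref=None, max_dist_bp=max_dist_bp))


def territory_from_positions(df: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Per-chromosome SNP-covered extents (min pos, max pos) of a table with
    ``chrom``/``pos`` columns — the space regions may be relocated within."""
    return {
        str(chrom): (int(sub["pos"].min()), int(sub["pos"].max()))
        for chrom, sub in df.groupby("chrom", sort=True)
    }


def reshuffle_empirical_p(
    regions_a: list[Region],
    regions_b: list[Region],
    territory: dict[str, tuple[int, int]],
    n_sims: int = 1000,
    seed: int = 0,
    max_dist_bp: int = 250_000,
    within_chrom: bool = False,
) -> float:
    """Empirical p for the observed number of close region pairs under a
    positional null.

    Each replicate relocates every trait-A region — size fixed, chromosome
    redrawn with probability proportional to territory length (or kept, with
    ``within_chrom=True``), start uniform within the chromosome's covered
    extent — and recounts pairs with lead distance under ``max_dist_bp``.
    Returns the proportion of replicates reaching the observed count.
    """
    observed = count_close_pairs(regions_a, regions_b, max_dist_bp)
    if not regions_a or not regions_b:
        return 1.0
    chroms = sorted(territory)
    lengths = np.array([territory[c][1] - territory[c][0] for c in chroms], dtype=float)
    rng = np.random.default_rng(seed)

    # B-side lead positions stay fixed; index them per chromosome
    b_leads: dict[str, np.ndarray] = {}
    for rb in regions_b:
        b_leads.setdefault(rb.chrom, [])
    for rb in regions_b:
        b_leads[rb.chrom].append(rb.lead_pos)
    b_leads = {c: np.sort(np.array(v)) for c, v in b_leads.items()}

    sizes = [r.size_bp for r in regions_a]
    lead_offsets = [r.lead_pos - r.start_bp for r in regions_a]
    for k, r in enumerate(regions_a):
        fits = lengths >= sizes[k] if not within_chrom else None
        if within_chrom:
            span = territory[r.chrom][1] - territory[r.chrom][0]
            if span < sizes[k]:
                raise ValueError(
                    f"region {r.lead_id} ({sizes[k]} bp) exceeds its chromosome territory"
                )
        elif not fits.any():
            raise ValueError(
                f"region {r.lead_id} ({sizes[k]} bp) exceeds every chromosome territory"
            )

    hits = 0
    for _ in range(n_sims):
        count = 0
        for k, r in enumerate(regions_a):
            size = sizes[k]
            if within_chrom:
                chrom = r.chrom
            else:
                fits = lengths >= size
                w = np.where(fits, lengths, 0.0)
                chrom = chroms[rng.choice(len(chroms), p=w / w.sum())]
            t0, t1 = territory[chrom]
            start = int(rng.integers(t0, t1 - size + 1))
            lead = start + lead_offsets[k]
            near = b_leads.get(chrom)
            if near is not None and near.size:
                lo = np.searchsorted(near, lead - max_dist_bp + 1)
                hi = np.searchsorted(near, lead + max_dist_bp - 1, side="right")
                count += int(hi - lo)
        if count >= observed:
            hits += 1
    return hits / n_sims
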