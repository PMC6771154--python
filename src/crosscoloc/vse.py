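"""LD-aware enrichment of an associated variant set in epigenomic intervals.

The associated variant set (AVS) is the list of tag SNPs plus, for each tag,
its LD block — every pool variant on the same chromosome with r² >= 0.8 to
the tag.  The null model preserves LD structure: each matched random variant
set (MRVS) replaces every tag by a random pool variant whose own LD block
has the same size (a widening +/-k tolerance ladder guarantees a match on
small pools).  A track's enrichment score is the number of tags whose block
touches at least one interval; the empirical p-value is the add-one
proportion of null sets scoring at least as high, Bonferroni-corrected
across tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .ld import LDError, LDReference
from .sumstats import SumStatsTable

logger = logging.getLogger(__name__)


@dataclass
class AVS:
    """Tag variants and their LD blocks: ``blocks[tag]`` is a list of
    ``(variant_id, chrom, pos)`` members, always containing the tag itself."""

    tags: list[str]
    blocks: dict[str, list[tuple[str, str, int]]]
    r2_tag: float = 0.8

    def block_sizes(self) -> list[int]:
        return [len(self.blocks[t]) for t in self.tags]


@dataclass
class FeatureTrack:
    """Named set of genomic intervals, 0-based half-open (BED convention)."""

    name: str
    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError(f"{self.name}: empty interval {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals)


@dataclass
class EnrichmentResult:
    """Observed score against the MRVS null for one feature track."""

    track: str
    observed: int
    null_scores: list[int]
    empirical_p: float
    bonferroni_p: float = float("nan")

    @property
    def z_score(self) -> float:
        mu = float(np.mean(self.null_scores))
        sd = float(np.std(self.null_scores))
        if sd == 0:
            return 0.0
        return (self.observed - mu) / sd


def read_bed(path, name: str | None = None) -> FeatureTrack:
    """Read a BED file (3+ columns, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    intervals = [(str(c), int(s), int(e)) for c, s, e in df.itertuples(index=False)]
    return FeatureTrack(name or str(path), intervals)


def _pool_arrays(pool: SumStatsTable, ref: LDReference):
    df = pool.df
    missing = [v for v in df["variant_id"] if v not in ref]
    if missing:
        raise LDError(f"pool variant(s) missing from reference: {missing[:5]}")
    return (
        df["variant_id"].to_numpy(),
        df["chrom"].to_numpy(),
        df["pos"].to_numpy(),
    )


def _chrom_r2(pool: SumStatsTable, ref: LDReference) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (pool row indices, r² matrix among those variants).

    Memoized on the (pool, reference) object pair — AVS construction and
    null-set sampling reuse the same matrices.
    """
    cache = getattr(ref, "_vse_r2_cache", None)
    if cache is not None and cache[0] is pool.df:
        return cache[1]
    vids, chroms, _ = _pool_arrays(pool, ref)
    out = {}
    for chrom in pd.unique(chroms):
        rows = np.flatnonzero(chroms == chrom)
        cols = np.array([ref._index[v] for v in vids[rows]])
        g = ref.genotypes[:, cols]
        sd = g.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise LDError(f"zero-variance pool variant(s): {[vids[rows[k]] for k in bad[:5]]}")
        z = (g - g.mean(axis=0)) / sd
        r2 = (z.T @ z / g.shape[0]) ** 2
        out[str(chrom)] = (rows, r2)
    ref._vse_r2_cache = (pool.df, out)
    return out


def build_avs(
    tags: list[str], pool: SumStatsTable, ref: LDReference, r2_tag: float = 0.8
) -> AVS:
    """LD block of each tag: all pool variants on the tag's chromosome with
    r² >= ``r2_tag`` to it (the tag always belongs to its own block)."""
    vids, chroms, pos = _pool_arrays(pool, ref)
    id_row = {v: k for k, v in enumerate(vids)}
    for t in tags:
        if t not in id_row:
            raise LDError(f"tag {t!r} not in pool")
        if t not in ref:
            raise LDError(f"tag {t!r} not in LD reference")
    per_chrom = _chrom_r2(pool, ref)
    blocks: dict[str, list[tuple[str, str, int]]] = {}
    for t in tags:
        row = id_row[t]
        chrom = str(chroms[row])
        rows, r2 = per_chrom[chrom]
        local = int(np.flatnonzero(rows == row)[0])
        hit = rows[r2[local] >= r2_tag]
        if row not in hit:
            hit = np.append(hit, row)
        blocks[t] = [(str(vids[k]), str(chroms[k]), int(pos[k])) for k in np.sort(hit)]
    return AVS(list(tags), blocks, r2_tag)


def _all_block_sizes(pool: SumStatsTable, ref: LDReference, r2_tag: float) -> np.ndarray:
    """LD-block size of every pool variant (used as the matching key)."""
    vids, chroms, _ = _pool_arrays(pool, ref)
    sizes = np.zeros(len(vids), dtype=int)
    for chrom, (rows, r2) in _chrom_r2(pool, ref).items():
        sizes[rows] = (r2 >= r2_tag).sum(axis=1)
    return sizes


def sample_mrvs(
    avs: AVS,
    pool: SumStatsTable,
    ref: LDReference,
    n_sets: int = 500,
    seed: int = 0,
) -> list[AVS]:
    """Matched random variant sets: per replicate, per real tag, draw a pool
    variant whose block size equals the real block size, widening the
    tolerance by one at a time until candidates exist."""
    vids, chroms, pos = _pool_arrays(pool, ref)
    sizes = _all_block_sizes(pool, ref, avs.r2_tag)
    max_size = int(sizes.max())
    per_chrom = _chrom_r2(pool, ref)
    rng = np.random.default_rng(seed)

    # candidate rows per block size, and expanded-tolerance fallbacks
    def candidates(target: int) -> np.ndarray:
        for tol in range(0, max_size + abs(target) + 1):
            sel = np.flatnonzero(np.abs(sizes - target) <= tol)
            if sel.size:
                if tol > 0:
                    logger.debug("block size %d matched at tolerance +/-%d", target, tol)
                return sel
        raise LDError(f"no pool candidate for block size {target}")

    cand_cache = {s: candidates(s) for s in set(avs.block_sizes())}
    block_cache: dict[int, list[tuple[str, str, int]]] = {}

    def block_of(row: int) -> list[tuple[str, str, int]]:
        cached = block_cache.get(row)
        if cached is None:
            chrom = str(chroms[row])
            rows, r2 = per_chrom[chrom]
            local = int(np.searchsorted(rows, row))
            hit = np.sort(rows[r2[local] >= avs.r2_tag])
            cached = [(str(vids[k]), str(chroms[k]), int(pos[k])) for k in hit]
            block_cache[row] = cached
        return cached

    # group real tags by target block size; within one replicate the matched
    # tags of a group are drawn without replacement (mirroring the AVS being
    # a set of distinct tags), falling back to replacement on tiny pools
    targets = [len(avs.blocks[t]) for t in avs.tags]
    groups: dict[int, int] = {}
    for s in targets:
        groups[s] = groups.get(s, 0) + 1

    out = []
    for _ in range(n_sets):
        tags_r: list[str] = []
        blocks_r: dict[str, list[tuple[str, str, int]]] = {}
        for target, g in groups.items():
            cand = cand_cache[target]
            rows = rng.choice(cand, size=g, replace=cand.size < g)
            for row in rows:
                vid = str(vids[int(row)])
                tags_r.append(vid)
                blocks_r[vid] = block_of(int(row))
        out.append(AVS(tags_r, blocks_r, avs.r2_tag))
    return out


def _track_trees(track: FeatureTrack) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in track.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _score(avs: AVS, trees: dict[str, IntervalTree]) -> int:
    """Number of tags whose block overlaps at least one interval.  Variant
    positions are 1-based; BED intervals half-open 0-based."""
    score = 0
    for t in avs.tags:
        for _, chrom, pos in avs.blocks[t]:
            tree = trees.get(chrom)
            if tree is not None and tree[pos - 1]:
                score += 1
                break
    return score


def enrichment_test(avs: AVS, mrvs: list[AVS], track: FeatureTrack) -> EnrichmentResult:
    """Score the real AVS against its matched null sets on one track, with
    the add-one empirical p-value ``(1 + #{null >= obs}) / (n_sets + 1)``."""
    trees = _track_trees(track)
    observed = _score(avs, trees)
    null_scores = [_score(m, trees) for m in mrvs]
    hits = sum(1 for s in null_scores if s >= observed)
    emp = (1 + hits) / (len(mrvs) + 1)
    return EnrichmentResult(track.name, observed, null_scores, emp)


def vse_analysis(
    avs: AVS, mrvs: list[AVS], tracks: list[FeatureTrack]
) -> list[EnrichmentResult]:
    """Per-track enrichment with Bonferroni correction across tracks."""
    results = [enrichment_test(avs, mrvs, t) for t in tracks]
    m = len(results)
    for r in results:
        r.bonferroni_p = min(1.0, r.empirical_p * m)
    return results
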