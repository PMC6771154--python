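"""Pairwise linkage disequilibrium from a genotype reference, and LD pruning.

The reference is an ``n_samples x n_variants`` matrix of allele dosages in
[0, 2] (unphased).  r-squared is the squared sample correlation of dosage
vectors; D-prime is computed from two-locus haplotype frequencies estimated
by EM, because phase is not observed.  Pruning reduces a summary-statistics
table to a set of approximately independent SNPs: within sliding windows of
``window_bp`` bases, one member of every pair with r² at or above the
threshold is removed, and the window slides forward by ``step`` retained
variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SumStatsTable


class LDError(ValueError):
    """Fatal problem with the LD reference or a pruning request."""


@dataclass
class LDReference:
    """Genotype dosages for a set of variants, column order fixed."""

    variant_ids: list[str]
    positions: np.ndarray
    genotypes: np.ndarray = field(repr=False)  # (n_samples, n_variants), dosages in [0,2]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.genotypes.shape[1] != len(self.variant_ids):
            raise LDError(
                f"genotype matrix has {self.genotypes.shape[1]} columns for "
                f"{len(self.variant_ids)} variant ids"
            )
        self._index = {v: k for k, v in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.genotypes[:, self._index[variant_id]]
        except KeyError:
            raise LDError(f"variant {variant_id!r} not in LD reference") from None

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index


@dataclass
class PrunedSet:
    """Result of LD pruning: retained ids plus the parameters that made them."""

    variant_ids: list[str]
    r2_max: float
    window_bp: int
    step: int

    def __len__(self) -> int:
        return len(self.variant_ids)


def load_ld_reference(path, sumstats: SumStatsTable | None = None) -> LDReference:
    """Read a tab-delimited dosage matrix (first column sample id, header row
    of variant ids).  When ``sumstats`` is given, positions are taken from it
    and every reference variant must be present there."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if sumstats is not None:
        pos_map = dict(zip(sumstats.df["variant_id"], sumstats.df["pos"]))
        missing = [v for v in ids if v not in pos_map]
        if missing:
            raise LDError(f"reference variants absent from summary stats: {missing[:5]}")
        positions = np.array([pos_map[v] for v in ids], dtype=np.int64)
    else:
        positions = np.zeros(len(ids), dtype=np.int64)
    return LDReference(ids, positions, df.to_numpy(dtype=float))


def write_ld_reference(ref: LDReference, path) -> None:
    df = pd.DataFrame(
        ref.genotypes,
        columns=ref.variant_ids,
        index=[f"sample_{k}" for k in range(ref.n_samples)],
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def pairwise_r2(ref: LDReference, i: str, j: str) -> float:
    """Squared sample (Pearson) correlation of the two dosage vectors."""
    x = ref.column(i)
    y = ref.column(j)
    for vid, v in ((i, x), (j, y)):
        if np.std(v) == 0:
            raise LDError(f"variant {vid!r} has zero variance in the reference")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _haplotype_em(
    n: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> np.ndarray:
    """EM estimate of two-locus haplotype frequencies (pAB, pAb, paB, pab)
    from a 3x3 joint genotype count table ``n[g1, g2]``.

    Every diplotype except the double heterozygote resolves phase uniquely;
    the double-het mass is split between AB/ab and Ab/aB in proportion to the
    current frequency products.
    """
    total = n.sum()
    pA = (2 * n[2, :].sum() + n[1, :].sum()) / (2 * total)
    pB = (2 * n[:, 2].sum() + n[:, 1].sum()) / (2 * total)
    # start from linkage equilibrium
    p = np.array(
        [pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)], dtype=float
    )
    # unambiguous haplotype counts: index haplotypes AB, Ab, aB, ab
    base = np.zeros(4)
    for g1 in range(3):
        for g2 in range(3):
            c = n[g1, g2]
            if c == 0 or (g1 == 1 and g2 == 1):
                continue
            # numbers of AB/Ab/aB/ab haplotypes in the unique diplotype
            nAB = {
                (0, 0): 0, (0, 1): 0, (0, 2): 0,
                (1, 0): 0, (1, 2): 1,
                (2, 0): 0, (2, 1): 1, (2, 2): 2,
            }[(g1, g2)]
            nAb = g1 - nAB
            naB = g2 - nAB
            nab = 2 - nAB - nAb - naB
            base += c * np.array([nAB, nAb, naB, nab])
    n_dh = n[1, 1]
    last_ll = -np.inf
    for _ in range(max_iter):
        # E-step: split double heterozygotes
        cis = p[0] * p[3]
        trans = p[1] * p[2]
        denom = cis + trans
        f_cis = 0.5 if denom == 0 else cis / denom
        counts = base + n_dh * np.array([f_cis, 1 - f_cis, 1 - f_cis, f_cis])
        p = counts / counts.sum()
        ll = _genotype_loglik(n, p)
        if ll - last_ll < tol:
            break
        last_ll = ll
    return p


def _genotype_loglik(n: np.ndarray, p: np.ndarray) -> float:
    pAB, pAb, paB, pab = p
    ll = 0.0
    probs = {
        (0, 0): pab**2, (0, 1): 2 * pab * paB, (0, 2): paB**2,
        (1, 0): 2 * pab * pAb, (1, 1): 2 * (pAB * pab + pAb * paB), (1, 2): 2 * paB * pAB,
        (2, 0): pAb**2, (2, 1): 2 * pAb * pAB, (2, 2): pAB**2,
    }
    for (g1, g2), pr in probs.items():
        if n[g1, g2] > 0:
            ll += n[g1, g2] * np.log(max(pr, 1e-300))
    return ll


def pairwise_dprime(ref: LDReference, i: str, j: str) -> float:
    """|D| / D_max with haplotype frequencies estimated by EM from dosages.

    Dosages are rounded to the nearest genotype before phase estimation.
    """
    x = np.clip(np.rint(ref.column(i)), 0, 2).astype(int)
    y = np.clip(np.rint(ref.column(j)), 0, 2).astype(int)
    for vid, v in ((i, x), (j, y)):
        if v.min() == v.max():
            raise LDError(f"variant {vid!r} is monomorphic in the reference")
    n = np.zeros((3, 3))
    for g1, g2 in zip(x, y):
        n[g1, g2] += 1
    p = _haplotype_em(n)
    pA = p[0] + p[1]
    pB = p[0] + p[2]
    d = p[0] - pA * pB
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        return 0.0
    return float(min(abs(d) / dmax, 1.0))


def _std_genotypes(g: np.ndarray, ids: list[str]) -> np.ndarray:
    """Column-standardized dosages; zero-variance columns are fatal."""
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise LDError(f"zero-variance reference column(s): {[ids[k] for k in bad[:5]]}")
    return (g - mu) / sd


def _prune_window(r2: np.ndarray, maf: np.ndarray, alive: np.ndarray, r2_max: float) -> None:
    """Greedy in-place removal inside one window.

    Scans violating pairs in (position-order) lexicographic order; from each
    pair removes the smaller-MAF member, breaking MAF ties by removing the
    variant at the larger position.  Repeats until no retained pair violates
    the threshold.
    """
    m = r2.shape[0]
    while True:
        removed = False
        for i in range(m):
            if not alive[i]:
                continue
            for j in range(i + 1, m):
                if not alive[j]:
                    continue
                if r2[i, j] >= r2_max:
                    if maf[i] < maf[j]:
                        alive[i] = False
                    else:
                        # equal MAF -> drop larger position, i.e. j
                        alive[j] = False
                    removed = True
                    break
            if removed:
                break
        if not removed:
            return


def ld_prune(
    table: SumStatsTable,
    ref: LDReference,
    r2_max: float = 0.2,
    window_bp: int = 500_000,
    step: int = 20,
) -> PrunedSet:
    """Windowed greedy LD pruning of ``table`` down to approximate linkage
    equilibrium.

    After the sliding-window pass, a final sweep enforces the output
    guarantee exactly: no two retained variants within ``window_bp`` of each
    other have r² >= ``r2_max`` (window stepping alone cannot certify pairs
    that straddle window boundaries).
    """
    df = table.df
    missing = [v for v in df["variant_id"] if v not in ref]
    if missing:
        raise LDError(f"{len(missing)} table variant(s) missing from reference: {missing[:5]}")

    keep_ids: list[str] = []
    for _, chrom_df in df.groupby("chrom", sort=True):
        ids = chrom_df["variant_id"].tolist()
        pos = chrom_df["pos"].to_numpy()
        maf = chrom_df["maf"].to_numpy()
        cols = np.array([ref._index[v] for v in ids])
        z = _std_genotypes(ref.genotypes[:, cols], ids)
        n = len(ids)
        alive = np.ones(n, dtype=bool)

        start = 0  # index into the retained sequence
        while True:
            retained = np.flatnonzero(alive)
            if start >= retained.size:
                break
            w0 = retained[start]
            in_win = retained[(pos[retained] >= pos[w0]) & (pos[retained] - pos[w0] <= window_bp)]
            if in_win.size > 1:
                sub = z[:, in_win]
                r2 = (sub.T @ sub / z.shape[0]) ** 2
                w_alive = np.ones(in_win.size, dtype=bool)
                _prune_window(r2, maf[in_win], w_alive, r2_max)
                alive[in_win[~w_alive]] = False
            start += step

        # certificate-enforcing sweep over all remaining close pairs
        _final_sweep(z, pos, maf, alive, r2_max, window_bp)
        keep_ids.extend([ids[k] for k in np.flatnonzero(alive)])

    order = {v: k for k, v in enumerate(df["variant_id"])}
    keep_ids.sort(key=order.__getitem__)
    return PrunedSet(keep_ids, r2_max, window_bp, step)


def _final_sweep(
    z: np.ndarray,
    pos: np.ndarray,
    maf: np.ndarray,
    alive: np.ndarray,
    r2_max: float,
    window_bp: int,
) -> None:
    n_samples = z.shape[0]
    changed = True
    while changed:
        changed = False
        retained = np.flatnonzero(alive)
        for a_idx in range(retained.size):
            i = retained[a_idx]
            for b_idx in range(a_idx + 1, retained.size):
                j = retained[b_idx]
                if not alive[j]:
                    continue
                if pos[j] - pos[i] > window_bp:
                    break
                r2 = (z[:, i] @ z[:, j] / n_samples) ** 2
                if r2 >= r2_max:
                    if maf[i] < maf[j]:
                        alive[i] = False
                    else:
                        alive[j] = False
                    changed = True
                    break
            if changed or not alive[i]:
                break
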