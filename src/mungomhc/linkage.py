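"""Linkage-disequilibrium structure of multi-locus amplicon genotypes.

Pairwise association between allele presence/absence columns is measured
by the Phi coefficient (Pearson correlation of binary variables); strong
positive blocks of alleles indicate loci travelling on one haplotype,
strong negative relations indicate alternative haplotypes. Blocks are
found by Ward hierarchical clustering on 1 - Phi, the tree cut at the
level maximising mean within-block Phi, and each block is summarised by
its co-occurrence percentage (fraction of individuals carrying the full
allele combination). Block sizes give a lower bound on the number of
loci per haplotype; so does half the maximum per-individual allele count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class HaplotypeBlock:
    alleles: frozenset
    mean_phi: float
    co_occurrence: float        # fraction of individuals with the full set


def phi_matrix(gm: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phi coefficients between all allele columns, with p-values.

    Phi is the Pearson correlation of the 0/1 columns; the p-value comes
    from the chi-squared approximation n * Phi^2 ~ chi2(1). Constant
    columns give undefined (NaN) entries.
    """
    if gm.shape[0] < 2:
        raise ValueError("need >= 2 individuals")
    if gm.shape[1] < 2:
        raise ValueError("need >= 2 allele columns")
    X = gm.to_numpy(dtype=float)
    n = X.shape[0]
    sd = X.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    pvals = stats.chi2.sf(n * corr ** 2, df=1)
    np.fill_diagonal(pvals, 0.0)
    cols = gm.columns
    return (pd.DataFrame(corr, index=cols, columns=cols),
            pd.DataFrame(pvals, index=cols, columns=cols))


def ward_linkage(phi: pd.DataFrame) -> np.ndarray:
    """Ward clustering on the dissimilarity 1 - Phi.

    Emulates Lance-Williams Ward on the raw dissimilarities ("ward.D"):
    scipy's ward updates squared inputs, so feeding sqrt(1 - Phi) yields
    the ward.D merge order on 1 - Phi (heights are the square roots).
    Undefined entries are treated as no association (Phi = 0).
    """
    d = 1.0 - phi.fillna(0.0).to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.sqrt(np.clip((d + d.T) / 2.0, 0.0, None))
    return linkage(squareform(d, checks=False), method="ward")


def _mean_within_phi(phi: np.ndarray, members: np.ndarray) -> float:
    sub = phi[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    vals = sub[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def cluster_blocks(phi: pd.DataFrame, genotypes: pd.DataFrame,
                   min_mean_phi: float = 0.5) -> list[HaplotypeBlock]:
    """Cut the Ward tree into haplotype blocks.

    Among all flat cuts of the tree, the one maximising the mean
    within-block Phi (averaged over blocks of size >= 2) is chosen; blocks
    with mean within-block Phi >= ``min_mean_phi`` are reported together
    with the fraction of individuals carrying the complete allele
    combination. Returns an empty list when no block reaches the
    threshold.
    """
    Z = ward_linkage(phi)
    phi_arr = phi.to_numpy()
    cols = list(phi.columns)
    best_score, best_assign = -math.inf, None
    for t in range(2, len(cols) + 1):
        assign = fcluster(Z, t=t, criterion="maxclust")
        scores = []
        for c in np.unique(assign):
            members = np.where(assign == c)[0]
            if len(members) >= 2:
                m = _mean_within_phi(phi_arr, members)
                if np.isfinite(m):
                    scores.append(m)
        if scores and np.mean(scores) > best_score:
            best_score, best_assign = float(np.mean(scores)), assign
    if best_assign is None:
        return []
    blocks = []
    gm = genotypes.to_numpy(dtype=bool)
    for c in np.unique(best_assign):
        members = np.where(best_assign == c)[0]
        if len(members) < 2:
            continue
        m = _mean_within_phi(phi_arr, members)
        if not np.isfinite(m) or m < min_mean_phi:
            continue
        member_names = frozenset(cols[i] for i in members)
        col_idx = [genotypes.columns.get_loc(cols[i]) for i in members]
        co = float(np.mean(gm[:, col_idx].all(axis=1)))
        blocks.append(HaplotypeBlock(alleles=member_names,
                                     mean_phi=m, co_occurrence=co))
    return sorted(blocks, key=lambda b: -len(b.alleles))


def min_loci_from_blocks(blocks: list[HaplotypeBlock],
                         genotypes: pd.DataFrame | None = None,
                         exon_of: dict | None = None,
                         exon: str | None = None) -> int:
    """Lower bound on loci per haplotype from the largest positive block.

    Positively correlated alleles in one block must sit on distinct loci
    of the same haplotype, so the bound is the maximum block size (for the
    requested exon when ``exon_of`` labels columns). With no blocks the
    bound falls back to the per-individual allele-count bound.
    """
    sizes = []
    for b in blocks:
        members = b.alleles
        if exon is not None and exon_of is not None:
            members = {a for a in members if exon_of.get(a) == exon}
        if len(members) >= 2:
            sizes.append(len(members))
    if sizes:
        return max(sizes)
    if genotypes is None:
        raise ValueError("no blocks and no genotypes for the fallback bound")
    return min_loci_from_max_alleles(genotypes, exon_of=exon_of, exon=exon)


def min_loci_from_max_alleles(genotypes: pd.DataFrame,
                              exon_of: dict | None = None,
                              exon: str | None = None) -> int:
    """Lower bound on loci: ceil(max per-individual allele count / 2).

    A diploid individual carries at most two alleles per locus, so half
    the largest observed per-individual allele count (rounded up) bounds
    the locus number from below.
    """
    cols = genotypes.columns
    if exon is not None and exon_of is not None:
        cols = [c for c in cols if exon_of.get(c) == exon]
    counts = genotypes[list(cols)].sum(axis=1)
    if counts.empty:
        return 0
    return math.ceil(counts.max() / 2.0)
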