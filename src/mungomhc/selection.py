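"""Codon-based selection inference.

Nei-Gojobori counting of potential and observed synonymous and
nonsynonymous sites with Jukes-Cantor correction for multiple hits, mean
dN-dS over all sequence pairs, a codon-bootstrap standard error, and the
one-tailed Z-test of positive selection (H0: dN <= dS). The analysis can
be restricted to amino-acid site masks (positively selected sites,
peptide-binding region).

Counting conventions: at each codon position the three possible
single-nucleotide changes are classified as synonymous or nonsynonymous;
changes creating a stop codon are excluded from the potential-site
denominator, and per codon N = 3 - S so that S + N = 3 x codons.
Observed differences in codons differing at d positions are averaged over
all d! mutational pathways, excluding pathways that pass through a stop
codon (when every pathway hits a stop, all are retained equally).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from Bio.Data.CodonTable import standard_dna_table as _TABLE

STOP_CODONS = frozenset(_TABLE.stop_codons)
NUCLEOTIDES = "ACGT"


def _aa(codon: str) -> str:
    return _TABLE.forward_table.get(codon, "*")


@dataclass
class PairCounts:
    """Potential (S, N) and observed (Sd, Nd) site counts for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float


@dataclass
class SelectionResult:
    dn_minus_ds: float
    se: float
    z: float
    p_value: float
    partition: str
    n_alleles: int
    n_codons: int
    n_pairs_used: int
    n_pairs_saturated: int


@lru_cache(maxsize=None)
def synonymous_fraction(codon: str) -> float:
    """Potential synonymous sites of one sense codon (0..3).

    Per position, the fraction of non-stop single-nucleotide changes that
    preserve the amino acid; summed over the three positions.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no potential-site count")
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in NUCLEOTIDES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            tot += 1
            if _aa(alt) == _aa(codon):
                syn += 1
        if tot:
            s += syn / tot
    return s


@lru_cache(maxsize=None)
def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Observed (synonymous, nonsynonymous) differences between two codons.

    Averages over all orderings of the single-nucleotide steps from
    ``codon_a`` to ``codon_b``; pathways through stop codons are excluded
    unless no pathway avoids them.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = nsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            if _aa(nxt) == _aa(current):
                syn += 1
            else:
                nsyn += 1
            current = nxt
        pathways.append((blocked, syn, nsyn))
    open_paths = [(s, n) for blocked, s, n in pathways if not blocked]
    if not open_paths:
        open_paths = [(s, n) for _, s, n in pathways]
    syn = float(np.mean([s for s, _ in open_paths]))
    nsyn = float(np.mean([n for _, n in open_paths]))
    return syn, nsyn


def _codons(seq: str) -> list:
    if len(seq) % 3 != 0:
        raise ValueError("sequence length not a multiple of 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def nei_gojobori_pair(seq_a: str, seq_b: str,
                      mask: list | None = None) -> PairCounts:
    """Nei-Gojobori site and difference counts for one sequence pair.

    ``mask`` is an optional list of 0-based codon (amino acid) positions
    to restrict the analysis to; by default all codons are used. Potential
    sites are averaged between the two sequences.
    """
    ca, cb = _codons(seq_a), _codons(seq_b)
    if len(ca) != len(cb):
        raise ValueError("sequences differ in length")
    idx = range(len(ca)) if mask is None else mask
    S = N = Sd = Nd = 0.0
    for i in idx:
        a, b = ca[i], cb[i]
        if a in STOP_CODONS or b in STOP_CODONS:
            raise ValueError(f"stop codon at codon {i}")
        sa, sb = synonymous_fraction(a), synonymous_fraction(b)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = pathway_counts(a, b)
        Sd += sd
        Nd += nd
    return PairCounts(S=S, N=N, Sd=Sd, Nd=Nd)


def jukes_cantor_correct(p: float) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3); requires p < 0.75."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise ValueError(f"saturated proportion p={p} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _pair_dn_minus_ds(counts: PairCounts) -> float:
    ps = counts.Sd / counts.S if counts.S > 0 else 0.0
    pn = counts.Nd / counts.N if counts.N > 0 else 0.0
    return jukes_cantor_correct(pn) - jukes_cantor_correct(ps)


def _pair_codon_tables(seq_codons: np.ndarray) -> tuple:
    """Per-pair, per-codon potential and observed count arrays.

    Returns (S, N, Sd, Nd), each shaped (n_pairs, n_codons), so that any
    codon resampling reduces to a column gather plus row sum.
    """
    n, n_codons = seq_codons.shape
    syn_frac = np.array([[synonymous_fraction(seq_codons[i, c])
                          for c in range(n_codons)] for i in range(n)])
    pairs = list(itertools.combinations(range(n), 2))
    S = np.empty((len(pairs), n_codons))
    Sd = np.empty_like(S)
    Nd = np.empty_like(S)
    for p, (i, j) in enumerate(pairs):
        S[p] = (syn_frac[i] + syn_frac[j]) / 2.0
        for c in range(n_codons):
            Sd[p, c], Nd[p, c] = pathway_counts(seq_codons[i, c],
                                                seq_codons[j, c])
    N = 3.0 - S
    return S, N, Sd, Nd


def _mean_stat_from_tables(tables: tuple, codon_idx: np.ndarray
                           ) -> tuple[float, int, int]:
    """Mean pairwise dN-dS for the given codon columns.

    Saturated pairs (pS or pN >= 0.75) are excluded; returns
    (mean, n_pairs_used, n_saturated).
    """
    S, N, Sd, Nd = (t[:, codon_idx].sum(axis=1) for t in tables)
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(S > 0, Sd / np.maximum(S, 1e-300), 0.0)
        pn = np.where(N > 0, Nd / np.maximum(N, 1e-300), 0.0)
    ok = (ps < 0.75) & (pn < 0.75)
    saturated = int(np.sum(~ok))
    if not np.any(ok):
        return float("nan"), 0, saturated
    ds = -0.75 * np.log1p(-4.0 * ps[ok] / 3.0)
    dn = -0.75 * np.log1p(-4.0 * pn[ok] / 3.0)
    return float(np.mean(dn - ds)), int(np.sum(ok)), saturated


def mean_dn_minus_ds(seqs: list, mask: list | None = None,
                     n_bootstrap: int = 1000, seed: int = 0,
                     partition: str = "all") -> SelectionResult:
    """Mean dN-dS over all pairs with bootstrap SE and one-tailed Z-test.

    The statistic averages the Jukes-Cantor-corrected dN - dS over all
    unordered sequence pairs within the codon ``mask`` (0-based amino acid
    positions; all codons by default). The SE is the sample SD of the
    statistic over ``n_bootstrap`` codon-resampled replicates; Z =
    mean/SE and p is the upper-tail normal probability for the test of
    positive selection (H0: dN <= dS). Pairs saturated under Jukes-Cantor
    are excluded with a warning; if every pair saturates an error is
    raised.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    codon_lists = [_codons(s) for s in seqs]
    if len({len(c) for c in codon_lists}) != 1:
        raise ValueError("sequences differ in length")
    arr = np.array(codon_lists)
    n_codons = arr.shape[1]
    codon_idx = np.arange(n_codons) if mask is None else np.asarray(mask, int)
    if codon_idx.size == 0:
        raise ValueError("empty site mask")

    tables = _pair_codon_tables(arr)
    mean, used, saturated = _mean_stat_from_tables(tables, codon_idx)
    if used == 0:
        raise ValueError("all sequence pairs saturated under Jukes-Cantor")
    if saturated:
        warnings.warn(f"{saturated} saturated pairs excluded")

    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_bootstrap):
        resampled = rng.choice(codon_idx, size=codon_idx.size, replace=True)
        m, u, _ = _mean_stat_from_tables(tables, resampled)
        if u > 0 and np.isfinite(m):
            reps.append(m)
    se = float(np.std(reps, ddof=1)) if len(reps) > 1 else float("nan")
    z = mean / se if se and se > 0 else float("nan")
    p = float(stats.norm.sf(z)) if np.isfinite(z) else float("nan")
    return SelectionResult(
        dn_minus_ds=mean, se=se, z=z, p_value=p, partition=partition,
        n_alleles=len(seqs), n_codons=int(codon_idx.size),
        n_pairs_used=used, n_pairs_saturated=saturated)
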