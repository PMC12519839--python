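"""Sequence polymorphism statistics and per-individual diversity summaries.

Implements the standard population-genetic descriptors for an allele
alignment — segregating sites S, total mutations eta, mean pairwise
nucleotide differences k, per-site nucleotide diversity pi = k/L, mean
pairwise percent identity, and the amino acid p-distance with a
column-bootstrap standard error — plus per-individual allele/supertype
summaries and allele accumulation curves.

Columns containing non-ACGT symbols (gaps, ambiguity codes) are excluded
from every statistic, with the effective length L adjusted accordingly
(complete deletion).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

VALID_BASES = frozenset("ACGT")


def _clean_columns(seqs: list) -> np.ndarray:
    """Alignment as a (n, L') character array after complete deletion."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arr = np.array([list(s) for s in seqs])
    keep = np.array([set(arr[:, j]) <= VALID_BASES
                     for j in range(arr.shape[1])])
    return arr[:, keep]


def polymorphism_stats(seqs: list) -> dict:
    """Nucleotide polymorphism descriptors of an allele set.

    Returns S (columns with >= 2 observed bases), eta (sum over columns of
    distinct bases minus one), k (mean pairwise Hamming difference), pi
    (k divided by the effective length) and mean pairwise percent
    identity. A single sequence yields zeros and 100% identity.
    """
    if len(seqs) == 0:
        raise ValueError("no sequences supplied")
    arr = _clean_columns(list(seqs))
    n, L = arr.shape
    out = {"n_alleles": n, "length": int(L)}
    if n == 1:
        out.update({"S": 0, "eta": 0, "k": 0.0, "pi": 0.0,
                    "pairwise_identity_pct": 100.0})
        return out
    n_states = np.array([len(set(arr[:, j])) for j in range(L)])
    S = int(np.sum(n_states >= 2))
    eta = int(np.sum(n_states - 1))
    diffs = [np.sum(arr[i] != arr[j])
             for i, j in itertools.combinations(range(n), 2)]
    k = float(np.mean(diffs))
    out.update({
        "S": S, "eta": eta, "k": k, "pi": k / L,
        "pairwise_identity_pct": float(100.0 * (1.0 - np.mean(diffs) / L)),
    })
    return out


def aa_p_distance(proteins: list, n_bootstrap: int = 1000,
                  seed: int = 0) -> tuple[float, float]:
    """Mean amino acid p-distance with a site-bootstrap standard error.

    p-distance is the proportion of differing residues per pair (uniform
    rates); the SE resamples residue columns with replacement and takes
    the sample SD of the recomputed mean over replicates.
    """
    proteins = list(proteins)
    if len(proteins) < 2:
        raise ValueError("need >= 2 proteins")
    if len({len(p) for p in proteins}) != 1:
        raise ValueError("proteins must be equal length")
    arr = np.array([list(p) for p in proteins])
    n, L = arr.shape
    if L == 0:
        raise ValueError("zero-length proteins")
    pairs = list(itertools.combinations(range(n), 2))
    diff = np.array([arr[i] != arr[j] for i, j in pairs])  # pairs x sites
    mean_p = float(diff.mean())
    rng = np.random.default_rng(seed)
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        cols = rng.integers(0, L, size=L)
        reps[b] = diff[:, cols].mean()
    return mean_p, float(np.std(reps, ddof=1))


def per_individual_summary(genotypes: pd.DataFrame,
                           supertype_map: dict) -> tuple[pd.DataFrame, dict]:
    """Allele and distinct-supertype counts per individual, with their
    Pearson correlation.

    ``genotypes`` is a binary individuals x alleles matrix; alleles absent
    from ``supertype_map`` (e.g. pseudogenes) contribute to the allele
    count but not to the supertype count. With fewer than 3 individuals or
    zero variance in either count the correlation is flagged undefined.
    """
    rows = []
    for ind, row in genotypes.iterrows():
        carried = [a for a in genotypes.columns if row[a]]
        sts = {supertype_map[a] for a in carried if a in supertype_map}
        rows.append({"individual": ind, "n_alleles": len(carried),
                     "n_supertypes": len(sts)})
    df = pd.DataFrame.from_records(rows).set_index("individual")
    x, y = df["n_alleles"].to_numpy(float), df["n_supertypes"].to_numpy(float)
    if len(df) < 3 or np.std(x) == 0 or np.std(y) == 0:
        corr = {"cor": float("nan"), "p": float("nan"), "defined": False}
    else:
        r, p = stats.pearsonr(x, y)
        corr = {"cor": float(r), "p": float(p), "defined": True}
    return df, corr


def allele_accumulation(genotypes: pd.DataFrame, n_permutations: int = 100,
                        seed: int = 0) -> np.ndarray:
    """Mean allele accumulation curve over random sample orderings.

    Entry m-1 is the expected number of unique alleles among the first m
    individuals; the curve is monotone non-decreasing and ends at the
    total allele count observed in the cohort.
    """
    if genotypes.empty:
        raise ValueError("no genotypes supplied")
    mat = genotypes.to_numpy(bool)
    n = mat.shape[0]
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        seen = np.zeros(mat.shape[1], dtype=bool)
        for m, idx in enumerate(order):
            seen |= mat[idx]
            curves[p, m] = seen.sum()
    return curves.mean(axis=0)
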