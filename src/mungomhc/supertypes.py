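"""Functional supertype clustering of MHC alleles.

Alleles are embedded by the five physicochemical z-descriptors of the
residues at selected sites (positively selected sites or peptide-binding
residues), clustered by repeated k-means with a BIC-based "goodfit" rule
for the number of clusters, and assigned by discriminant analysis of
principal components (DAPC). Repeatability over runs is summarised by
Light's Kappa (mean pairwise Cohen's kappa after Hungarian label
alignment) and the mean assignment proportion (mean maximum posterior
membership).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import cohen_kappa_score

# Five z-scale descriptors per amino acid (lipophilicity, steric bulk /
# polarisability, polarity, and two electronic-property scales) derived
# from 26 measured and computed physicochemical properties of the
# proteinogenic amino acids.
Z_DESCRIPTORS: dict = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}


@dataclass
class SupertypeAssignment:
    labels: dict                 # allele_id -> supertype label (1-based)
    k: int
    kappa: float
    mean_assignment_proportion: float
    per_run_labels: np.ndarray = field(repr=False, default=None)


def encode_z_descriptors(proteins: dict, sites: list) -> tuple[np.ndarray, list]:
    """Embed proteins as concatenated z-descriptor vectors at ``sites``.

    ``sites`` are 0-based residue positions; each contributes five
    dimensions. Euclidean distance on the rows is the physicochemical
    (Sandberg-style) distance between alleles. Residues without a
    descriptor (gaps, X) raise an error naming the allele and site.
    """
    if not sites:
        raise ValueError("empty site list")
    names = sorted(proteins)
    rows = []
    for name in names:
        seq = proteins[name]
        vec = []
        for s in sites:
            if s >= len(seq):
                raise ValueError(f"site {s} beyond protein {name}")
            residue = seq[s]
            if residue not in Z_DESCRIPTORS:
                raise ValueError(
                    f"no z-descriptors for residue {residue!r} "
                    f"(allele {name}, site {s})")
            vec.extend(Z_DESCRIPTORS[residue])
        rows.append(vec)
    return np.asarray(rows, dtype=float), names


def _bic_kmeans(X: np.ndarray, k: int, rng_seed: int) -> float:
    """BIC of a k-means solution: n ln(WSS/n) + k ln(n)."""
    n = X.shape[0]
    if k == 1:
        wss = float(((X - X.mean(axis=0)) ** 2).sum())
    else:
        km = KMeans(n_clusters=k, n_init=5, random_state=rng_seed).fit(X)
        wss = float(km.inertia_)
    wss = max(wss, 1e-12)
    return n * np.log(wss / n) + k * np.log(n)


def select_cluster_number(X: np.ndarray, k_max: int = 20,
                          n_reps: int = 500, seed: int = 0,
                          step_fraction: float = 0.1) -> dict:
    """Repeated k-means cluster-number selection with a BIC elbow rule.

    Per repetition, k-means is run for k = 1..k_max and the selected k is
    the smallest one after which every further BIC improvement step stays
    below ``step_fraction`` of the largest single-step improvement (the
    elbow of the BIC curve). This emulates a goodness-of-fit stopping rule
    while staying robust to the slow monotone BIC drift past the elbow
    that k-means exhibits on small samples. Reports the mean, mode and
    median of the selected k over repetitions; the consensus k is the mode
    (ties broken toward smaller k).
    """
    n = X.shape[0]
    if n < 2 or np.unique(X, axis=0).shape[0] < 2:
        return {"k_mean": 1.0, "k_mode": 1, "k_median": 1.0,
                "k_consensus": 1, "per_rep": [1] * n_reps}
    k_max_eff = min(k_max, n - 1)
    rng = np.random.default_rng(seed)
    selected = []
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        bic = np.array([_bic_kmeans(X, k, rep_seed + k)
                        for k in range(1, k_max_eff + 1)])
        steps = bic[:-1] - bic[1:]          # improvement of k -> k+1
        max_step = steps.max() if steps.size else 0.0
        if max_step <= 0:
            selected.append(1)
            continue
        k_sel = k_max_eff
        for k in range(1, k_max_eff):
            if steps[k - 1] < step_fraction * max_step:
                k_sel = k
                break
        selected.append(k_sel)
    counts = collections.Counter(selected)
    top = max(counts.values())
    mode = min(k for k, c in counts.items() if c == top)
    return {"k_mean": float(np.mean(selected)),
            "k_mode": mode,
            "k_median": float(np.median(selected)),
            "k_consensus": mode,
            "per_rep": selected}


def _align_labels(reference: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel ``labels`` to best match ``reference`` (Hungarian matching)."""
    confusion = np.zeros((k, k))
    for r, l in zip(reference, labels):
        confusion[r, l] += 1
    row, col = linear_sum_assignment(-confusion)
    mapping = {c: r for r, c in zip(row, col)}
    return np.array([mapping[l] for l in labels])


def assign_supertypes_dapc(X: np.ndarray, k: int, names: list | None = None,
                           n_reps: int = 500, seed: int = 0,
                           var_retained: float = 0.9) -> SupertypeAssignment:
    """Repeated DAPC assignment of alleles to k supertypes.

    Per repetition: k-means grouping, PCA retaining the smallest number of
    components explaining >= ``var_retained`` of the variance (capped at
    n/3), then linear discriminant analysis on the groups with posterior
    memberships. Labels are aligned across runs by Hungarian matching on
    confusion matrices; the final label per allele is the modal aligned
    label, Light's Kappa is the mean Cohen's kappa over all run pairs, and
    the mean assignment proportion averages the per-allele maximum
    posterior over runs.
    """
    n = X.shape[0]
    if names is None:
        names = [f"allele_{i}" for i in range(n)]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return SupertypeAssignment(labels={nm: 1 for nm in names}, k=1,
                                   kappa=1.0, mean_assignment_proportion=1.0,
                                   per_run_labels=np.zeros((n_reps, n), int))

    rng = np.random.default_rng(seed)
    all_labels = np.empty((n_reps, n), dtype=int)
    max_posteriors = np.empty(n_reps)
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        km = KMeans(n_clusters=k, n_init=1, random_state=rep_seed).fit(X)
        groups = km.labels_
        n_comp_cap = max(1, n // 3)
        pca = PCA(n_components=min(n - 1, X.shape[1]), random_state=rep_seed)
        scores = pca.fit_transform(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_comp = min(int(np.argmax(cum >= var_retained)) + 1, n_comp_cap)
        scores = scores[:, :n_comp]
        k_eff = len(np.unique(groups))
        if k_eff < 2:
            all_labels[rep] = groups
            max_posteriors[rep] = 1.0
            continue
        lda = LinearDiscriminantAnalysis()
        lda.fit(scores, groups)
        post = lda.predict_proba(scores)
        all_labels[rep] = lda.classes_[np.argmax(post, axis=1)]
        max_posteriors[rep] = float(post.max(axis=1).mean())

    reference = all_labels[0]
    aligned = np.empty_like(all_labels)
    for rep in range(n_reps):
        aligned[rep] = _align_labels(reference, all_labels[rep], k)

    # Light's Kappa: mean pairwise Cohen's kappa over runs
    kappas = []
    for i in range(n_reps):
        for j in range(i + 1, n_reps):
            if np.array_equal(aligned[i], aligned[j]):
                kappas.append(1.0)
            else:
                kappas.append(cohen_kappa_score(aligned[i], aligned[j]))
    kappa = float(np.mean(kappas)) if kappas else 1.0

    final = np.array([np.bincount(aligned[:, i], minlength=k).argmax()
                      for i in range(n)])
    labels = {nm: int(l) + 1 for nm, l in zip(names, final)}
    return SupertypeAssignment(
        labels=labels, k=k, kappa=kappa,
        mean_assignment_proportion=float(max_posteriors.mean()),
        per_run_labels=aligned)
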