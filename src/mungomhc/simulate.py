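"""Synthetic data generation for every pipeline stage.

Emulates the study's inputs with known ground truth: amplicon sequencing
runs with PCR/sequencing artefacts and duplicate samples, population
genotype matrices built from a small set of haplotypes (producing linkage
blocks), codon alignments evolved under site-specific dN/dS classes, and
cross-species trait tables with Brownian phylogenetic covariance.

All randomness flows from ``SimConfig.seed`` (or an explicit ``seed``
argument); identical seed and configuration give byte-identical outputs.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# configuration and ground truth containers
# ---------------------------------------------------------------------------

STOP_CODONS = {"TAA", "TAG", "TGA"}
NUCLEOTIDES = "ACGT"

#: amino acid required at the "classical" diagnostic column of simulated
#: proteins; alleles carrying anything else there are nonclassical.
CONSERVED_RESIDUE = "Y"
#: 0-based protein position of that diagnostic column.
CONSERVED_SITE = 5


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: amplicons of a few hundred
    in-frame nucleotides, a few hundred duplicate-typed individuals,
    read depths of order 100-5000 per amplicon, and a small number of
    common haplotypes carrying several alleles each.
    """

    seed: int = 0
    n_alleles: int = 24
    seq_length_nt: int = 228
    n_individuals: int = 120
    n_haplotypes: int = 6
    haplotype_size: int = 4
    error_rate: float = 0.0
    artefact_fraction: float = 0.0
    depth_mean: float = 600.0
    depth_dispersion: float = 5.0
    pseudo_fraction: float = 0.0
    nonclassical_fraction: float = 0.0
    inbreeding_f: float = 0.0
    exon: str = "I-2"

    def __post_init__(self) -> None:
        for name in ("error_rate", "artefact_fraction", "pseudo_fraction",
                     "nonclassical_fraction", "inbreeding_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pseudo_fraction + self.nonclassical_fraction > 1.0:
            raise ValueError("pseudo_fraction + nonclassical_fraction exceed 1")
        if self.seq_length_nt < 30:
            raise ValueError("seq_length_nt must be >= 30")
        if self.seq_length_nt % 3 != 0:
            raise ValueError("seq_length_nt must be a multiple of 3")
        if self.n_haplotypes < 1:
            raise ValueError("n_haplotypes must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_alleles: list = field(default_factory=list)   # (allele_id, seq, status)
    haplotypes: list = field(default_factory=list)     # list of frozenset of allele ids
    haplotype_freqs: list = field(default_factory=list)
    individual_haplotypes: dict = field(default_factory=dict)  # ind -> (h1, h2)
    genotypes: dict = field(default_factory=dict)      # ind -> frozenset allele ids
    artefact_log: list = field(default_factory=list)   # dicts per artefact event
    omega_classes: list = field(default_factory=list)  # per-codon dN/dS class
    model_params: dict = field(default_factory=dict)

    @property
    def allele_seqs(self) -> dict:
        return {a: s for a, s, _ in self.true_alleles}

    @property
    def allele_status(self) -> dict:
        return {a: st for a, _, st in self.true_alleles}


# ---------------------------------------------------------------------------
# allele pool
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted(
    c for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)

# codons for the conserved residue (Tyr) and plausible replacements
_CODON_BY_AA: dict = {}
from Bio.Data.CodonTable import standard_dna_table as _tab  # noqa: E402

for _codon, _aa in _tab.forward_table.items():
    _CODON_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODON_BY_AA:
    _CODON_BY_AA[_aa].sort()


def _random_coding_sequence(rng: np.random.Generator, n_codons: int) -> list:
    """Random in-frame codon list without stop codons."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return [_SENSE_CODONS[i] for i in idx]


def simulate_allele_pool(cfg: SimConfig) -> tuple[str, GroundTruth]:
    """Generate a pool of distinct allele sequences with status labels.

    Returns the FASTA text of the pool and a :class:`GroundTruth` whose
    ``true_alleles`` holds ``(allele_id, sequence, status)`` with status in
    ``{"classical", "nonclassical", "pseudogene"}``. A ``pseudo_fraction``
    subset carries an in-frame stop codon; a ``nonclassical_fraction``
    subset carries a non-conserved residue at the designated conserved
    protein column; the remainder are classical coding sequences sharing
    the conserved motif.
    """
    rng = np.random.default_rng(cfg.seed)
    n_codons = cfg.seq_length_nt // 3
    n_pseudo = int(round(cfg.pseudo_fraction * cfg.n_alleles))
    n_nonclassical = int(round(cfg.nonclassical_fraction * cfg.n_alleles))
    if n_pseudo + n_nonclassical > cfg.n_alleles:
        raise ValueError("status fractions leave no room for classical alleles")

    # common scaffold with ~35% variable codon positions: keeps alleles
    # alignable (the real alleles are 84-95% pairwise identical)
    scaffold = _random_coding_sequence(rng, n_codons)
    scaffold[CONSERVED_SITE] = _CODON_BY_AA[CONSERVED_RESIDUE][0]
    variable = rng.choice(
        [i for i in range(n_codons) if i != CONSERVED_SITE],
        size=max(2, int(0.35 * n_codons)), replace=False)

    truth = GroundTruth()
    seen = set()
    non_conserved_aas = sorted(set(_CODON_BY_AA) - {CONSERVED_RESIDUE})
    for i in range(cfg.n_alleles):
        while True:
            codons = list(scaffold)
            for pos in variable:
                if rng.random() < 0.5:
                    codons[pos] = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
            if i < n_pseudo:
                status = "pseudogene"
                stop_pos = int(rng.integers(1, n_codons - 1))
                codons[stop_pos] = sorted(STOP_CODONS)[rng.integers(3)]
            elif i < n_pseudo + n_nonclassical:
                status = "nonclassical"
                aa = non_conserved_aas[rng.integers(len(non_conserved_aas))]
                codons[CONSERVED_SITE] = _CODON_BY_AA[aa][0]
            else:
                status = "classical"
            seq = "".join(codons)
            if status != "pseudogene":
                internal = {seq[j:j + 3] for j in range(0, len(seq), 3)}
                if internal & STOP_CODONS:
                    continue  # a variable draw created a stop; redraw
            if seq not in seen:
                seen.add(seq)
                break
        allele_id = f"allele_{i + 1:02d}"
        truth.true_alleles.append((allele_id, seq, status))

    _assign_haplotypes(truth, cfg, rng)

    fasta = io.StringIO()
    for allele_id, seq, status in truth.true_alleles:
        fasta.write(f">{allele_id} status={status}\n{seq}\n")
    return fasta.getvalue(), truth


def _assign_haplotypes(truth: GroundTruth, cfg: SimConfig,
                       rng: np.random.Generator) -> None:
    """Partition-ish assignment of alleles to haplotypes with frequencies."""
    ids = [a for a, _, _ in truth.true_alleles]
    haps = []
    for h in range(cfg.n_haplotypes):
        size = min(cfg.haplotype_size, len(ids))
        members = rng.choice(ids, size=size, replace=False)
        haps.append(frozenset(members.tolist()))
    freqs = rng.dirichlet(np.full(cfg.n_haplotypes, 5.0))
    truth.haplotypes = haps
    truth.haplotype_freqs = freqs.tolist()


# ---------------------------------------------------------------------------
# population genotypes
# ---------------------------------------------------------------------------

def simulate_population_genotypes(truth: GroundTruth, cfg: SimConfig,
                                  haplotypes: list | None = None,
                                  haplotype_freqs: list | None = None,
                                  ) -> pd.DataFrame:
    """Draw two haplotypes per individual and return a binary genotype matrix.

    With probability ``cfg.inbreeding_f`` the two haplotypes are identical
    by descent; otherwise they are drawn independently from the haplotype
    frequency distribution. The genotype is the union of the two allele
    sets (presence/absence only, as NGS amplicon typing cannot count
    copies). Rows are individuals, columns allele ids.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    haps = list(haplotypes if haplotypes is not None else truth.haplotypes)
    freqs = np.asarray(haplotype_freqs if haplotype_freqs is not None
                       else truth.haplotype_freqs, dtype=float)
    if len(haps) == 0:
        raise ValueError("no haplotypes defined")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")

    all_alleles = sorted({a for h in haps for a in h})
    rows = {}
    for i in range(cfg.n_individuals):
        ind = f"ind_{i + 1:03d}"
        h1 = int(rng.choice(len(haps), p=freqs))
        if rng.random() < cfg.inbreeding_f:
            h2 = h1
        else:
            h2 = int(rng.choice(len(haps), p=freqs))
        genotype = frozenset(haps[h1] | haps[h2])
        truth.individual_haplotypes[ind] = (h1, h2)
        truth.genotypes[ind] = genotype
        rows[ind] = {a: int(a in genotype) for a in all_alleles}
    gm = pd.DataFrame.from_dict(rows, orient="index", columns=all_alleles)
    gm.index.name = "individual"
    return gm


# ---------------------------------------------------------------------------
# amplicon runs
# ---------------------------------------------------------------------------

def _mutate(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    """Substitute ``n_sub`` distinct positions of ``seq``."""
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for p in pos:
        alternatives = [b for b in NUCLEOTIDES if b != chars[p]]
        chars[p] = alternatives[rng.integers(3)]
    return "".join(chars)


def simulate_amplicon_run(truth: GroundTruth, cfg: SimConfig,
                          plate_size: int = 94) -> pd.DataFrame:
    """Simulate a duplicate-typed amplicon sequencing run.

    Every individual in ``truth.genotypes`` is amplified twice (replicates
    1 and 2); each plate additionally carries one negative control with
    near-zero reads. Per amplicon, each true allele receives a negative-
    binomial read count around ``depth_mean``; with probability
    ``artefact_fraction`` an artefact variant is spawned at 1-2 nt from
    its parent allele, at a within-amplicon frequency strictly below the
    parent's, and logged in ``truth.artefact_log``. ``error_rate`` adds
    unconditioned stray variants at low depth.

    Returns the variant table with columns
    ``sample_id, replicate, plate, well, sequence, reads``.
    """
    if cfg.depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(cfg.seed + 2)
    seqs = truth.allele_seqs
    records = []
    truth.artefact_log.clear()

    individuals = sorted(truth.genotypes)
    n_plates = max(1, math.ceil(len(individuals) / plate_size))
    # NB parameterised by mean m and dispersion r: p = r/(r+m)
    r = cfg.depth_dispersion
    p_nb = r / (r + cfg.depth_mean)

    for i, ind in enumerate(individuals):
        plate = i // plate_size + 1
        well = f"W{i % plate_size + 1:02d}"
        genotype = sorted(truth.genotypes[ind])
        for rep in (1, 2):
            amplicon = {}
            for allele in genotype:
                reads = int(rng.negative_binomial(r, p_nb)) + 1
                amplicon[seqs[allele]] = amplicon.get(seqs[allele], 0) + reads
            # PCR/sequencing artefacts: child variant 1-2 nt from a parent
            for allele in genotype:
                if rng.random() < cfg.artefact_fraction:
                    parent_seq = seqs[allele]
                    child = _mutate(parent_seq, int(rng.integers(1, 3)), rng)
                    if child in amplicon:
                        continue
                    frac = rng.uniform(0.05, 0.45)
                    reads = max(1, int(frac * amplicon[parent_seq]))
                    amplicon[child] = reads
                    truth.artefact_log.append({
                        "sample_id": ind, "replicate": rep,
                        "parent": allele, "parent_seq": parent_seq,
                        "sequence": child, "reads": reads})
            if cfg.error_rate > 0:
                for allele in genotype:
                    if rng.random() < cfg.error_rate * len(seqs[allele]):
                        child = _mutate(seqs[allele], 1, rng)
                        if child not in amplicon:
                            amplicon[child] = max(1, int(
                                0.02 * amplicon[seqs[allele]]) or 1)
                            truth.artefact_log.append({
                                "sample_id": ind, "replicate": rep,
                                "parent": allele, "parent_seq": seqs[allele],
                                "sequence": child, "reads": amplicon[child]})
            for seq, reads in sorted(amplicon.items()):
                records.append((ind, rep, plate, well, seq, reads))

    # one near-empty negative control per plate
    pool = sorted(seqs.values())
    for plate in range(1, n_plates + 1):
        ctrl = f"NEG_{plate:02d}"
        reads = int(rng.integers(0, 4))
        if reads > 0:
            records.append((ctrl, 1, plate, "W95", pool[rng.integers(len(pool))],
                            reads))
        else:
            records.append((ctrl, 1, plate, "W95", pool[0], 0))

    table = pd.DataFrame(records, columns=[
        "sample_id", "replicate", "plate", "well", "sequence", "reads"])
    return table[table["reads"] > 0].reset_index(drop=True)


# ---------------------------------------------------------------------------
# codon alignments under site-specific omega
# ---------------------------------------------------------------------------

def _translate_codon(codon: str) -> str:
    return _tab.forward_table.get(codon, "*")


def _evolve_codons(codons: list, brlen: float, omega: np.ndarray,
                   rng: np.random.Generator, rate: float = 1.0) -> list:
    """Evolve a codon sequence along one branch.

    Jukes-Cantor nucleotide proposals at ``rate`` substitutions per site,
    thinned by acceptance probability min(1, omega) for nonsynonymous
    proposals (synonymous proposals always accepted); proposals creating a
    stop codon are rejected.
    """
    codons = list(codons)
    n_nt = 3 * len(codons)
    n_events = rng.poisson(rate * brlen * n_nt)
    for _ in range(n_events):
        pos = int(rng.integers(n_nt))
        ci, off = divmod(pos, 3)
        old = codons[ci]
        alt = [b for b in NUCLEOTIDES if b != old[off]]
        new = old[:off] + alt[rng.integers(3)] + old[off + 1:]
        if new in STOP_CODONS:
            continue
        w = omega[ci]
        if _translate_codon(new) == _translate_codon(old):
            # omega > 1 is realised by thinning synonymous changes instead
            if rng.random() < min(1.0, 1.0 / w) if w > 0 else True:
                codons[ci] = new
        elif rng.random() < min(1.0, w):
            codons[ci] = new
    return codons


def simulate_selection_alignment(tree: dendropy.Tree,
                                 omega_by_site: np.ndarray,
                                 cfg: SimConfig,
                                 rate: float = 1.0) -> dict:
    """Evolve codon sequences along ``tree`` under site-specific omega.

    ``omega_by_site`` gives the per-codon dN/dS class; branch lengths are
    in expected substitutions per site (before selective thinning). Returns
    ``{taxon_label: sequence}`` for the extant tips; no extant sequence
    contains a stop codon.
    """
    omega = np.asarray(omega_by_site, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega values must be > 0")
    if cfg.seq_length_nt % 3 != 0:
        raise ValueError("seq_length_nt must be a multiple of 3")
    n_codons = cfg.seq_length_nt // 3
    if len(omega) != n_codons:
        raise ValueError("omega_by_site length must equal codon count")
    rng = np.random.default_rng(cfg.seed + 3)
    root_codons = _random_coding_sequence(rng, n_codons)

    seqs = {}
    state = {tree.seed_node: root_codons}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_codons = state[node.parent_node]
        brlen = node.edge.length or 0.0
        state[node] = _evolve_codons(parent_codons, brlen, omega, rng, rate)
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(state[node])
    return seqs


# ---------------------------------------------------------------------------
# comparative trait data
# ---------------------------------------------------------------------------

IUCN_LEVELS = ["LC", "NT", "VU", "EN", "CR"]


def simulate_comparative_dataset(tree: dendropy.Tree,
                                 betas: dict,
                                 variances: dict,
                                 n_obs_per_species: int = 2,
                                 seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate a cross-species MHC diversity table on a phylogeny.

    log10 allele count = intercept + beta_status*status + beta_log10n*log10(n)
    + beta_exons*exons + beta_class*class + species effect + phylogenetic
    effect (covariance proportional to shared branch length) + residual.

    ``betas`` needs keys ``intercept, status, log10n, exons, mhc_class``;
    ``variances`` needs ``species, phylo, resid`` (all >= 0). Returns the
    trait table and a ground-truth dict (including the latent continuous
    response ``y``).
    """
    for k, v in variances.items():
        if v < 0:
            raise ValueError(f"variance {k} must be >= 0")
    rng = np.random.default_rng(seed)
    taxa = sorted(t.label for t in tree.taxon_namespace)
    from .comparative import phylo_covariance  # shared covariance definition
    cov = phylo_covariance(tree, taxa)
    C = cov.loc[taxa, taxa].to_numpy()

    n_sp = len(taxa)
    sp_eff = rng.normal(0.0, math.sqrt(variances["species"]), size=n_sp)
    if variances["phylo"] > 0:
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n_sp))
        phy_eff = math.sqrt(variances["phylo"]) * (L @ rng.standard_normal(n_sp))
    else:
        phy_eff = np.zeros(n_sp)

    rows = []
    y_true = []
    status_by_sp = rng.integers(1, 6, size=n_sp)  # IUCN status is a species trait
    for si, sp in enumerate(taxa):
        status = int(status_by_sp[si])
        for _ in range(n_obs_per_species):
            sample_size = int(rng.integers(5, 500))
            mhc_class = "I" if rng.random() < 0.5 else "II"
            n_exons = int(rng.integers(1, 3))
            y = (betas["intercept"]
                 + betas["status"] * status
                 + betas["log10n"] * math.log10(sample_size)
                 + betas["exons"] * n_exons
                 + betas["mhc_class"] * (mhc_class == "II")
                 + sp_eff[si] + phy_eff[si]
                 + rng.normal(0.0, math.sqrt(variances["resid"])))
            n_alleles = max(1, int(round(10.0 ** y)))
            y_true.append(y)
            rows.append((sp, n_alleles, sample_size, mhc_class, n_exons,
                         IUCN_LEVELS[status - 1]))
    table = pd.DataFrame(rows, columns=[
        "species", "n_alleles", "sample_size", "mhc_class", "n_exons",
        "iucn_status"])
    truth = {"betas": dict(betas), "variances": dict(variances),
             "species_effects": sp_eff, "phylo_effects": phy_eff,
             "y": np.array(y_true)}
    return table, truth


# ---------------------------------------------------------------------------
# serialisation helpers
# ---------------------------------------------------------------------------

def write_fasta(path, seqs: dict) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def ground_truth_to_json(truth: GroundTruth) -> dict:
    return {
        "true_alleles": [list(t) for t in truth.true_alleles],
        "haplotypes": [sorted(h) for h in truth.haplotypes],
        "haplotype_freqs": truth.haplotype_freqs,
        "individual_haplotypes": {k: list(v)
                                  for k, v in truth.individual_haplotypes.items()},
        "genotypes": {k: sorted(v) for k, v in truth.genotypes.items()},
        "n_artefact_events": len(truth.artefact_log),
    }
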