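"""Amplicon genotype validation.

Turns per-sample sequence variant tables (one row per sample, replicate
and variant, with read counts) into validated per-individual genotypes:
frequency thresholding, a three-rule allele/artefact decision procedure,
replicate merging, genotype reproducibility, negative-control screening
and pedigree plausibility checks.

The decision procedure formalises the criteria used for manual MHC allele
validation: per-amplicon frequency, nucleotide distance to a more frequent
variant, co-occurrence with that variant, replicate concordance, and the
number of independent samples a variant appears in. Branch priority is
(i) global frequency floor, (ii) artefact signature, (iii) allele support;
the exact branch thresholds are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["sample_id", "replicate", "sequence", "reads"]


@dataclass
class ValidationParams:
    """Thresholds of the allele/artefact decision procedure."""

    min_frequency: float = 0.01
    max_distance_artefact: int = 2
    min_samples: int = 3
    min_reads: int = 10

    def __post_init__(self) -> None:
        if self.min_frequency < 0 or self.max_distance_artefact < 0 \
                or self.min_samples < 0 or self.min_reads < 0:
            raise ValueError("thresholds must be >= 0")


def hamming(a: str, b: str) -> float:
    """Nucleotide distance; unequal lengths never merge (distance inf)."""
    if len(a) != len(b):
        return math.inf
    return sum(x != y for x, y in zip(a, b))


def _with_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the within-amplicon frequency of every variant row."""
    t = table.copy()
    totals = t.groupby(["sample_id", "replicate"])["reads"].transform("sum")
    t["frequency"] = t["reads"] / totals
    return t


def estimate_frequency_threshold(table: pd.DataFrame,
                                 max_distance_artefact: int = 2,
                                 floor: float = 0.01) -> float:
    """Median within-amplicon frequency of putative artefacts.

    A putative artefact is a variant at nucleotide distance
    <= ``max_distance_artefact`` from a strictly higher-frequency variant
    in the same amplicon. When no such variant exists the configured
    ``floor`` is returned.
    """
    if table.empty:
        raise ValueError("variant table is empty")
    t = _with_frequencies(table)
    artefact_freqs = []
    for _, amp in t.groupby(["sample_id", "replicate"]):
        rows = amp[["sequence", "frequency"]].to_records(index=False)
        for seq_i, freq_i in rows:
            for seq_j, freq_j in rows:
                if freq_j > freq_i and hamming(seq_i, seq_j) <= max_distance_artefact:
                    artefact_freqs.append(freq_i)
                    break
    if not artefact_freqs:
        return floor
    return float(np.median(artefact_freqs))


def validate_variants(table: pd.DataFrame,
                      params: ValidationParams) -> pd.DataFrame:
    """Label every unique sequence as allele or artefact.

    Deterministic per-sequence decision:

    i.   below ``min_frequency`` in every amplicon -> artefact;
    ii.  within ``max_distance_artefact`` of a higher-frequency variant,
         co-occurring with such a variant in every amplicon where it
         appears, and never seen in both replicates of a sample ->
         artefact;
    iii. present in both replicates of at least one sample, or present in
         >= ``min_samples`` samples with depth >= ``min_reads`` -> allele.

    Sequences matching none of the branches lack allele-level support and
    are labelled artefacts. Returns a table (sequence, label, rule) plus
    per-sequence evidence columns.
    """
    t = _with_frequencies(table)
    # higher-frequency parent per amplicon, ties broken by reads then sequence
    records = []
    co_occurs = {}      # seq -> True while every amplicon has a close parent
    for _, amp in t.groupby(["sample_id", "replicate"]):
        amp = amp.sort_values(["frequency", "reads", "sequence"],
                              ascending=[False, False, True])
        rows = list(amp[["sequence", "frequency"]].itertuples(index=False))
        for i, (seq_i, freq_i) in enumerate(rows):
            has_parent = any(
                freq_j > freq_i
                and hamming(seq_i, seq_j) <= params.max_distance_artefact
                for seq_j, freq_j in rows)
            prev = co_occurs.get(seq_i, True)
            co_occurs[seq_i] = prev and has_parent

    by_seq = t.groupby("sequence")
    max_freq = by_seq["frequency"].max()
    # replicate concordance: sequence seen in both replicates of one sample
    rep_support = (t.groupby(["sequence", "sample_id"])["replicate"]
                   .nunique().groupby("sequence").max() >= 2)
    n_samples_deep = (t[t["reads"] >= params.min_reads]
                      .groupby("sequence")["sample_id"].nunique())
    n_samples = by_seq["sample_id"].nunique()
    has_close = co_occurs  # whether every amplicon carried a close parent

    for seq in sorted(t["sequence"].unique()):
        in_both = bool(rep_support.get(seq, False))
        deep = int(n_samples_deep.get(seq, 0))
        if max_freq[seq] < params.min_frequency:
            label, rule = "artefact", "below_min_frequency"
        elif has_close.get(seq, False) and not in_both:
            label, rule = "artefact", "artefact_signature"
        elif in_both or deep >= params.min_samples:
            label, rule = "allele", "replicate_or_sample_support"
        else:
            label, rule = "artefact", "insufficient_support"
        records.append({
            "sequence": seq, "label": label, "rule": rule,
            "max_frequency": float(max_freq[seq]),
            "in_both_replicates": in_both,
            "n_samples": int(n_samples[seq]),
            "n_samples_deep": deep,
        })
    return pd.DataFrame.from_records(records)


def merge_replicates(table: pd.DataFrame,
                     labels: pd.DataFrame) -> pd.DataFrame:
    """Merge replicate amplicons into per-individual genotypes.

    The genotype is the union of allele-labelled variants across the two
    replicates; variants seen in a single replicate survive because their
    allele label already certifies global support. Individuals with no
    surviving alleles are flagged ``failed``.
    """
    allele_seqs = set(labels.loc[labels["label"] == "allele", "sequence"])
    rows = []
    for sample, grp in table.groupby("sample_id"):
        alleles = sorted(set(grp["sequence"]) & allele_seqs)
        rows.append({"individual_id": sample,
                     "alleles": frozenset(alleles),
                     "n_alleles": len(alleles),
                     "failed": len(alleles) == 0})
    return pd.DataFrame.from_records(rows).set_index("individual_id")


def reproducibility(set_a, set_b) -> float:
    """Genotype reproducibility: 2*|A & B| / (|A| + |B|).

    Equals 1 iff the replicate allele sets are identical; NaN when both
    are empty.
    """
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return float("nan")
    return 2.0 * len(a & b) / (len(a) + len(b))


def replicate_reproducibility(table: pd.DataFrame,
                              labels: pd.DataFrame) -> pd.Series:
    """Per-sample reproducibility between the two replicate allele sets."""
    allele_seqs = set(labels.loc[labels["label"] == "allele", "sequence"])
    out = {}
    for sample, grp in table.groupby("sample_id"):
        reps = {rep: set(sub["sequence"]) & allele_seqs
                for rep, sub in grp.groupby("replicate")}
        if len(reps) < 2:
            continue
        out[sample] = reproducibility(reps.get(1, set()), reps.get(2, set()))
    return pd.Series(out, name="reproducibility", dtype=float)


def check_negative_controls(table: pd.DataFrame, max_reads: float,
                            is_control=None) -> pd.DataFrame:
    """Flag negative-control amplicons whose total reads exceed ``max_reads``.

    ``is_control`` is a predicate on sample_id; by default sample ids
    starting with ``NEG`` are controls. An empty result means the run is
    clean. Missing controls produce an empty report (with a warning via
    the returned attrs).
    """
    if is_control is None:
        is_control = lambda s: str(s).startswith("NEG")  # noqa: E731
    ctrl = table[table["sample_id"].map(is_control)]
    report = (ctrl.groupby(["sample_id", "replicate"])["reads"].sum()
              .reset_index(name="total_reads"))
    flagged = report[report["total_reads"] > max_reads].reset_index(drop=True)
    flagged.attrs["n_controls"] = int(len(report))
    flagged.attrs["warning"] = "no negative controls present" if report.empty else ""
    return flagged


def pedigree_consistency(genotypes: dict, triads: list) -> pd.DataFrame:
    """Parent-offspring plausibility on multi-locus presence/absence.

    For each ``(dam, sire, offspring)`` triad, every offspring allele must
    occur in at least one parent; violations are listed per allele. Triads
    with an ungenotyped member are skipped (reported with reason).
    """
    rows = []
    for dam, sire, off in triads:
        missing = [m for m in (dam, sire, off) if m not in genotypes]
        if missing:
            rows.append({"dam": dam, "sire": sire, "offspring": off,
                         "allele": None, "issue": f"missing: {missing}"})
            continue
        parental = set(genotypes[dam]) | set(genotypes[sire])
        for allele in sorted(set(genotypes[off]) - parental):
            rows.append({"dam": dam, "sire": sire, "offspring": off,
                         "allele": allele, "issue": "allele absent from parents"})
    return pd.DataFrame.from_records(
        rows, columns=["dam", "sire", "offspring", "allele", "issue"])


def genotypes_to_matrix(genotypes: pd.DataFrame,
                        sequence_names: dict | None = None) -> pd.DataFrame:
    """Binary individuals x alleles matrix from merged genotypes.

    ``sequence_names`` optionally maps sequences to allele ids for the
    column labels.
    """
    ok = genotypes[~genotypes["failed"]]
    all_alleles = sorted({a for s in ok["alleles"] for a in s})
    data = {ind: {a: int(a in row) for a in all_alleles}
            for ind, row in ok["alleles"].items()}
    gm = pd.DataFrame.from_dict(data, orient="index", columns=all_alleles)
    if sequence_names:
        gm.columns = [sequence_names.get(c, c) for c in gm.columns]
    gm.index.name = "individual"
    return gm.sort_index()
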