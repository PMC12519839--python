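"""Allele translation, pseudogene flagging, classical/nonclassical
classification against reference-anchored conserved sites, and
frequency-ordered nomenclature.

Classification follows the convention used for MHC catalogues: an allele
with an in-frame stop codon is a pseudogene (suffix ``-Ps``); a coding
allele that fails a required conserved residue (e.g. the tyrosines
anchoring the peptide-binding groove in classical class I molecules) is
putatively nonclassical; everything else is classical. Conserved-site
columns are numbered 1-based on the reference sequence within a pairwise
reference/allele alignment; gaps in the reference are not numbered.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq


@dataclass
class ConservedSiteSpec:
    """One diagnostic alignment column on the reference protein."""

    exon: str
    reference_id: str
    column: int              # 1-based position on the reference
    expected_residue: str
    role: str = "classical-required"   # or "diagnostic"


#: Default diagnostic columns for the three amplified exons, numbered on
#: the HLA-anchored reference alignment of each exon. The first column of
#: each pair discriminates classical from nonclassical alleles (it fails
#: in known nonclassical sequences); the second is conserved across all
#: alleles and serves as an alignment sanity check. Override with a
#: custom list whenever a different reference anchoring is used.
DEFAULT_CONSERVED_SITES: list["ConservedSiteSpec"] = []


def _build_default_sites() -> None:
    entries = [
        ("I-2", "HLA-B", 83, "Y", "classical-required"),
        ("I-2", "HLA-B", 108, "Y", "diagnostic"),
        ("I-3", "HLA-B", 195, "Y", "classical-required"),
        ("I-3", "HLA-B", 167, "Y", "diagnostic"),
        ("DRB-2", "HLA-DRB1", 90, "W", "classical-required"),
        ("DRB-2", "HLA-DRB1", 110, "H", "diagnostic"),
    ]
    for exon, ref, col, residue, role in entries:
        DEFAULT_CONSERVED_SITES.append(
            ConservedSiteSpec(exon=exon, reference_id=ref, column=col,
                              expected_residue=residue, role=role))


def translate_and_flag(seq: str, frame: int = 1) -> tuple[str | None, bool]:
    """Translate from the given frame; internal stop codons flag a pseudogene.

    Returns ``(protein, is_pseudogene)``; for pseudogenes the protein is
    the translation with ``*`` marking stops.
    """
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    sub = seq[frame - 1:]
    sub = sub[:len(sub) - len(sub) % 3]
    if len(sub) < 3:
        raise ValueError("sequence shorter than one codon after frame offset")
    protein = str(Seq(sub).translate())
    return protein, "*" in protein


def _align_to_reference(reference: str, protein: str):
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner.align(reference, protein)[0]


def map_reference_column(alignment, column: int) -> str:
    """Residue of the query aligned under 1-based reference ``column``.

    Gap characters in the reference do not advance the column counter; a
    query gap at the requested column returns ``-``.
    """
    ref_aln, query_aln = alignment[0], alignment[1]
    ref_pos = 0
    for r, q in zip(ref_aln, query_aln):
        if r != "-":
            ref_pos += 1
            if ref_pos == column:
                return q
    raise ValueError(f"reference column {column} beyond alignment")


def classify_classical(protein: str, reference: str,
                       specs: list[ConservedSiteSpec]) -> tuple[str, list]:
    """Classify a coding allele as classical or nonclassical.

    Nonclassical iff any ``classical-required`` conserved residue
    mismatches after anchoring the protein on the reference. Returns the
    status and the list of mismatched columns.
    """
    if not specs:
        raise ValueError("no conserved-site specifications supplied")
    alignment = _align_to_reference(reference, protein)
    mismatches = []
    for spec in specs:
        residue = map_reference_column(alignment, spec.column)
        if spec.role == "classical-required" and residue != spec.expected_residue:
            mismatches.append((spec.column, spec.expected_residue, residue))
    return ("nonclassical" if mismatches else "classical"), mismatches


def build_catalog(seqs: dict, exon: str, frame: int, reference: str,
                  specs: list[ConservedSiteSpec]) -> pd.DataFrame:
    """Translate, flag pseudogenes and classify a pool of allele sequences.

    Pseudogene status takes precedence over the conserved-site check: a
    stop codon makes conserved-residue status moot.
    """
    rows = []
    for allele_id, seq in seqs.items():
        protein, is_pseudo = translate_and_flag(seq, frame)
        if is_pseudo:
            status, protein_out = "pseudogene", None
        else:
            status, _ = classify_classical(protein, reference, specs)
            protein_out = protein
        rows.append({"allele_id": allele_id, "exon": exon, "sequence": seq,
                     "protein": protein_out, "status": status})
    df = pd.DataFrame.from_records(rows)
    if df["sequence"].duplicated().any():
        raise ValueError("duplicate sequences in catalog; deduplicate upstream")
    return df


EXON_TAGS = {"I-2": "class-I-2", "I-3": "class-I-3", "DRB-2": "DRB"}


def assign_nomenclature(catalog: pd.DataFrame, genotypes: pd.DataFrame,
                        prefix: str = "Mumu") -> pd.DataFrame:
    """Name alleles by decreasing population frequency.

    Population frequency is the fraction of genotyped individuals carrying
    the allele. Names follow ``<Prefix> <tag>*<rank>`` with a zero-padded
    two-digit rank and a ``-Ps`` suffix for pseudogenes; frequency ties
    break by lexicographic sequence order for determinism.
    """
    if genotypes.empty:
        raise ValueError("no genotypes supplied")
    freqs = genotypes.mean(axis=0)
    cat = catalog.copy()
    cat["frequency"] = cat["allele_id"].map(freqs).fillna(0.0)
    cat = cat.sort_values(["frequency", "sequence"],
                          ascending=[False, True], kind="mergesort")
    names = []
    for rank, (_, row) in enumerate(cat.iterrows(), start=1):
        tag = EXON_TAGS.get(row["exon"], row["exon"])
        name = f"{prefix} {tag}*{rank:02d}"
        if row["status"] == "pseudogene":
            name += "-Ps"
        names.append(name)
    cat["name"] = names
    if cat["name"].duplicated().any():
        raise ValueError("nomenclature produced duplicate names")
    return cat.reset_index(drop=True)


def allele_frequency_spectrum(catalog: pd.DataFrame,
                              genotypes: pd.DataFrame) -> pd.DataFrame:
    """Carrier fraction per allele, grouped by status.

    Returns one row per allele with its fraction of individuals carrying
    it and the catalog status, sorted by decreasing frequency.
    """
    if genotypes.empty:
        raise ValueError("no genotypes supplied")
    freqs = genotypes.mean(axis=0)
    out = catalog[["allele_id", "status"]].copy()
    out["carrier_fraction"] = out["allele_id"].map(freqs).fillna(0.0)
    return (out.sort_values("carrier_fraction", ascending=False)
            .reset_index(drop=True))


_build_default_sites()
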