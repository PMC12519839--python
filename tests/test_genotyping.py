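"""Allele/artefact validation, replicate merging and plausibility checks."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mungomhc as m
from mungomhc.genotyping import genotypes_to_matrix, replicate_reproducibility


def make_table(rows):
    return pd.DataFrame(rows, columns=[
        "sample_id", "replicate", "plate", "well", "sequence", "reads"])


class TestFrequencyThreshold:
    def test_no_close_variants_returns_floor(self):
        table = make_table([
            ("s1", 1, 1, "W1", "AAAAAAAA", 90),
            ("s1", 1, 1, "W1", "TTTTTTTT", 10),
        ])
        assert m.estimate_frequency_threshold(table, floor=0.013) == 0.013

    def test_median_of_artefact_frequencies(self):
        # three amplicons, each with one artefact 1 nt from its parent at
        # within-amplicon frequencies 0.01, 0.03, 0.05 -> median 0.03
        rows = []
        for i, f in enumerate([0.01, 0.03, 0.05]):
            parent_reads = int(round(1000 * (1 - f)))
            child_reads = int(round(1000 * f))
            rows += [(f"s{i}", 1, 1, "W1", "AAAAAAAA", parent_reads),
                     (f"s{i}", 1, 1, "W1", "AAAAAAAT", child_reads)]
        assert m.estimate_frequency_threshold(make_table(rows)) \
            == pytest.approx(0.03)

    def test_invariant_to_row_order(self):
        rows = [("s1", 1, 1, "W1", "AAAAAAAA", 950),
                ("s1", 1, 1, "W1", "AAAAAAAT", 50),
                ("s2", 1, 1, "W1", "AAAAAAAA", 800),
                ("s2", 1, 1, "W1", "AAAAATAA", 200)]
        t = make_table(rows)
        shuffled = t.sample(frac=1, random_state=5).reset_index(drop=True)
        assert m.estimate_frequency_threshold(t) \
            == m.estimate_frequency_threshold(shuffled)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            m.estimate_frequency_threshold(make_table([]))


class TestValidateVariants:
    def test_distant_variant_in_both_replicates_is_allele(self):
        rows = []
        for s in ("s1", "s2", "s3"):
            for rep in (1, 2):
                rows += [(s, rep, 1, "W1", "AAAAAAAA", 500),
                         (s, rep, 1, "W1", "TTTTTTTT", 400)]
        labels = m.validate_variants(make_table(rows), m.ValidationParams())
        assert set(labels["label"]) == {"allele"}

    def test_co_occurring_close_single_replicate_variant_is_artefact(self):
        rows = [("s1", 1, 1, "W1", "AAAAAAAA", 1000),
                ("s1", 1, 1, "W1", "AAAAAAAT", 100),
                ("s1", 2, 1, "W1", "AAAAAAAA", 1000),
                ("s2", 1, 1, "W1", "AAAAAAAA", 1000),
                ("s2", 2, 1, "W1", "AAAAAAAA", 900)]
        labels = m.validate_variants(make_table(rows),
                                     m.ValidationParams()).set_index("sequence")
        assert labels.loc["AAAAAAAT", "label"] == "artefact"
        assert labels.loc["AAAAAAAT", "rule"] == "artefact_signature"
        assert labels.loc["AAAAAAAA", "label"] == "allele"

    def test_below_floor_everywhere_is_artefact(self):
        rows = [("s1", 1, 1, "W1", "AAAAAAAA", 9990),
                ("s1", 1, 1, "W1", "CCCCCCCC", 10)]
        params = m.ValidationParams(min_frequency=0.01)
        labels = m.validate_variants(make_table(rows),
                                     params).set_index("sequence")
        assert labels.loc["CCCCCCCC", "rule"] == "below_min_frequency"

    def test_validation_shrinks_and_is_idempotent(self, noisy_study):
        cfg, truth, gm, table = noisy_study
        thr = m.estimate_frequency_threshold(table)
        params = m.ValidationParams(min_frequency=thr)
        labels = m.validate_variants(table, params)
        retained = set(labels.loc[labels["label"] == "allele", "sequence"])
        assert retained <= set(table["sequence"])   # monotone shrinkage
        sub = table[table["sequence"].isin(retained)]
        labels2 = m.validate_variants(sub, params)
        assert set(labels2.loc[labels2["label"] == "allele", "sequence"]) \
            == retained                              # idempotent

    def test_noise_free_validation_recovers_ground_truth(self, noise_free_study):
        cfg, truth, gm, table = noise_free_study
        thr = m.estimate_frequency_threshold(table)
        labels = m.validate_variants(
            table, m.ValidationParams(min_frequency=thr))
        merged = m.merge_replicates(
            table[~table["sample_id"].str.startswith("NEG")], labels)
        seqs = truth.allele_seqs
        for ind, genotype in truth.genotypes.items():
            assert merged.loc[ind, "alleles"] == \
                frozenset(seqs[a] for a in genotype)


class TestMergeReplicates:
    def test_identical_replicates_give_that_genotype(self):
        rows = [("s1", 1, 1, "W1", "AAAAAAAA", 500),
                ("s1", 1, 1, "W1", "TTTTTTTT", 500),
                ("s1", 2, 1, "W1", "AAAAAAAA", 400),
                ("s1", 2, 1, "W1", "TTTTTTTT", 600)]
        table = make_table(rows)
        labels = m.validate_variants(table, m.ValidationParams())
        merged = m.merge_replicates(table, labels)
        assert merged.loc["s1", "alleles"] == {"AAAAAAAA", "TTTTTTTT"}

    def test_artefact_never_enters_genotypes(self, noisy_study):
        cfg, truth, gm, table = noisy_study
        labels = m.validate_variants(table, m.ValidationParams(
            min_frequency=m.estimate_frequency_threshold(table)))
        artefacts = set(labels.loc[labels["label"] == "artefact", "sequence"])
        merged = m.merge_replicates(table, labels)
        for alleles in merged["alleles"]:
            assert not alleles & artefacts

    def test_failed_individuals_are_flagged(self):
        table = make_table([("s1", 1, 1, "W1", "ACGTACGT", 3)])
        labels = pd.DataFrame({"sequence": ["ACGTACGT"],
                               "label": ["artefact"], "rule": ["x"]})
        merged = m.merge_replicates(table, labels)
        assert merged.loc["s1", "failed"]


class TestReproducibility:
    def test_identity_and_disjoint(self):
        assert m.reproducibility({"a", "b"}, {"a", "b"}) == 1.0
        assert m.reproducibility({"a"}, {"b"}) == 0.0
        assert m.reproducibility({"a", "b", "c"}, {"a", "b"}) \
            == pytest.approx(0.8)

    def test_both_empty_is_missing(self):
        assert math.isnan(m.reproducibility(set(), set()))

    @settings(derandomize=True, max_examples=50)
    @given(a=st.sets(st.integers(0, 10)), b=st.sets(st.integers(0, 10)))
    def test_symmetric_bounded_and_one_iff_equal(self, a, b):
        if not a and not b:
            return
        r = m.reproducibility(a, b)
        assert r == m.reproducibility(b, a)
        assert 0.0 <= r <= 1.0
        assert (r == 1.0) == (a == b)


class TestControlsAndPedigree:
    def test_clean_controls(self, noisy_study):
        cfg, truth, gm, table = noisy_study
        assert m.check_negative_controls(table, max_reads=50).empty

    def test_contaminated_control_flagged(self):
        table = make_table([("NEG_01", 1, 1, "W95", "ACGTACGT", 200),
                            ("s1", 1, 1, "W1", "ACGTACGT", 900)])
        report = m.check_negative_controls(table, max_reads=100)
        assert list(report["sample_id"]) == ["NEG_01"]
        assert m.check_negative_controls(table, max_reads=math.inf).empty

    def test_pedigree_violations(self):
        genotypes = {"dam": {"a", "b"}, "sire": {"c"}, "kid": {"a", "z"},
                     "kid2": {"a", "c"}}
        report = m.pedigree_consistency(
            genotypes, [("dam", "sire", "kid"), ("dam", "sire", "kid2")])
        assert len(report) == 1
        assert report.iloc[0]["allele"] == "z"
        assert m.pedigree_consistency(genotypes, []).empty

    def test_missing_member_skipped_with_warning(self):
        report = m.pedigree_consistency({"dam": {"a"}},
                                        [("dam", "sire", "kid")])
        assert "missing" in report.iloc[0]["issue"]


def test_per_sample_reproducibility_perfect_without_noise(noise_free_study):
    cfg, truth, gm, table = noise_free_study
    labels = m.validate_variants(table, m.ValidationParams(
        min_frequency=m.estimate_frequency_threshold(table)))
    rep = replicate_reproducibility(table, labels)
    assert (rep == 1.0).all()


def test_genotype_matrix_roundtrip(noise_free_study):
    cfg, truth, gm_true, table = noise_free_study
    labels = m.validate_variants(table, m.ValidationParams(
        min_frequency=m.estimate_frequency_threshold(table)))
    merged = m.merge_replicates(
        table[~table["sample_id"].str.startswith("NEG")], labels)
    seq_to_id = {s: a for a, s in truth.allele_seqs.items()}
    gm = genotypes_to_matrix(merged, sequence_names=seq_to_id)
    common = sorted(set(gm.columns) & set(gm_true.columns))
    pd.testing.assert_frame_equal(gm[common], gm_true[common],
                                  check_dtype=False)
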