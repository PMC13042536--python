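"""PFM construction, ∆PFM statistic, column mapping, homolog filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from passdesign.io import Alignment
from passdesign.msa import (
    NON_THERMOPHILIC,
    THERMOPHILIC,
    LabeledFamily,
    UnmappedPositionError,
    build_pfm,
    delta_pfm,
    family_dpfm,
    greedy_redundancy_filter,
    map_columns_to_query,
    mutation_dpfm,
    pairwise_identity,
    similarity_window_filter,
)
from passdesign.mutations import parse_mutation
from passdesign.synthetic import FamilyDesign, gen_family


class TestColumnMapping:
    def test_gap_skipping(self):
        aln = Alignment(ids=["q", "s"], sequences=["AC-GT", "ACAGT"])
        assert map_columns_to_query(aln, "q") == {1: 1, 2: 2, 4: 3, 5: 4}

    def test_ungapped_query_is_identity(self):
        aln = Alignment(ids=["q", "s"], sequences=["ACGT", "ACGA"])
        assert map_columns_to_query(aln, "q") == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_all_gap_query_rejected(self):
        aln = Alignment(ids=["q", "s"], sequences=["----", "ACGT"])
        with pytest.raises(ValueError):
            map_columns_to_query(aln, "q")


class TestBuildPfm:
    def test_hand_counted_frequencies(self, planted_family):
        pfm = build_pfm(planted_family, THERMOPHILIC)
        assert pfm.freq(3, "T") == pytest.approx(0.75)
        assert pfm.freq(3, "E") == pytest.approx(0.25)

    def test_single_sequence_class_is_one_hot(self):
        aln = Alignment(ids=["q", "t"], sequences=["ACD", "ACD"])
        fam = LabeledFamily(aln, {"t": THERMOPHILIC}, "q")
        pfm = build_pfm(fam, THERMOPHILIC)
        assert pfm.freq(1, "A") == 1.0
        assert pfm.freq(1, "C") == 0.0

    def test_gap_fraction_and_non_gap_normalisation(self):
        aln = Alignment(
            ids=["q", "a", "b", "c", "d"],
            sequences=["T", "T", "T", "-", "-"],
        )
        fam = LabeledFamily(aln, {x: THERMOPHILIC for x in "abcd"}, "q")
        pfm = build_pfm(fam, THERMOPHILIC)
        assert pfm.gap_fraction[0] == pytest.approx(0.5)
        assert pfm.freq(1, "T") == pytest.approx(1.0)

    def test_empty_class_rejected(self, planted_family):
        with pytest.raises(ValueError):
            build_pfm(planted_family, "no_such_class")


class TestDeltaPfm:
    def test_planted_contrast_signs_and_magnitudes(self, planted_family):
        d = family_dpfm(planted_family)
        # thermo: 3/4 T, 1/4 E; meso: 4/4 E
        assert d.value(3, "T") == pytest.approx(0.75)
        assert d.value(3, "E") == pytest.approx(0.25 - 1.0)

    def test_identical_classes_give_zero(self, planted_family):
        pfm = build_pfm(planted_family, THERMOPHILIC)
        d = delta_pfm(pfm, pfm)
        assert np.allclose(d.values, 0.0)

    def test_bound_attained_at_full_contrast(self):
        aln = Alignment(ids=["q", "t", "m"], sequences=["K", "K", "A"])
        fam = LabeledFamily(aln, {"t": THERMOPHILIC, "m": NON_THERMOPHILIC}, "q")
        d = family_dpfm(fam)
        assert d.value(1, "K") == pytest.approx(1.0)

    def test_antisymmetry_exact(self, planted_family):
        a = build_pfm(planted_family, THERMOPHILIC)
        b = build_pfm(planted_family, NON_THERMOPHILIC)
        assert np.array_equal(delta_pfm(a, b).values, -delta_pfm(b, a).values)

    def test_mutation_lookup_and_unmapped_error(self, planted_family):
        d = family_dpfm(planted_family)
        assert mutation_dpfm(d, parse_mutation("E3T")) > 0
        with pytest.raises(UnmappedPositionError):
            mutation_dpfm(d, parse_mutation("E99T"))


@given(seed=st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_pfm_normalisation_and_dpfm_bounds_on_random_families(seed):
    """Each PFM row sums to 1 over non-gaps (or 0 when fully gapped) and
    every ∆PFM entry lies in [-1, 1], for arbitrary generated families."""
    fam = gen_family(FamilyDesign(
        length=30, n_thermo=8, n_meso=6,
        planted={5: ("T", "E")}, p=0.9, gap_rate=0.15, seed=seed,
    ))
    for cls in (THERMOPHILIC, NON_THERMOPHILIC):
        pfm = build_pfm(fam, cls)
        sums = pfm.frequencies.sum(axis=1)
        fully_gapped = pfm.gap_fraction == 1.0
        assert np.allclose(sums[~fully_gapped], 1.0, atol=1e-9)
        assert np.allclose(sums[fully_gapped], 0.0)
    d = family_dpfm(fam)
    assert np.all(d.values >= -1.0 - 1e-12) and np.all(d.values <= 1.0 + 1e-12)


def test_dpfm_sign_recovery_at_study_conditions():
    """With 50 sequences per class and planted preference probability 0.8,
    the planted ∆PFM sign is recovered in at least 95% of seeds."""
    hits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        fam = gen_family(FamilyDesign(
            length=60, n_thermo=50, n_meso=50,
            planted={10: ("T", "E")}, p=0.8, seed=seed,
        ))
        d = family_dpfm(fam)
        if d.value(10, "T") > 0 and d.value(10, "E") < 0:
            hits += 1
    assert hits / n_seeds >= 0.95


class TestHomologFilters:
    def test_identical_sequences_deduplicated(self):
        kept = greedy_redundancy_filter(["a", "b"], ["ACDEF", "ACDEF"])
        assert len(kept) == 1

    def test_distinct_sequences_both_retained(self):
        # identity 2/5 = 0.4 < 0.9
        kept = greedy_redundancy_filter(["a", "b"], ["ACDEF", "ACLMN"])
        assert sorted(kept) == ["a", "b"]

    def test_copies_plus_one_distinct(self):
        seqs = ["ACDEFGHIKL"] * 4 + ["MNPQRSTVWY"]
        kept = greedy_redundancy_filter(list("abcde"), seqs)
        assert len(kept) == 2

    def test_similarity_window(self):
        query = "ACDEFGHIKL"
        seqs = {
            "self": query,                    # identity 1.0
            "half": "ACDEFAAAAA",             # identity 0.5
            "low": "ACDAAAAAAA",              # identity 0.3
        }
        kept = similarity_window_filter(
            list(seqs), list(seqs.values()), query, lo=0.40, hi=1.00
        )
        assert kept == ["self", "half"]

    def test_window_bounds_validated(self):
        with pytest.raises(ValueError):
            similarity_window_filter(["a"], ["AC"], "AC", lo=0.9, hi=0.1)

    def test_noop_window(self):
        kept = similarity_window_filter(["a", "b"], ["AAAA", "CCCC"], "AAAA", lo=0, hi=1)
        assert kept == ["a", "b"]

    def test_identity_ignores_gapped_columns(self):
        assert pairwise_identity("AC-E", "ACD-") == pytest.approx(2 / 3)
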