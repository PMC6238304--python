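from itertools import combinations_with_replacement

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cyp2d6star.caller import (
    ALT_ALT,
    MISSING,
    REF_ALT,
    REF_REF,
    SampleRecord,
    call_batch,
    call_diplotype,
    canonical_pair,
    consistent_pairs,
    predict_exon9,
    predict_genotype,
)
from oracles import naive_consistent_pairs


def record(genotypes=None, **kw):
    defaults = dict(sample_id="S", genotypes=genotypes or {}, exon9_conversion="untested")
    defaults.update(kw)
    return SampleRecord(**defaults)


class TestPredictGenotype:
    @pytest.mark.parametrize(
        "pair, locus, expected",
        [
            (("*2", "*10"), "C100T", REF_ALT),
            (("*2", "*10"), "C2850T", REF_ALT),
            (("*2", "*10"), "G4180C", ALT_ALT),
            (("*2", "*10"), "G1846A", REF_REF),
            (("*1", "*1"), "C100T", REF_REF),
            (("*1", "*1"), "G4180C", REF_REF),
            # hemizygote masking: the surviving haplotype appears homozygous
            (("*2", "*5"), "C2850T", ALT_ALT),
            (("*2", "*5"), "C100T", REF_REF),
            (("*5", "*5"), "C100T", MISSING),
        ],
    )
    def test_examples(self, table, pair, locus, expected):
        assert predict_genotype(pair, locus, table) == expected

    def test_unknown_locus_raises(self, table):
        with pytest.raises(KeyError):
            predict_genotype(("*1", "*1"), "C9999T", table)

    def test_unknown_allele_raises(self, table):
        with pytest.raises(KeyError):
            predict_genotype(("*1", "*77"), "C100T", table)

    @pytest.mark.parametrize(
        "pair, expected",
        [
            (("*1", "*10"), "absent"),
            (("*1", "*36"), "present"),
            (("*36", "*36"), "homozygous"),
            (("*5", "*36"), "homozygous"),  # masking applies to the conversion too
            (("*5", "*10"), "absent"),
            (("*5", "*5"), "untested"),
        ],
    )
    def test_exon9_appearance(self, table, pair, expected):
        assert predict_exon9(pair, table) == expected


class TestConsistentPairs:
    def test_unique_het_profile(self, table):
        s = record({"C100T": REF_ALT, "G1846A": REF_REF, "C2850T": REF_ALT, "G4180C": ALT_ALT})
        assert consistent_pairs(s, table) == [("*2", "*10")]

    def test_deletion_band_all_reference(self, table):
        s = record(
            {"C100T": REF_REF, "G1846A": REF_REF, "C2850T": REF_REF, "G4180C": REF_REF},
            deletion_band=True,
        )
        assert consistent_pairs(s, table) == [("*1", "*5")]

    def test_impossible_profile_is_empty(self, table):
        # a splice-defect homozygote without the co-occurring substitutions
        s = record({"C100T": REF_REF, "G1846A": ALT_ALT, "C2850T": REF_REF, "G4180C": REF_REF})
        assert consistent_pairs(s, table) == []

    def test_untested_exon9_excludes_conversion_allele(self, table):
        s = record({"C100T": ALT_ALT, "G1846A": REF_REF, "C2850T": REF_REF, "G4180C": ALT_ALT})
        assert consistent_pairs(s, table) == [("*10", "*10")]
        ambiguous = consistent_pairs(s, table, allow_untested_exon9_ambiguity=True)
        assert set(ambiguous) == {("*10", "*10"), ("*10", "*36"), ("*36", "*36")}

    def test_unknown_genotype_locus_raises(self, table):
        s = record({"C9999T": REF_REF})
        with pytest.raises(KeyError, match="C9999T"):
            consistent_pairs(s, table)


class TestCallDiplotype:
    def test_unique_call(self, table):
        s = record({"C100T": REF_ALT, "G1846A": REF_REF, "C2850T": REF_ALT, "G4180C": ALT_ALT})
        call = call_diplotype(s, table)
        assert call.status == "unique"
        assert call.best_pair == ("*2", "*10")

    def test_hemizygous_reduced_function_call(self, table):
        s = record(
            {"C100T": ALT_ALT, "G1846A": REF_REF, "C2850T": REF_REF, "G4180C": ALT_ALT},
            deletion_band=True,
        )
        call = call_diplotype(s, table)
        assert (call.best_pair, call.status) == (("*5", "*10"), "unique")

    def test_splice_defect_het_calls_star4(self, table):
        s = record({"C100T": ALT_ALT, "G1846A": REF_ALT, "C2850T": REF_REF, "G4180C": ALT_ALT})
        call = call_diplotype(s, table)
        assert (call.best_pair, call.status) == (("*4", "*10"), "unique")

    def test_het_with_deletion_band_is_inconsistent_not_an_exception(self, table):
        s = record(
            {"C100T": REF_ALT, "G1846A": REF_REF, "C2850T": REF_REF, "G4180C": REF_ALT},
            deletion_band=True,
        )
        call = call_diplotype(s, table)
        assert call.status == "inconsistent"
        assert "het_call_with_deletion_band" in call.notes
        assert call.consistent_pairs == []

    def test_homozygous_deletion_degenerate_case(self, table):
        s = record(
            {l: MISSING for l in table.informative_loci},
            deletion_band=True,
        )
        call = call_diplotype(s, table)
        assert (call.best_pair, call.status) == (("*5", "*5"), "unique")
        assert "homozygous_deletion_no_template" in call.notes

    def test_missing_locus_with_multiple_survivors(self, table):
        s = record({"C100T": ALT_ALT, "G1846A": MISSING, "C2850T": REF_REF, "G4180C": ALT_ALT})
        call = call_diplotype(s, table)
        assert call.status == "insufficient_data"
        # the missing splice-defect call leaves its dose unconstrained
        assert set(call.consistent_pairs) == {("*4", "*4"), ("*4", "*10"), ("*10", "*10")}

    def test_inconsistent_requires_complete_data(self, table):
        s = record({"C100T": REF_REF, "G1846A": ALT_ALT, "C2850T": MISSING, "G4180C": REF_REF})
        assert call_diplotype(s, table).status == "insufficient_data"

    def test_duplication_band_annotates_without_filtering(self, table):
        s = record(
            {"C100T": REF_ALT, "G1846A": REF_REF, "C2850T": REF_ALT, "G4180C": ALT_ALT},
            duplication_band=True,
        )
        call = call_diplotype(s, table)
        assert call.best_pair == ("*2", "*10")
        assert "duplication_present_copy_number_unresolved" in call.notes


class TestProperties:
    def test_oracle_equivalence_on_randomized_samples(self, table):
        """Enumeration must agree with an independent re-implementation."""
        import numpy as np

        rng = np.random.default_rng(2018)
        calls = [REF_REF, REF_ALT, ALT_ALT, MISSING]
        exon9 = ["present", "homozygous", "absent", "untested"]
        for i in range(1000):
            genotypes = {l: calls[rng.integers(4)] for l in table.informative_loci}
            deletion = bool(rng.random() < 0.25)
            s = SampleRecord(
                sample_id=f"R{i}",
                genotypes=genotypes,
                deletion_band=deletion,
                exon9_conversion=exon9[rng.integers(4)],
            )
            assert consistent_pairs(s, table) == naive_consistent_pairs(s, table), s

    @given(data=st.data())
    def test_dropping_a_call_never_shrinks_the_pair_set(self, table, data):
        calls = [REF_REF, REF_ALT, ALT_ALT, MISSING]
        genotypes = {
            l: data.draw(st.sampled_from(calls), label=l) for l in table.informative_loci
        }
        exon9 = data.draw(st.sampled_from(["present", "absent", "untested"]))
        s = record(dict(genotypes), exon9_conversion=exon9)
        before = set(consistent_pairs(s, table))
        drop = data.draw(st.sampled_from(table.informative_loci))
        s2 = record({**genotypes, drop: MISSING}, exon9_conversion=exon9)
        assert before <= set(consistent_pairs(s2, table))

    @given(
        weights=st.lists(
            st.floats(min_value=0.01, max_value=10.0, allow_nan=False),
            min_size=6, max_size=6,
        )
    )
    def test_unique_calls_are_prior_invariant(self, table, weights):
        priors = dict(zip(table.allele_names, weights))
        for a, b in combinations_with_replacement(table.allele_names, 2):
            from cyp2d6star.simulate import render_sample

            s = render_sample((a, b), table, exon9_policy="render")
            call = call_diplotype(s, table, priors)
            assert call.status == "unique"
            assert call.best_pair == canonical_pair(a, b)


class TestBatch:
    def test_empty_batch(self, table):
        assert call_batch([], table) == []

    def test_isolation_and_order(self, table):
        good = record({"C100T": REF_ALT, "G1846A": REF_REF, "C2850T": REF_ALT, "G4180C": ALT_ALT})
        bad = record(
            {"C100T": REF_ALT, "G1846A": REF_REF, "C2850T": REF_REF, "G4180C": REF_ALT},
            deletion_band=True, sample_id="BAD",
        )
        calls = call_batch([good, bad, good], table)
        assert [c.status for c in calls] == ["unique", "inconsistent", "unique"]
        assert calls[1].sample_id == "BAD"
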