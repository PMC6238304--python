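import math

import pytest

from cyp2d6star import (
    call_batch,
    compare_populations,
    hwe_exact,
    load_population_panel,
    reduced_function_fraction,
    render_sample,
    summarize_cohort,
)
from cyp2d6star.caller import call_diplotype
from cyp2d6star.popstats import marker_frequencies
from oracles import hwe_exact_oracle


class TestSummarize:
    def test_single_reference_sample(self, table):
        call = call_diplotype(render_sample(("*1", "*1"), table), table)
        s = summarize_cohort([call], table)
        assert s.allele_freqs == {"*1": 1.0}
        assert all(f == 0 for f in s.derived_snp_freqs.values())
        assert s.function_burden["normal"] == 1.0

    def test_empty_cohort_is_an_error(self, table):
        with pytest.raises(ValueError):
            summarize_cohort([], table)

    def test_conservation(self, table, karen_summary):
        s = karen_summary
        assert sum(s.allele_counts.values()) == 2 * s.n_samples
        assert sum(s.diplotype_counts.values()) == s.n_samples
        assert math.isclose(sum(s.allele_freqs.values()), 1.0, abs_tol=1e-12)

    def test_snp_freqs_agree_between_diplotype_and_allele_routes(self, table, karen_summary):
        s = karen_summary
        for vid in table.variants:
            via_diplotypes = sum(
                f * (table.allele(a).carries(vid) + table.allele(b).carries(vid))
                for (a, b), f in s.diplotype_freqs.items()
            ) / 2.0
            assert math.isclose(via_diplotypes, s.derived_snp_freqs[vid], abs_tol=1e-12)

    def test_non_unique_calls_are_excluded_not_imputed(self, table):
        unique = call_diplotype(render_sample(("*2", "*10"), table), table)
        from cyp2d6star.caller import MISSING, SampleRecord

        vague = call_diplotype(
            SampleRecord(
                "V",
                {"C100T": "alt_alt", "G1846A": MISSING, "C2850T": "ref_ref", "G4180C": "alt_alt"},
            ),
            table,
        )
        s = summarize_cohort([unique, vague], table)
        assert s.n_samples == 1
        assert s.n_excluded == 1

    def test_mean_activity_score(self, table):
        calls = [
            call_diplotype(render_sample(p, table), table)
            for p in [("*1", "*1"), ("*10", "*10"), ("*4", "*5")]
        ]
        s = summarize_cohort(calls, table)
        assert math.isclose(s.mean_activity_score, (2.0 + 1.0 + 0.0) / 3)


class TestReducedFunction:
    def test_all_classes_sum_to_one(self, karen_summary):
        assert math.isclose(
            reduced_function_fraction(karen_summary, {"normal", "decreased", "none"}), 1.0
        )

    def test_null_alleles_only(self, karen_summary):
        assert math.isclose(reduced_function_fraction(karen_summary, {"none"}), 7 / 140)

    def test_unknown_class_rejected(self, karen_summary):
        with pytest.raises(ValueError):
            reduced_function_fraction(karen_summary, {"super"})


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact(1, 0, 0) == 1.0

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            hwe_exact(0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 2, 0)

    def test_balanced_large_sample_is_maximally_consistent(self):
        assert hwe_exact(25, 50, 25) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n_het", [0, 2])
    def test_two_by_two_enumeration(self, n_het):
        hom = (2 - n_het) // 2
        assert hwe_exact(hom, n_het, hom) == pytest.approx(
            hwe_exact_oracle(hom, n_het, hom), abs=1e-12
        )

    def test_matches_full_enumeration_up_to_twenty_alleles(self):
        """Exhaustive agreement with the pairing-enumeration oracle, 2n <= 20."""
        for n in range(1, 8):  # all genotype configurations with n samples
            for n_ref_hom in range(n + 1):
                for n_het in range(n - n_ref_hom + 1):
                    n_alt_hom = n - n_ref_hom - n_het
                    expected = hwe_exact_oracle(n_ref_hom, n_het, n_alt_hom)
                    assert hwe_exact(n_ref_hom, n_het, n_alt_hom) == pytest.approx(
                        expected, abs=1e-9
                    ), (n_ref_hom, n_het, n_alt_hom)
        for counts in [(3, 4, 3), (0, 10, 0), (8, 1, 1), (1, 8, 1), (5, 0, 5)]:
            assert hwe_exact(*counts) == pytest.approx(
                hwe_exact_oracle(*counts), abs=1e-9
            ), counts


class TestComparePopulations:
    def test_self_comparison_is_zero(self, table, karen_summary):
        from cyp2d6star.popstats import PopulationPanel
        import pandas as pd

        row = {"population": "self", **marker_frequencies(karen_summary, table)}
        panel = PopulationPanel(pd.DataFrame([row]))
        out = compare_populations(karen_summary, panel, table=table)
        assert out["divergence"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_karen_marker_convention(self, table, karen_summary):
        markers = marker_frequencies(karen_summary, table)
        # marker columns hold the defining allele's frequency, not the SNP's
        assert markers["C100T"] == pytest.approx(56 / 140)
        assert markers["C2850T"] == pytest.approx(46 / 140)
        assert markers["deletion"] == pytest.approx(4 / 140)
        assert markers["G4180C"] == pytest.approx(106 / 140)

    def test_karen_versus_south_india(self, table, karen_summary):
        panel = load_population_panel()
        out = compare_populations(karen_summary, panel, variants=("C100T",), table=table)
        row = out[out.population == "South India 2006"].iloc[0]
        assert row["d_C100T"] == pytest.approx(0.30, abs=0.005)

    def test_nearest_populations_are_asian(self, table, karen_summary):
        panel = load_population_panel()
        out = compare_populations(karen_summary, panel, table=table)
        others = out[out.population != "Karen (current study)"]
        assert list(others["group"].iloc[:3]) == ["Asian", "Asian", "Asian"]
        # the published same-cohort row itself sits at the top
        assert out["population"].iloc[0] == "Karen (current study)"

    def test_undetermined_markers_are_excluded_per_row(self, table, karen_summary):
        panel = load_population_panel()
        out = compare_populations(
            karen_summary, panel, variants=("C100T", "G1846A", "C2850T"), table=table
        )
        viet = out[out.population == "Vietnamese 2010"].iloc[0]
        assert math.isnan(viet["d_G1846A"])  # that study did not type the splice defect
        assert viet["n_markers"] == 2

    def test_missing_marker_in_panel_raises(self, table, karen_summary):
        panel = load_population_panel()
        with pytest.raises(KeyError):
            compare_populations(karen_summary, panel, variants=("XYZ",), table=table)
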