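"""Variant tables, minimal mixtures, degenerate unions, suggested fixes."""

import numpy as np
import pandas as pd
import pytest

from primerscope import iupac
from primerscope.design import (
    compare_mixture_vs_degenerate,
    degenerate_union,
    design_mixture,
    suggest_degeneracies,
    tabulate_variants,
)
from primerscope.primers import DegeneratePrimer

from conftest import make_fragment

P = DegeneratePrimer("p", "ACGTACGTAC", "forward")


def frags_of(variant_counts, sample="S01", primer="p"):
    out = []
    i = 0
    for variant, n in variant_counts.items():
        for _ in range(n):
            out.append(make_fragment(variant, sample=sample, primer=primer,
                                     read_id=f"{sample}-r{i}"))
            i += 1
    return out


class TestTabulateVariants:
    def test_three_variants_70_20_10(self):
        v1, v2, v3 = "ACGTACGTAC", "TCGTACGTAC", "GGGTACGTAC"
        t = tabulate_variants(frags_of({v1: 70, v2: 20, v3: 10}), P)
        assert list(t["variant"]) == [v1, v2, v3]
        assert list(t["overall_abundance"]) == pytest.approx([0.7, 0.2, 0.1])
        assert list(t["matched"]) == [True, False, False]

    def test_single_variant(self):
        t = tabulate_variants(frags_of({"ACGTACGTAC": 42}), P)
        assert len(t) == 1
        assert t["overall_abundance"].iloc[0] == pytest.approx(1.0)

    def test_per_dataset_frequencies_sum_to_one(self):
        frags = (frags_of({"ACGTACGTAC": 30, "TCGTACGTAC": 10}, "S01")
                 + frags_of({"ACGTACGTAC": 5, "GGGTACGTAC": 15}, "S02"))
        t = tabulate_variants(frags, P)
        assert t["freq_S01"].sum() == pytest.approx(1.0)
        assert t["freq_S02"].sum() == pytest.approx(1.0)
        # overall = unweighted mean of per-dataset frequencies
        row = t[t["variant"] == "ACGTACGTAC"].iloc[0]
        assert row["overall_abundance"] == pytest.approx((0.75 + 0.25) / 2)

    def test_planted_three_dataset_truth(self):
        planted = {
            "S01": {"ACGTACGTAC": 60, "TCGTACGTAC": 40},
            "S02": {"ACGTACGTAC": 80, "GGGTACGTAC": 20},
            "S03": {"ACGTACGTAC": 50, "TCGTACGTAC": 25, "GGGTACGTAC": 25},
        }
        frags = [f for s, vc in planted.items() for f in frags_of(vc, s)]
        t = tabulate_variants(frags, P)
        for s, vc in planted.items():
            total = sum(vc.values())
            for v, n in vc.items():
                got = t.loc[t["variant"] == v, f"freq_{s}"].iloc[0]
                assert got == pytest.approx(n / total)

    def test_reverse_primer_variants_in_synthesis_orientation(self):
        rev = DegeneratePrimer("r", "GTACGTACGT", "reverse")
        # fragment in reference orientation = revcomp of the primer
        frag = make_fragment(iupac.reverse_complement(rev.sequence),
                             primer="r")
        t = tabulate_variants([frag], rev)
        assert t["variant"].iloc[0] == rev.sequence
        assert bool(t["matched"].iloc[0])

    def test_rare_tail_flagged_not_dropped(self):
        t = tabulate_variants(frags_of({"ACGTACGTAC": 99, "TTTTACGTAC": 1}), P)
        assert bool(t.loc[t["variant"] == "TTTTACGTAC",
                          "possible_error"].iloc[0])
        assert len(t) == 2


class TestDesignMixture:
    def test_single_variant_trivial(self):
        t = tabulate_variants(frags_of({"ACGTACGTAC": 10}), P)
        d = design_mixture(t, "p", seed="ACGTACGTAC")
        assert list(d.oligos) == ["ACGTACGTAC"]
        assert d.overall_coverage == pytest.approx(1.0)

    def test_all_above_threshold_included(self):
        v1, v2, v3 = "ACGTACGTAC", "TCGTACGTAC", "GGGTACGTAC"
        t = tabulate_variants(frags_of({v1: 60, v2: 35, v3: 5}), P)
        d = design_mixture(t, "p", seed=v1, abundance_threshold=0.02)
        assert set(d.oligos) == {v1, v2, v3}
        assert d.overall_coverage == pytest.approx(1.0)

    def test_threshold_one_returns_seed_and_curated_only(self):
        t = tabulate_variants(frags_of({"ACGTACGTAC": 60,
                                        "TCGTACGTAC": 40}), P)
        d = design_mixture(t, "p", seed="ACGTACGTAC", abundance_threshold=1.0,
                           must_include=["GGGGACGTAC"])
        assert set(d.oligos) == {"ACGTACGTAC", "GGGGACGTAC"}
        assert d.justification["GGGGACGTAC"] == "curated"

    def test_tiny_threshold_returns_every_observed_variant(self):
        counts = {"ACGTACGTAC": 50, "TCGTACGTAC": 30, "GGGTACGTAC": 15,
                  "TTTTACGTAC": 5}
        t = tabulate_variants(frags_of(counts), P)
        d = design_mixture(t, "p", abundance_threshold=1e-9)
        assert set(d.oligos) == set(counts)

    def test_coverage_conservation(self):
        counts = {"ACGTACGTAC": 70, "TCGTACGTAC": 20, "GGGTACGTAC": 7,
                  "TTTTACGTAC": 3}
        t = tabulate_variants(frags_of(counts), P)
        d = design_mixture(t, "p", abundance_threshold=0.05)
        excluded = t[~t["variant"].isin(set(d.oligos))]
        assert d.overall_coverage == pytest.approx(
            1.0 - excluded["overall_abundance"].sum()
        )

    def test_coverage_nondecreasing_in_mixture_size(self):
        counts = {"ACGTACGTAC": 50, "TCGTACGTAC": 30, "GGGTACGTAC": 15,
                  "TTTTACGTAC": 5}
        t = tabulate_variants(frags_of(counts), P)
        covs = [
            design_mixture(t, "p", abundance_threshold=th).overall_coverage
            for th in (0.4, 0.2, 0.1, 0.01)
        ]
        assert covs == sorted(covs)

    def test_union_covers_all_members(self):
        counts = {"ACGTACGTAC": 50, "TCTTACGTAC": 30, "GCGAACGTAC": 20}
        t = tabulate_variants(frags_of(counts), P)
        d = design_mixture(t, "p", abundance_threshold=0.01)
        assert set(d.oligos) <= set(
            iupac.expand(d.degenerate_union, cap=10**6)
        )
        assert d.n_oligos <= d.union_degeneracy

    def test_seed_defaults_to_top_matched_variant(self):
        t = tabulate_variants(frags_of({"TCGTACGTAC": 60,
                                        "ACGTACGTAC": 40}), P)
        d = design_mixture(t, "p", abundance_threshold=0.9)
        assert d.seed == "ACGTACGTAC"  # matched beats more-abundant unmatched

    def test_length_incompatible_curated_oligo_rejected(self):
        t = tabulate_variants(frags_of({"ACGTACGTAC": 10}), P)
        with pytest.raises(ValueError, match="length"):
            design_mixture(t, "p", must_include=["ACGT"])


class TestDegenerateUnion:
    def test_two_oligos_three_two_way_positions(self):
        # differ at 3 positions with 2 alternatives each -> degeneracy 8
        u = degenerate_union(["AAACGTACGT", "TCCCGTACGT"])
        assert iupac.degeneracy(u) == 8

    def test_acg_atc_union(self):
        assert degenerate_union(["ACG", "ATC"]) == "AYS"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            degenerate_union(["ACG", "ACGT"])


class TestCompareMixture:
    def test_two_member_single_position(self):
        t = tabulate_variants(frags_of({"ACGTACGTAC": 60,
                                        "AGGTACGTAC": 40}), P)
        d = design_mixture(t, "p", abundance_threshold=0.01)
        rep = compare_mixture_vs_degenerate(d, t)
        assert rep["union_degeneracy"] == 2
        assert rep["n_redundant_oligos"] == 0

    def test_redundancy_counts_unobserved_expansions(self):
        t = tabulate_variants(frags_of({"ACG": 60, "ATC": 40},
                                       primer="p3"),
                              DegeneratePrimer("p3", "ACG", "forward"))
        d = design_mixture(t, "p3", abundance_threshold=0.01)
        rep = compare_mixture_vs_degenerate(d, t)
        assert rep["union_degeneracy"] == 4
        assert rep["n_redundant_oligos"] == 2

    def test_high_redundancy_scenario(self):
        # three oligos pairwise-different at many positions: the union
        # explodes while the mixture stays at 3
        oligos = {"ACGTACGTAC": 50, "TGCAACGTAC": 30, "CAATACGTAC": 20}
        t = tabulate_variants(frags_of(oligos), P)
        d = design_mixture(t, "p", abundance_threshold=0.01)
        rep = compare_mixture_vs_degenerate(d, t)
        assert rep["degeneracy_ratio"] >= 9


class TestSuggestDegeneracies:
    P785 = DegeneratePrimer("785R-like", "GACTACHVGGGTATCTAATCC", "forward")

    @staticmethod
    def table(rows):
        """rows: (variant, overall_abundance); matched computed vs P785."""
        df = pd.DataFrame(rows, columns=["variant", "overall_abundance"])
        df["n_mismatches"] = [
            iupac.count_mismatches(TestSuggestDegeneracies.P785.sequence, v)
            for v in df["variant"]
        ]
        df["matched"] = df["n_mismatches"] == 0
        df["freq_S01"] = df["overall_abundance"]
        return df

    def test_single_mismatch_dominant_variant_fixed_at_position_7(self):
        perfect = iupac.expand("GACTACHVGGGTATCTAATCC")[0]
        # SAR11-style variant: G at position 7 where H = {A,C,T}
        variant = perfect[:6] + "G" + perfect[7:]
        t = self.table([(perfect, 0.6), (variant, 0.4)])
        out = suggest_degeneracies(t, self.P785)
        top = out.iloc[0]
        assert top["position"] == 7
        assert top["old_code"] == "H"
        assert top["new_code"] == "N"
        assert top["new_degeneracy"] == 12
        assert top["abundance_gained"] == pytest.approx(0.4)

    def test_fully_matched_table_gives_no_suggestions(self):
        perfect = iupac.expand("GACTACHVGGGTATCTAATCC")[0]
        out = suggest_degeneracies(self.table([(perfect, 1.0)]), self.P785)
        assert out.empty

    def test_ranking_by_abundance_gained(self):
        perfect = iupac.expand("GACTACHVGGGTATCTAATCC")[0]
        v_pos7 = perfect[:6] + "G" + perfect[7:]          # gain 0.3
        v_pos1 = "T" + perfect[1:]                         # gain 0.1
        t = self.table([(perfect, 0.6), (v_pos7, 0.3), (v_pos1, 0.1)])
        out = suggest_degeneracies(t, self.P785)
        assert list(out["position"][:2]) == [7, 1]
        assert list(out["abundance_gained"][:2]) == pytest.approx([0.3, 0.1])

    def test_top_edit_gain_verified_by_recompute(self):
        perfect = iupac.expand("GACTACHVGGGTATCTAATCC")[0]
        v = perfect[:6] + "G" + perfect[7:]
        t = self.table([(perfect, 0.7), (v, 0.3)])
        top = suggest_degeneracies(t, self.P785).iloc[0]
        pos = int(top["position"]) - 1
        widened = (self.P785.sequence[:pos] + top["new_code"]
                   + self.P785.sequence[pos + 1:])

        def matched_abundance(primer_seq):
            return sum(
                row["overall_abundance"]
                for _, row in t.iterrows()
                if iupac.count_mismatches(primer_seq, row["variant"]) == 0
            )

        gain = matched_abundance(widened) - matched_abundance(
            self.P785.sequence)
        assert gain == pytest.approx(top["abundance_gained"])
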