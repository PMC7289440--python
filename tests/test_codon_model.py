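"""Codon counting, decoding weights, CBI/tAI and construct comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from codonlab import codon_model as cm
from codonlab.genetic_code import (
    ADAT_FAMILIES,
    CODON_TO_AA,
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
)


# ---------------------------------------------------------------------------
# count_codons
# ---------------------------------------------------------------------------

class TestCountCodons:
    def test_two_sense_codons_terminal_stop_dropped(self):
        table = cm.count_codons("ATGGCCTAA")
        assert table.counts["ATG"] == 1
        assert table.counts["GCC"] == 1
        assert table.total == 2

    def test_empty_sequence_gives_zero_table(self):
        table = cm.count_codons("")
        assert table.total == 0
        assert table.freq_per_thousand.isna().all()

    def test_matches_sliding_triplet_tally_oracle(self, rng):
        sense = [c for c in SENSE_CODONS]
        seq = "".join(sense[i] for i in rng.integers(0, len(sense), 300))
        table = cm.count_codons(seq)
        # independent oracle: stride-3 substring tally
        oracle: dict[str, int] = {}
        for i in range(0, len(seq), 3):
            oracle[seq[i:i + 3]] = oracle.get(seq[i:i + 3], 0) + 1
        for codon in SENSE_CODONS:
            assert table.counts[codon] == oracle.get(codon, 0)

    def test_freq_per_thousand_sums_to_1000(self, rng):
        sense = [c for c in SENSE_CODONS]
        seq = "".join(sense[i] for i in rng.integers(0, len(sense), 200))
        table = cm.count_codons(seq)
        assert table.freq_per_thousand.sum() == pytest.approx(1000, abs=1e-6)

    @pytest.mark.parametrize(
        "seq,err",
        [
            ("ATGNCCTAA", cm.InvalidSequenceError),
            ("ATGC", cm.FrameError),
            ("ATGTAAGCC", cm.InvalidSequenceError),  # internal stop
        ],
    )
    def test_rejects_malformed_sequences(self, seq, err):
        with pytest.raises(err):
            cm.count_codons(seq)


# ---------------------------------------------------------------------------
# family_relative_values
# ---------------------------------------------------------------------------

class TestFamilyRelativeValues:
    def test_pool_fraction_ratio_arithmetic(self):
        pool = cm.TRNAPool.from_records(
            [("A", "AGC", 10), ("A", "CGC", 0), ("A", "UGC", 5)]
        )
        frac = cm.family_relative_values(pool)
        assert frac.loc["Ala", "AGC"] == pytest.approx(10 / 15)
        assert frac.loc["Ala", "UGC"] == pytest.approx(5 / 15)

    def test_single_member_family_is_one(self):
        pool = cm.TRNAPool.from_records([("A", "AGC", 3)])
        frac = cm.family_relative_values(pool)
        assert frac.loc["Ala", "AGC"] == 1.0

    def test_zero_total_family_is_nan_not_zero(self):
        pool = cm.TRNAPool.from_records([("A", "AGC", 0), ("R", "ACG", 4)])
        frac = cm.family_relative_values(pool)
        assert np.isnan(frac.loc["Ala"].dropna().sum()) or frac.loc["Ala"].isna().all()
        assert frac.loc["Arg", "ACG"] == 1.0

    def test_rows_sum_to_one_for_nonempty_families(self, rng):
        records = []
        for fam in ADAT_FAMILIES.values():
            records.append((fam["aa"], fam["anticodon"], int(rng.integers(1, 20))))
            # add the GNN anticodon of the same box
            gnn = "G" + fam["anticodon"][1:]
            records.append((fam["aa"], gnn, int(rng.integers(1, 20))))
        pool = cm.TRNAPool.from_records(records)
        frac = cm.family_relative_values(pool)
        sums = frac.sum(axis=1, skipna=True)
        assert np.allclose(sums.to_numpy(), 1.0)
        # hand-summed check for one family
        ala = [r for r in records if r[0] == "A"]
        total = sum(r[2] for r in ala)
        agc = sum(r[2] for r in ala if r[1] == "AGC")
        assert frac.loc["Ala", "AGC"] == pytest.approx(agc / total)

    def test_usage_table_fractions(self):
        counts = pd.Series(0, index=list(SENSE_CODONS))
        counts["GCC"], counts["GCT"], counts["GCA"], counts["GCG"] = 6, 2, 1, 1
        frac = cm.family_relative_values(cm.CodonUsageTable(counts))
        assert frac.loc["Ala", "GCC"] == pytest.approx(0.6)
        assert frac.loc["Ala"].sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# decoding weights and wobble rules
# ---------------------------------------------------------------------------

def brute_force_weights(pool, rules):
    """Enumeration oracle: try every anticodon against every sense codon."""
    from codonlab.genetic_code import RNA_COMPLEMENT, dna_to_rna

    weights = {c: 0.0 for c in SENSE_CODONS}
    for entry in pool.entries:
        base34 = entry.anticodon[0]
        eligible = any(
            f["anticodon"] == entry.anticodon and f["aa"] == entry.amino_acid
            for f in ADAT_FAMILIES.values()
        )
        if rules.include_i34 and eligible:
            base34 = "I"
        for codon in SENSE_CODONS:
            if CODON_TO_AA[codon] != entry.amino_acid:
                continue
            rna = dna_to_rna(codon)
            if RNA_COMPLEMENT[rna[0]] != entry.anticodon[2]:
                continue
            if RNA_COMPLEMENT[rna[1]] != entry.anticodon[1]:
                continue
            w = rules.pairings.get((base34, codon[2]))
            if w is not None:
                weights[codon] += w * entry.gene_copy_number
    return pd.Series(weights)


class TestDecodingWeights:
    def test_i34_expands_arg_acg_to_c_u_a_codons(self):
        # inosine at position 34 wobble-pairs with C, U and A
        pool = cm.TRNAPool.from_records([("R", "ACG", 5)])
        w = cm.decoding_weights(pool, cm.WobbleRuleSet.default(include_i34=True))
        assert w["CGC"] > 0
        assert w["CGT"] > 0
        assert w["CGA"] > 0
        assert w["CGG"] == 0

    def test_without_i34_a34_reads_only_u3(self):
        pool = cm.TRNAPool.from_records([("R", "ACG", 5)])
        w = cm.decoding_weights(pool, cm.WobbleRuleSet.default(include_i34=False))
        assert w["CGC"] == 0
        assert w["CGT"] == 5.0

    def test_matches_enumeration_oracle_on_toy_pool(self):
        pool = cm.TRNAPool.from_records(
            [("A", "AGC", 7), ("A", "GGC", 3), ("K", "UUU", 4)]
        )
        for include_i34 in (True, False):
            rules = cm.WobbleRuleSet.default(include_i34=include_i34)
            got = cm.decoding_weights(pool, rules)
            want = brute_force_weights(pool, rules)
            pd.testing.assert_series_equal(got, want, check_names=False)

    def test_without_i34_is_lower_bound_on_nnc_weights(self, rng):
        records = [
            (f["aa"], f["anticodon"], int(rng.integers(1, 15)))
            for f in ADAT_FAMILIES.values()
        ]
        pool = cm.TRNAPool.from_records(records)
        w_on = cm.decoding_weights(pool, cm.WobbleRuleSet.default(include_i34=True))
        w_off = cm.decoding_weights(pool, cm.WobbleRuleSet.default(include_i34=False))
        for fam in ADAT_FAMILIES.values():
            assert w_off[fam["nnc"]] <= w_on[fam["nnc"]]
            # no GNN cognate in this pool, so strictly lower
            assert w_off[fam["nnc"]] < w_on[fam["nnc"]]

    def test_partial_editing_interpolates(self):
        pool = cm.TRNAPool.from_records([("R", "ACG", 10)])
        rules = cm.WobbleRuleSet.default(include_i34=True)
        full = cm.decoding_weights(pool, rules)
        half = cm.decoding_weights(pool, rules, editing={"ACG": 0.5})
        none = cm.decoding_weights(pool, rules, editing={"ACG": 0.0})
        assert half["CGC"] == pytest.approx(0.5 * full["CGC"])
        assert none["CGC"] == 0.0
        # the A34 complement keeps reading CGU
        assert half["CGT"] == pytest.approx(0.5 * full["CGT"] + 0.5 * 10.0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            cm.decoding_weights(cm.TRNAPool([]), cm.WobbleRuleSet.default())


class TestPoolUsageCorrelation:
    def test_proportional_weights_give_r_one(self):
        counts = pd.Series(0, index=list(SENSE_CODONS))
        weights = pd.Series(0.0, index=list(SENSE_CODONS))
        for i, codon in enumerate(["GCC", "GCT", "CGC", "AAA"]):
            counts[codon] = 10 * (i + 1)
            weights[codon] = float(i + 1)
        r = cm.pool_usage_correlation(weights, cm.CodonUsageTable(counts))
        assert r == pytest.approx(1.0)

    def test_matches_closed_form_pearson_on_toy(self):
        codons = ["GCC", "GCT", "CGC", "AAA"]
        counts = pd.Series(0, index=list(SENSE_CODONS))
        weights = pd.Series(0.0, index=list(SENSE_CODONS))
        usage_vals = [40, 30, 20, 10]
        weight_vals = [1.0, 2.0, 3.0, 4.0]  # reversed ranking
        for c, u, w in zip(codons, usage_vals, weight_vals):
            counts[c], weights[c] = u, w
        r = cm.pool_usage_correlation(weights, cm.CodonUsageTable(counts))
        # closed-form Pearson computed by hand
        x, y = np.array(weight_vals), np.array(usage_vals, float)
        y = y / y.sum() * 1000
        hand = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert r == pytest.approx(hand, abs=1e-12)
        assert r == pytest.approx(-1.0)

    def test_brute_force_equivalence_random_inputs(self, rng):
        for _ in range(5):
            weights = pd.Series(rng.random(61), index=list(SENSE_CODONS))
            counts = pd.Series(rng.integers(1, 100, 61), index=list(SENSE_CODONS))
            usage = cm.CodonUsageTable(counts)
            r = cm.pool_usage_correlation(weights, usage)
            x = weights.to_numpy()
            y = usage.freq_per_thousand.to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            brute = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
            assert r == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        counts = pd.Series(1, index=list(SENSE_CODONS))
        weights = pd.Series(1.0, index=list(SENSE_CODONS))
        with pytest.raises(cm.UndefinedStatisticError):
            cm.pool_usage_correlation(weights, cm.CodonUsageTable(counts))


# ---------------------------------------------------------------------------
# CBI / tAI / NNC content
# ---------------------------------------------------------------------------

def _optimal_one_per_aa():
    return frozenset(
        sorted(codons)[0] for codons in SYNONYMOUS_FAMILIES.values() if len(codons) > 1
    )


class TestCBI:
    def test_all_optimal_gene_is_exactly_one(self):
        optimal = _optimal_one_per_aa()
        counts = pd.Series(0, index=list(SENSE_CODONS))
        for c in list(optimal)[:10]:
            counts[c] = 5
        assert cm.cbi(counts, optimal) == 1.0

    def test_uniform_synonymous_usage_is_zero(self):
        optimal = _optimal_one_per_aa()
        counts = pd.Series(0, index=list(SENSE_CODONS))
        for codons in SYNONYMOUS_FAMILIES.values():
            if len(codons) > 1:
                for c in codons:
                    counts[c] = 7
        assert cm.cbi(counts, optimal) == pytest.approx(0.0, abs=1e-9)

    def test_lysine_toy_matches_hand_formula(self):
        # Lys AAA/AAG counts 3/1, optimal AAG:
        # N_opt=1, N_tot=4, N_ran=4/2=2 -> (1-2)/(4-2) = -0.5
        optimal = frozenset(
            {"AAG"} | {c for c in _optimal_one_per_aa() if CODON_TO_AA[c] != "K"}
        )
        counts = pd.Series(0, index=list(SENSE_CODONS))
        counts["AAA"], counts["AAG"] = 3, 1
        assert cm.cbi(counts, optimal) == pytest.approx(-0.5)

    def test_met_trp_only_gene_is_undefined(self):
        counts = pd.Series(0, index=list(SENSE_CODONS))
        counts["ATG"], counts["TGG"] = 3, 2
        assert math.isnan(cm.cbi(counts, _optimal_one_per_aa()))

    def test_optimal_set_from_usage_is_most_frequent(self):
        counts = pd.Series(1, index=list(SENSE_CODONS))
        counts["GCG"] = 50
        optimal = cm.optimal_codons_from_usage(cm.CodonUsageTable(counts))
        assert "GCG" in optimal
        # one codon per multi-codon amino acid
        n_multi = sum(1 for c in SYNONYMOUS_FAMILIES.values() if len(c) > 1)
        assert len(optimal) == n_multi


class TestTAI:
    def test_uniform_adaptiveness_gives_one(self):
        counts = pd.Series(0, index=list(SENSE_CODONS))
        counts["GCC"], counts["AAA"] = 5, 5
        weights = pd.Series(0.0, index=list(SENSE_CODONS))
        weights["GCC"] = weights["AAA"] = 2.0
        assert cm.tai(counts, weights) == pytest.approx(1.0)

    def test_geometric_mean_of_two_codons(self):
        counts = pd.Series(0, index=list(SENSE_CODONS))
        counts["GCC"], counts["AAA"] = 1, 1
        weights = pd.Series(0.0, index=list(SENSE_CODONS))
        weights["GCC"], weights["AAA"] = 0.25, 1.0
        assert cm.tai(counts, weights) == pytest.approx(0.5)

    def test_matches_log_domain_oracle(self, rng):
        codons = list(rng.choice(list(SENSE_CODONS), 10, replace=False))
        counts = pd.Series(0, index=list(SENSE_CODONS))
        weights = pd.Series(0.0, index=list(SENSE_CODONS))
        w_vals = rng.uniform(0.1, 1.0, 10)
        for c, w in zip(codons, w_vals):
            counts[c] = int(rng.integers(1, 5))
            weights[c] = w
        got = cm.tai(counts, weights)
        rel = w_vals / w_vals.max()
        logs = []
        for c, r in zip(codons, rel):
            logs += [math.log(r)] * int(counts[c])
        assert got == pytest.approx(math.exp(sum(logs) / len(logs)), abs=1e-12)

    def test_doubling_multiplicity_closed_form(self):
        counts = pd.Series(0, index=list(SENSE_CODONS))
        counts["GCC"], counts["AAA"] = 1, 1
        weights = pd.Series(0.0, index=list(SENSE_CODONS))
        weights["GCC"], weights["AAA"] = 0.25, 1.0
        doubled = counts.copy()
        doubled["GCC"] = 2
        # geometric mean: (0.25^2 * 1)^(1/3)
        assert cm.tai(doubled, weights) == pytest.approx((0.25 ** 2) ** (1 / 3))

    def test_zero_weight_codon_floored_not_collapsed(self):
        counts = pd.Series(0, index=list(SENSE_CODONS))
        counts["GCC"], counts["AAA"] = 1, 1
        weights = pd.Series(0.0, index=list(SENSE_CODONS))
        weights["AAA"] = 1.0
        got = cm.tai(counts, weights, zero_weight_floor=1e-4)
        assert got == pytest.approx(math.sqrt(1e-4))
        assert got > 0

    def test_empty_orf_rejected(self):
        with pytest.raises(ValueError):
            cm.tai(pd.Series(0, index=list(SENSE_CODONS)), pd.Series(1.0, index=list(SENSE_CODONS)))


class TestAdatNncContent:
    def test_two_of_ten_codons(self):
        seq = "GCC" + "TCC" + "AAA" * 8
        assert cm.adat_nnc_content(cm.count_codons(seq)) == pytest.approx(0.2)

    def test_no_nnc_codons_is_zero(self):
        assert cm.adat_nnc_content(cm.count_codons("AAA" * 10)) == 0.0

    def test_matches_set_membership_oracle(self, rng):
        from codonlab.genetic_code import ADAT_NNC_CODONS

        sense = list(SENSE_CODONS)
        codons = [sense[i] for i in rng.integers(0, len(sense), 500)]
        counts = cm.count_codons("".join(codons)).counts
        want = sum(1 for c in codons if c in ADAT_NNC_CODONS) / 500
        assert cm.adat_nnc_content(counts) == pytest.approx(want, abs=1e-12)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            cm.adat_nnc_content(pd.Series(0, index=list(SENSE_CODONS)))


# ---------------------------------------------------------------------------
# ORF comparison
# ---------------------------------------------------------------------------

class TestCompareOrfCodons:
    def test_identical_orfs_zero_changes(self):
        assert cm.compare_orf_codons("GCCGCC", "GCCGCC").n_changed == 0

    def test_single_nnc_to_nnt_swap(self):
        cmp = cm.compare_orf_codons("GCCGCC", "GCTGCC", mode="adat_nnc_to_nnt")
        assert cmp.n_changed == 1

    def test_synonymous_but_not_nnc_change_not_counted_in_nnc_mode(self):
        # GCA -> GCG is synonymous but not an NNC->NNU swap
        cmp = cm.compare_orf_codons("GCAGCC", "GCGGCC", mode="adat_nnc_to_nnt")
        assert cmp.n_changed == 0
        assert cm.compare_orf_codons("GCAGCC", "GCGGCC", mode="all").n_changed == 1

    def test_non_synonymous_difference_reported_as_violation(self):
        cmp = cm.compare_orf_codons("GCCAAA", "GCCCGC")
        assert cmp.n_changed == 0
        assert cmp.violations == [(2, "AAA", "CGC")]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cm.compare_orf_codons("GCC", "GCCGCC")

    def test_recovers_generator_truth_on_reporter_trio(self, rng):
        from codonlab.synthetic_data import make_reporter_trio

        wt, opt, c2t, truth = make_reporter_trio(rng, n_codons=550)
        assert cm.compare_orf_codons(wt, opt, mode="all").n_changed == truth["n_optimized"]
        assert (
            cm.compare_orf_codons(opt, c2t, mode="adat_nnc_to_nnt").n_changed
            == truth["n_nnc_to_nnt"]
        )
        assert not cm.compare_orf_codons(wt, opt).violations
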