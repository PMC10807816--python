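import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prshift import (
    MSA,
    ShiftDifferenceRecord,
    classify_by_diagnostic,
    conservation_scatter,
    correlate_shift_conservation,
    entropy_conservation,
    mi_apc,
    read_alignment_fasta,
    scale_delta,
)
from prshift.constants import MAX_COLUMN_ENTROPY_BITS, gyromagnetic_scale


def msa_from_rows(rows, ids=None, ref=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return MSA(ids=ids, sequences=rows, ref_id=ref or ids[0])


@pytest.fixture
def toy_family():
    """6 green + 6 blue sequences; position 3 is the diagnostic L/Q column."""
    green = ["AALAA", "AALAA", "AALCA", "AALAA", "AALAA", "AALCA"]
    blue = ["AAQAA", "AAQAA", "AAQCA", "AAQAA", "AAQGA", "AAQCA"]
    ids = [f"G{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
    msa = msa_from_rows(green + blue, ids=ids)
    labels = {i: ("green" if i.startswith("G") else "blue") for i in ids}
    return msa, labels


class TestMSA:
    def test_column_map_skips_reference_gaps(self):
        msa = msa_from_rows(["A-CD", "AECD"], ids=["ref", "x"])
        assert msa.column_map == {1: 0, 2: 2, 3: 3}
        with pytest.raises(KeyError, match="not mapped"):
            msa.column_at_position(4)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            msa_from_rows(["AAA", "AA"])

    def test_fasta_round_trip(self, tmp_path, toy_family):
        msa, _ = toy_family
        path = tmp_path / "aln.fasta"
        msa.write_fasta(path)
        back = read_alignment_fasta(path, ref_id=msa.ref_id)
        assert back.ids == msa.ids
        assert back.sequences == msa.sequences


class TestClassification:
    def test_rule_maps_leu_green_gln_blue_gap_unclassified(self):
        msa = msa_from_rows(["AL", "AQ", "A-", "AW"], ids=["g", "b", "gap", "other"])
        labels = classify_by_diagnostic(msa, ref_position=2)
        assert labels == {
            "g": "green",
            "b": "blue",
            "gap": "unclassified",
            "other": "unclassified",
        }

    def test_idempotent_and_order_independent(self, toy_family):
        msa, truth = toy_family
        got = classify_by_diagnostic(msa, ref_position=3)
        assert got == truth
        shuffled = MSA(
            ids=list(reversed(msa.ids)),
            sequences=list(reversed(msa.sequences)),
            ref_id=msa.ref_id,
        )
        got2 = classify_by_diagnostic(shuffled, ref_position=3)
        assert got2 == truth


class TestConservationScatter:
    def test_fully_conserved_column_sits_on_diagonal(self, toy_family):
        msa, labels = toy_family
        prof = conservation_scatter(msa, labels)
        assert prof.loc[1, "p_green"] == 1.0
        assert prof.loc[1, "p_same_in_blue"] == 1.0

    def test_diagnostic_column_at_one_zero(self, toy_family):
        msa, labels = toy_family
        prof = conservation_scatter(msa, labels)
        assert prof.loc[3, "top_residue_green"] == "L"
        assert (prof.loc[3, "p_green"], prof.loc[3, "p_same_in_blue"]) == (1.0, 0.0)
        assert (prof.loc[3, "p_blue"], prof.loc[3, "p_same_in_green"]) == (1.0, 0.0)

    def test_frequency_counting(self):
        # A at 60% in green, 20% in blue
        green = ["A", "A", "A", "C", "D"]
        blue = ["A", "C", "C", "D", "D"]
        ids = [f"g{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        msa = msa_from_rows(green + blue, ids=ids)
        labels = {i: ("green" if i.startswith("g") else "blue") for i in ids}
        prof = conservation_scatter(msa, labels)
        assert prof.loc[1, "top_residue_green"] == "A"
        assert prof.loc[1, "p_green"] == pytest.approx(0.6)
        assert prof.loc[1, "p_same_in_blue"] == pytest.approx(0.2)

    def test_group_frequencies_sum_to_one(self, toy_family):
        msa, labels = toy_family
        rows_g = [i for i, sid in enumerate(msa.ids) if labels[sid] == "green"]
        from prshift.conservation import _column_freqs

        for pos, col in msa.column_map.items():
            freqs, n = _column_freqs(msa.column(col)[rows_g])
            assert sum(freqs.values()) == pytest.approx(1.0)

    def test_empty_group_is_hard_error(self, toy_family):
        msa, labels = toy_family
        all_green = {k: "green" for k in labels}
        with pytest.raises(ValueError, match="nonempty"):
            conservation_scatter(msa, all_green)


class TestEntropy:
    def test_fully_conserved_column(self):
        msa = msa_from_rows(["AA", "AA", "AA"])
        df = entropy_conservation(msa)
        assert df.loc[1, "entropy"] == 0.0
        assert df.loc[1, "conservation"] == pytest.approx(MAX_COLUMN_ENTROPY_BITS)

    def test_uniform_four_state_column_has_two_bits(self):
        msa = msa_from_rows(["A", "C", "D", "E"])
        assert entropy_conservation(msa).loc[1, "entropy"] == pytest.approx(2.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(10)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        cols = ["".join(rng.choice(aa, 8)) for _ in range(30)]
        msa = msa_from_rows(cols)
        df = entropy_conservation(msa)
        for pos in msa.mapped_positions():
            chars = [s[pos - 1] for s in cols]
            freqs = {c: chars.count(c) / len(chars) for c in set(chars)}
            want = -sum(p * math.log2(p) for p in freqs.values())
            assert df.loc[pos, "entropy"] == pytest.approx(want, abs=1e-12)

    def test_all_gap_column_reported_missing(self):
        msa = msa_from_rows(["A-", "A-"], ids=["ref", "x"], ref="x")
        # make reference map both columns
        msa = MSA(ids=["r", "x"], sequences=["AC", "A-"], ref_id="r")
        df = entropy_conservation(msa)
        assert not np.isnan(df.loc[1, "entropy"])


class TestCovariation:
    def test_identical_uniform_four_state_columns_give_two_bits(self):
        rows = [c * 2 for c in "ACDE" * 5]  # 20 sequences, two identical columns
        msa = msa_from_rows(rows)
        cov = mi_apc(msa)
        assert cov.mi[0, 1] == 2.0  # exact

    def test_mi_of_identical_column_equals_its_entropy(self):
        rng = np.random.default_rng(11)
        col = "".join(rng.choice(list("ACDEFGHIK"), 60))
        msa = msa_from_rows([c * 2 for c in col])
        h = entropy_conservation(msa).loc[1, "entropy"]
        assert mi_apc(msa).mi[0, 1] == pytest.approx(h, abs=1e-12)

    def test_constant_column_has_zero_mi(self):
        msa = msa_from_rows(["AC", "AD", "AC", "AE"])
        assert mi_apc(msa).mi[0, 1] == 0.0

    def test_independent_columns_apc_near_zero(self):
        rng = np.random.default_rng(12)
        n = 2000
        cols = [rng.choice(list("ACDE"), n) for _ in range(6)]
        rows = ["".join(c[i] for c in cols) for i in range(n)]
        cov = mi_apc(msa_from_rows(rows))
        off = cov.apc[np.triu_indices(6, 1)]
        # APC strips the finite-sample bias; residuals are ~1e-3 at n=2000
        assert np.max(np.abs(off)) < 0.02

    def test_symmetry_and_nonnegativity(self, toy_family):
        msa, _ = toy_family
        cov = mi_apc(msa)
        assert np.allclose(cov.mi, cov.mi.T)
        assert np.allclose(cov.apc, cov.apc.T)
        assert np.all(cov.mi >= 0)


class TestGyromagneticScaling:
    def test_carbon_is_identity(self):
        rec = ShiftDifferenceRecord((1, "CA"), "13C", 2.0)
        assert scale_delta(rec) == 2.0

    def test_nitrogen_scaling_factor(self):
        # 6.3 ppm × |γ15N|/|γ13C| ≈ 2.540
        assert scale_delta(("15N", 6.3)) == pytest.approx(6.3 * 0.403165, abs=2e-3)
        assert gyromagnetic_scale("15N") == pytest.approx(0.4032, abs=5e-4)

    def test_zero_maps_to_zero(self):
        assert scale_delta(("15N", 0.0)) == 0.0

    def test_unknown_nucleus_is_hard_error(self):
        with pytest.raises(KeyError):
            scale_delta(("31P", 1.0))


class TestCorrelation:
    def test_perfect_monotone_gives_rho_one(self):
        cons = {i: i * 0.4 for i in range(1, 11)}
        deltas = {i: 0.1 * i**2 for i in range(1, 11)}
        res = correlate_shift_conservation(deltas, cons, n_permutations=500, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.p_value < 0.01

    def test_statistic_matches_scipy_spearman(self):
        rng = np.random.default_rng(13)
        cons = pd.Series(rng.uniform(0, 4, 25), index=range(1, 26))
        deltas = pd.Series(rng.normal(0, 1, 25), index=range(1, 26))
        res = correlate_shift_conservation(deltas, cons, n_permutations=100, seed=0)
        want = stats.spearmanr(cons.values, deltas.abs().values).statistic
        assert res.rho == pytest.approx(want, abs=1e-12)

    def test_too_few_matches_is_hard_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            correlate_shift_conservation({1: 0.1, 2: 0.2}, {1: 1.0, 2: 2.0})

    def test_profile_dataframe_accepted(self):
        df = pd.DataFrame(
            {"conservation": [1.0, 2.0, 3.0, 4.0]}, index=[1, 2, 3, 4]
        )
        deltas = {1: 0.1, 2: 0.2, 3: 0.3, 4: 0.4}
        res = correlate_shift_conservation(deltas, df, n_permutations=200, seed=1)
        assert res.rho == pytest.approx(1.0)
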