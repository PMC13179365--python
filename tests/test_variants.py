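import pytest
from hypothesis import given
from hypothesis import strategies as st

from petkit import variants
from petkit.errors import DataError
from petkit.variants import (
    AMINO_ACIDS,
    ChargeModel,
    Mutation,
    VariantSpec,
    apply_mutations,
    net_charge_delta,
    parse_mutation,
)


class TestParseMutation:
    def test_basic(self):
        m = parse_mutation("L93F")
        assert (m.wt_residue, m.position, m.new_residue) == ("L", 93, "F")

    def test_round_trip(self):
        assert str(parse_mutation("E148K")) == "E148K"

    def test_silent_mutation_rejected(self):
        with pytest.raises(DataError, match="silent"):
            parse_mutation("A7A")

    @pytest.mark.parametrize("token", ["", "93F", "L93", "LX3F", "B93F", "L0F", "L-3F"])
    def test_malformed(self, token):
        with pytest.raises(DataError):
            parse_mutation(token)

    @given(
        wt=st.sampled_from(sorted(AMINO_ACIDS)),
        pos=st.integers(min_value=1, max_value=9999),
        new=st.sampled_from(sorted(AMINO_ACIDS)),
    )
    def test_round_trip_property(self, wt, pos, new):
        token = f"{wt}{pos}{new}"
        if wt == new:
            with pytest.raises(DataError):
                parse_mutation(token)
        else:
            assert str(parse_mutation(token)) == token


class TestVariantSpec:
    def test_duplicate_positions_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            VariantSpec.from_tokens("bad", ["L93F", "L93T"])

    def test_round_bounds(self):
        with pytest.raises(DataError):
            VariantSpec.from_tokens("bad", ["L93F"], round=7)


class TestApplyMutations:
    def test_empty_set_identity(self):
        v = VariantSpec("wt", ())
        assert apply_mutations("ALE", v) == "ALE"

    def test_single_substitution(self):
        v = VariantSpec.from_tokens("m", ["L2F"])
        assert apply_mutations("ALE", v) == "AFE"

    def test_wt_mismatch_reports_position(self):
        v = VariantSpec.from_tokens("m", ["K2F"])
        with pytest.raises(DataError, match="expected K at position 2, found L"):
            apply_mutations("ALE", v)

    def test_position_beyond_length(self):
        v = VariantSpec.from_tokens("m", ["L9F"])
        with pytest.raises(DataError, match="beyond sequence length"):
            apply_mutations("ALE", v)

    def test_inverse_round_trip(self):
        v = VariantSpec.from_tokens("m", ["L2F", "E3K"])
        assert apply_mutations(apply_mutations("ALE", v), v.inverse()) == "ALE"

    def test_differs_only_at_mutated_positions(self):
        seq = "ACDEFGHIKL"
        v = VariantSpec.from_tokens("m", ["C2W", "K9R"])
        out = apply_mutations(seq, v)
        diffs = [i + 1 for i, (a, b) in enumerate(zip(seq, out)) if a != b]
        assert diffs == [2, 9]


class TestNetChargeDelta:
    def test_e148k(self):
        # formal charges: E is -1, K is +1, so the swap contributes +2
        assert net_charge_delta(VariantSpec.from_tokens("m", ["E148K"])) == +2

    def test_neutral_pair(self):
        assert net_charge_delta(VariantSpec.from_tokens("m", ["V115T"])) == 0

    def test_r2m2_shifts_minus6_to_minus4(self, variant_table):
        r2m2 = variant_table["R2M2"]
        assert len(r2m2.mutations) == 24
        delta = net_charge_delta(r2m2)
        assert delta == +2
        assert -6 + delta == -4

    def test_additive_over_disjoint_sets(self):
        a = VariantSpec.from_tokens("a", ["E148K", "D196S"])
        b = VariantSpec.from_tokens("b", ["R111T", "N113D"])
        combined = VariantSpec.from_tokens("ab", ["E148K", "D196S", "R111T", "N113D"])
        assert net_charge_delta(combined) == net_charge_delta(a) + net_charge_delta(b)

    def test_reversion_cancels(self, variant_table):
        for name in ("R2M2", "R4M6", "R4M10"):
            v = variant_table[name]
            assert net_charge_delta(v) + net_charge_delta(v.inverse()) == 0

    def test_his_neutral_at_ph8(self):
        assert net_charge_delta(VariantSpec.from_tokens("m", ["H109Y"])) == 0

    def test_charge_model_validation(self):
        with pytest.raises(DataError):
            ChargeModel(charges={"D": -2})


class TestVariantTable:
    def test_known_lineage(self, variant_table):
        assert variant_table["R4M6"].parent == "R3M9"
        assert variant_table["R4M6"].round == 4
        assert len(variant_table["R4M6"].mutations) == 22

    def test_r4m10_extends_r4m6(self, variant_table):
        r4m6 = {str(m) for m in variant_table["R4M6"].mutations}
        r4m10 = {str(m) for m in variant_table["R4M10"].mutations}
        assert r4m10 - r4m6 == {"L93F", "Q95Y"}

    def test_r3_variants_are_reversions_of_r2m2(self, variant_table):
        r2m2 = {str(m) for m in variant_table["R2M2"].mutations}
        r3m9 = {str(m) for m in variant_table["R3M9"].mutations}
        assert r3m9 == r2m2 - {"G155P", "S186A", "S208D"}

    def test_all_entries_parse_and_are_position_disjoint(self, variant_table):
        assert len(variant_table) >= 30
        for spec in variant_table.values():
            positions = [m.position for m in spec.mutations]
            assert len(positions) == len(set(positions))

    def test_salt_bridge_swap_variant(self, variant_table):
        r4m6 = {str(m) for m in variant_table["R4M6"].mutations}
        r4m12 = {str(m) for m in variant_table["R4M12"].mutations}
        assert "E148K" not in r4m12
        assert "D233K" in r4m12
        assert r4m6 - r4m12 == {"E148K"}
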