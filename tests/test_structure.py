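"""MS2 regiochemistry, PLA2 digestion and acyl summary statistics."""

import warnings

import pytest

from memlipid import (
    AcylChain,
    LipidSpecies,
    acyl_summaries,
    assign_sn_positions,
    asymmetry_metrics,
    diagnostic_fragments,
    parse_label,
    pla2_digest,
    species_mass,
)
from memlipid.chemistry import PROTON_MASS, WATER, monoisotopic_mass
from memlipid.quantify import QuantRecord
from memlipid.simulate import gen_ms2

PI_28 = LipidSpecies("PI", "sn_resolved", (AcylChain(18, 0), AcylChain(10, 0)))
WATER_MASS = monoisotopic_mass(WATER)


class TestDiagnosticFragments:
    def test_carboxylate_masses(self):
        frags = diagnostic_fragments(PI_28)
        c18_acid = monoisotopic_mass(AcylChain(18, 0).acid_composition())
        c10_acid = monoisotopic_mass(AcylChain(10, 0).acid_composition())
        assert frags[0]["carboxylate"] == pytest.approx(c18_acid - PROTON_MASS, abs=1e-6)
        assert frags[1]["carboxylate"] == pytest.approx(c10_acid - PROTON_MASS, abs=1e-6)

    def test_acid_loss_mass_conservation(self):
        frags = diagnostic_fragments(PI_28)
        mh = species_mass(PI_28) - PROTON_MASS
        for i, chain in enumerate(PI_28.chains):
            acid = monoisotopic_mass(chain.acid_composition())
            assert frags[i]["acid_loss"] + acid == pytest.approx(mh, abs=1e-9)

    def test_ketene_offset_is_water(self):
        frags = diagnostic_fragments(PI_28)
        for i in (0, 1):
            assert frags[i]["ketene_loss"] - frags[i]["acid_loss"] == pytest.approx(
                WATER_MASS, abs=1e-9
            )

    def test_sum_level_rejected(self):
        with pytest.raises(ValueError, match="resolve chains"):
            diagnostic_fragments(parse_label("PI 28:0"))


class TestSnAssignment:
    def test_planted_regiochemistry_recovered(self):
        spectrum = gen_ms2(PI_28, sn2_factor=8.0)
        res = assign_sn_positions(spectrum, parse_label("PI 28:0"))
        assert res.species.label == "PI 18:0/10:0"
        assert res.confidence == "assigned"
        assert res.sn2_over_sn1_ratio == pytest.approx(8.0)

    def test_equal_losses_ambiguous(self):
        res = assign_sn_positions(gen_ms2(PI_28, sn2_factor=1.0), parse_label("PI 28:0"))
        assert res.confidence == "ambiguous"

    def test_ratio_at_min_ratio_is_assigned(self):
        res = assign_sn_positions(
            gen_ms2(PI_28, sn2_factor=7.0), parse_label("PI 28:0"), min_ratio=7.0
        )
        assert res.confidence == "assigned"

    def test_scale_invariance(self):
        spectrum = gen_ms2(PI_28, sn2_factor=8.0)
        r1 = assign_sn_positions(spectrum, parse_label("PI 28:0"))
        r2 = assign_sn_positions(spectrum.scaled(10.0), parse_label("PI 28:0"))
        assert r1.species == r2.species
        assert r1.sn2_over_sn1_ratio == pytest.approx(r2.sn2_over_sn1_ratio)

    def test_uninformative_spectrum_rejected(self):
        from memlipid import Ms2Spectrum, Peak

        empty = Ms2Spectrum(753.0, (Peak(100.0, 1.0),))
        with pytest.raises(ValueError, match="uninformative"):
            assign_sn_positions(empty, parse_label("PI 28:0"))


class TestPla2Digest:
    def test_flagship_species(self):
        products, profile = pla2_digest([PI_28])
        assert products[0].lyso.label == "LPI 18:0"
        assert products[0].free_fatty_acid == AcylChain(10, 0)
        assert "10:0" not in profile.index  # C10:0 not recovered lipid-bound

    def test_symmetric_species_profile_unchanged(self):
        sym = parse_label("PC 16:0/16:0")
        _, profile = pla2_digest([sym])
        assert list(profile.index) == ["16:0"]

    def test_sn2_c10_fully_removed(self):
        table = [
            (PI_28, 0.6),
            (LipidSpecies("PC", "sn_resolved", (AcylChain(16, 0), AcylChain(10, 0))), 0.4),
        ]
        _, profile = pla2_digest(table)
        assert "10:0" not in profile.index

    def test_mass_conservation(self):
        from memlipid import elemental_composition

        products, _ = pla2_digest([PI_28])
        parent = elemental_composition(PI_28)
        lyso = elemental_composition(products[0].lyso)
        fa = products[0].free_fatty_acid.acid_composition()
        assert lyso + fa == parent + WATER

    def test_lyso_input_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipping"):
            products, _ = pla2_digest([parse_label("LPI 18:0")])
        assert products == []


class TestAsymmetry:
    def test_flagship_pi_28_0(self):
        m = asymmetry_metrics(parse_label("PI 28:0"), sn2_chain=AcylChain(10, 0))
        assert m["chain_diff"] == 8
        assert m["is_asymmetrical"]

    def test_pc_16_18_not_asymmetrical(self):
        m = asymmetry_metrics(parse_label("PC 16:0/18:1"))
        assert m == {"chain_diff": 2, "is_asymmetrical": False}

    def test_26_0_boundary(self):
        m = asymmetry_metrics(parse_label("PI 26:0"), sn2_chain=AcylChain(10, 0))
        assert m == {"chain_diff": 6, "is_asymmetrical": True}

    def test_symmetric_in_chain_order(self):
        a = asymmetry_metrics(parse_label("PI 18:0/10:0"))
        b = asymmetry_metrics(parse_label("PI 10:0/18:0"))
        assert a == b

    def test_undeterminable_rejected(self):
        with pytest.raises(ValueError, match="not determinable"):
            asymmetry_metrics(parse_label("PI 28:0"))


def _record(label, molpct):
    return QuantRecord(parse_label(label), molpct, molpct)


class TestAcylSummaries:
    def test_single_species_average(self):
        summary, _ = acyl_summaries([_record("PI 28:0", 100.0)])
        assert summary.loc["PI", "avg_combined_length"] == pytest.approx(28.0)

    def test_weighted_mean_and_db_distribution(self):
        summary, db = acyl_summaries(
            [_record("PI 28:0", 50.0), _record("PI 36:2", 50.0)]
        )
        assert summary.loc["PI", "avg_combined_length"] == pytest.approx(32.0)
        pcts = dict(zip(db["double_bonds"], db["pct"]))
        assert pcts == {0: pytest.approx(50.0), 2: pytest.approx(50.0)}

    def test_assumed_sn2_asymmetric_fraction(self):
        summary, _ = acyl_summaries(
            [_record("PI 28:0", 90.0), _record("PI 34:1", 10.0)],
            assume_sn2={"PI": AcylChain(10, 0)},
        )
        # 28:0 with sn-2 C10:0 -> diff 8 (asymmetric); 34:1 -> diff 14?  no:
        # 34 - 10 = 24 at sn-1 -> diff 14, also asymmetric under the blanket
        # assumption, so restrict the check to the flagged species
        assert summary.loc["PI", "asymmetrical_pct"] == pytest.approx(100.0)

    def test_sn_resolved_fraction(self):
        recs = [
            QuantRecord(parse_label("PI 18:0/10:0"), 90.0, 90.0),
            QuantRecord(parse_label("PI 16:0/18:1"), 10.0, 10.0),
        ]
        summary, _ = acyl_summaries(recs)
        assert summary.loc["PI", "asymmetrical_pct"] == pytest.approx(90.0)
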