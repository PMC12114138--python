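import pytest
from hypothesis import given, settings, strategies as st

from oglyco.digest import Glycopeptide, PeptideSpan
from oglyco.fragments import (
    GlycanRetention,
    Series,
    Spectrum,
    TheoreticalIon,
    backbone_ion_mz,
    match_peaks,
    oxonium_ions,
    theoretical_ion_set,
)
from oglyco.masses import (
    HEXNAC_REMNANT,
    PROTON,
    RESIDUE_MASSES,
    GlycanComposition,
    glycan_neutral_mass,
    peptide_neutral_mass,
)

CORE1 = GlycanComposition(HexNAc=1, Hex=1)

sequences = st.text(alphabet=sorted(RESIDUE_MASSES), min_size=2, max_size=25)


def make(sequence, start, sites):
    span = PeptideSpan(sequence, start, start + len(sequence) - 1)
    return Glycopeptide(span, {s: CORE1 for s in sites})


class TestBackboneIonMz:
    def test_srlpgp_y5_naked(self):
        gp = make("SRLPGP", 126, [126])
        assert round(backbone_ion_mz(gp, Series.Y, 5), 2) == 539.33

    def test_tpilpq_y5_naked(self):
        gp = make("TPILPQ", 134, [134])
        assert round(backbone_ion_mz(gp, Series.Y, 5), 2) == 567.35

    def test_slpsp_b2_remnant(self):
        gp = make("SLPSP", 121, [121])
        naked = backbone_ion_mz(gp, Series.B, 2)
        remnant = backbone_ion_mz(gp, Series.B, 2, 1, GlycanRetention.HEXNAC_REMNANT)
        assert round(naked, 2) == 201.12
        assert round(remnant, 2) == 404.20
        assert remnant - naked == pytest.approx(HEXNAC_REMNANT, abs=1e-12)

    def test_skappslpsp_b3_remnant(self):
        gp = make("SKAPPPSLPSP", 115, [115])
        assert round(backbone_ion_mz(gp, Series.B, 3), 2) == 287.17

    def test_sskappp_zdot6_full(self):
        gp = make("SSKAPPP", 114, [114, 115])
        mz = backbone_ion_mz(gp, Series.Z_DOT, 6, 1, GlycanRetention.FULL)
        assert round(mz, 2) == 945.45

    def test_slpsp_zdot4_naked(self):
        gp = make("SLPSP", 121, [121])
        assert round(backbone_ion_mz(gp, Series.Z_DOT, 4), 2) == 397.22

    def test_z_conventions_are_fixed_offsets(self):
        gp = make("SLPSP", 121, [121])
        y4 = backbone_ion_mz(gp, Series.Y, 4)
        assert backbone_ion_mz(gp, Series.Z, 4) == pytest.approx(y4 - 17.02655, abs=1e-5)
        assert backbone_ion_mz(gp, Series.Z_DOT, 4) == pytest.approx(y4 - 16.01872, abs=1e-5)
        assert backbone_ion_mz(gp, Series.Z_PLUS1, 4) == pytest.approx(y4 - 15.01090, abs=1e-5)

    def test_glycan_state_on_siteless_range_rejected(self):
        gp = make("SRLPGP", 126, [126])
        with pytest.raises(ValueError):
            backbone_ion_mz(gp, Series.Y, 5, 1, GlycanRetention.FULL)

    def test_index_out_of_range_rejected(self):
        gp = make("SRLPGP", 126, [126])
        with pytest.raises(ValueError):
            backbone_ion_mz(gp, Series.B, 6)

    def test_glycan_state_ordering(self):
        gp = make("SSKAPPP", 114, [114, 115])
        for series, index in [(Series.B, 3), (Series.C, 4), (Series.Y, 7 - 1)]:
            naked = backbone_ion_mz(gp, series, index)
            remnant = backbone_ion_mz(gp, series, index, 1, GlycanRetention.HEXNAC_REMNANT)
            full = backbone_ion_mz(gp, series, index, 1, GlycanRetention.FULL)
            assert full >= remnant >= naked
            n_sites = sum(1 for p in (1, 2) if series in (Series.B, Series.C) and p <= index) or 1
            assert remnant - naked == pytest.approx(n_sites * HEXNAC_REMNANT, abs=1e-9)
            assert full - naked == pytest.approx(
                n_sites * glycan_neutral_mass(CORE1), abs=1e-9
            )


@settings(max_examples=100, deadline=None)
@given(sequences, st.data())
def test_complementarity(sequence, data):
    """b_i + y_{n-i} = M + 2 protons; c/z pairs give the same sum once the
    z-convention shift is compensated."""
    gp = make(sequence, 1, [])
    n = len(sequence)
    i = data.draw(st.integers(min_value=1, max_value=n - 1))
    total = peptide_neutral_mass(sequence) + 2 * PROTON
    b = backbone_ion_mz(gp, Series.B, i)
    y = backbone_ion_mz(gp, Series.Y, n - i)
    assert b + y == pytest.approx(total, abs=1e-6)
    c = backbone_ion_mz(gp, Series.C, i)
    z = backbone_ion_mz(gp, Series.Z, n - i)
    assert c + z == pytest.approx(total, abs=1e-6)
    z_dot = backbone_ion_mz(gp, Series.Z_DOT, n - i)
    assert c + z_dot - 1.007825 == pytest.approx(total, abs=1e-6)


class TestTheoreticalIonSet:
    def test_naked_only_count(self):
        gp = make("TPILPQ", 134, [134])
        ions = theoretical_ion_set(gp, "HCD", states=[GlycanRetention.NONE])
        assert len(ions) == 10  # b1..b5, y1..y5

    def test_remnant_twins_cover_site(self):
        gp = make("SLPSP", 121, [121])
        ions = theoretical_ion_set(
            gp, "HCD", states=[GlycanRetention.NONE, GlycanRetention.HEXNAC_REMNANT]
        )
        remnants = {(i.series, i.index) for i in ions if i.glycan_state is GlycanRetention.HEXNAC_REMNANT}
        # site at position 1: all b ions cover it, only y4 (range 2..5 has no
        # site ... positions 2-5) -> y ions never cover position 1
        assert remnants == {(Series.B, 1), (Series.B, 2), (Series.B, 3), (Series.B, 4)}

    def test_ethcd_default_states(self):
        gp = make("SDTPILPQ", 132, [132])
        ions = theoretical_ion_set(gp, "EThcD")
        assert {i.series for i in ions} == {Series.C, Series.Z_DOT}
        for ion in ions:
            lo = 1 if ion.series is Series.C else len(gp.sequence) - ion.index + 1
            hi = ion.index if ion.series is Series.C else len(gp.sequence)
            covers_site = lo <= 1 <= hi
            expected = GlycanRetention.FULL if covers_site else GlycanRetention.NONE
            assert ion.glycan_state is expected

    def test_duplicate_free(self):
        gp = make("SSKAPPP", 114, [114, 115])
        ions = theoretical_ion_set(gp, "HCD", charges=(1, 2))
        keys = [(i.series, i.index, i.charge, i.glycan_state) for i in ions]
        assert len(keys) == len(set(keys))

    def test_oxonium_values(self):
        by_name = {i.name: i.mz for i in oxonium_ions()}
        assert by_name["ox-HexNAc"] == pytest.approx(204.0867, abs=1e-4)
        assert by_name["ox-HexNAcHex"] == pytest.approx(366.1395, abs=1e-4)
        assert by_name["ox-NeuAc"] == pytest.approx(292.1027, abs=1e-4)
        assert by_name["ox-HexNAc-H2O"] == pytest.approx(186.0761, abs=1e-4)


def ion(mz, series=Series.B, index=2):
    return TheoreticalIon(series, index, 1, GlycanRetention.NONE, mz)


class TestMatchPeaks:
    def test_exact_match(self):
        gp = make("SRLPGP", 126, [126])
        y5 = backbone_ion_mz(gp, Series.Y, 5)
        spectrum = Spectrum(991.49, 1, [(y5, 100.0)])
        matches = match_peaks(spectrum, [ion(y5, Series.Y, 5)], tolerance_ppm=20)
        assert len(matches) == 1
        assert matches[0].error_ppm == pytest.approx(0.0, abs=1e-9)

    def test_out_of_tolerance(self):
        spectrum = Spectrum(991.49, 1, [(539.3412, 100.0)])
        matches = match_peaks(spectrum, [ion(539.32999, Series.Y, 5)], tolerance_ppm=20)
        assert matches == []

    def test_nearest_peak_wins(self):
        spectrum = Spectrum(865.40, 1, [(404.2020, 50.0), (404.2035, 40.0)])
        matches = match_peaks(spectrum, [ion(404.2028)], tolerance_ppm=20)
        assert len(matches) == 1
        assert matches[0].peak_mz == 404.2035

    def test_tie_goes_to_higher_intensity(self):
        spectrum = Spectrum(865.40, 1, [(404.2020, 10.0), (404.2036, 90.0)])
        matches = match_peaks(spectrum, [ion(404.2028)], tolerance_ppm=20)
        assert matches[0].peak_mz == 404.2036

    def test_empty_spectrum(self):
        assert match_peaks(Spectrum(500.0, 1, []), [ion(400.0)], tolerance_ppm=20) == []

    def test_one_peak_many_ions(self):
        spectrum = Spectrum(865.40, 1, [(404.2028, 10.0)])
        ions = [ion(404.2028, Series.B, 2), ion(404.2029, Series.C, 2)]
        assert len(match_peaks(spectrum, ions, tolerance_ppm=20)) == 2

    def test_exactly_one_tolerance_required(self):
        spectrum = Spectrum(865.40, 1, [(404.2028, 10.0)])
        with pytest.raises(ValueError):
            match_peaks(spectrum, [ion(404.2028)], tolerance_ppm=20, tolerance_da=0.02)
        with pytest.raises(ValueError):
            match_peaks(spectrum, [ion(404.2028)], tolerance_ppm=None)
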