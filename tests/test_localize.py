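import pytest

from oglyco.digest import Glycopeptide, PeptideSpan
from oglyco.fragments import (
    GlycanRetention,
    Series,
    Spectrum,
    backbone_ion_mz,
    match_peaks,
    theoretical_ion_set,
)
from oglyco.glycans import CORE1
from oglyco.localize import (
    DEFAULT_PRIOR_SITES,
    EvidenceTier,
    SiteAssignment,
    aggregate_sites,
    localize_spectrum,
)
from oglyco.search import identify, identify_spectrum, localize_identifications
from oglyco.simulate import (
    SpectraParams,
    fsh_ctp_truth,
    simulate_spectra,
)


def make(sequence, start, sites):
    span = PeptideSpan(sequence, start, start + len(sequence) - 1)
    return Glycopeptide(span, {s: CORE1 for s in sites})


def spectrum_with_ions(glycopeptide, picks, precursor_charge=2):
    """Spectrum containing exactly the requested (series, index, state) ions."""
    peaks = [
        (backbone_ion_mz(glycopeptide, series, index, 1, state), 100.0)
        for series, index, state in picks
    ]
    return Spectrum(glycopeptide.precursor_mz(precursor_charge), precursor_charge, peaks)


def matched(glycopeptide, spectrum, mode):
    ions = theoretical_ion_set(glycopeptide, mode=mode)
    return match_peaks(spectrum, ions, tolerance_ppm=20)


class TestLocalizeSpectrum:
    def test_hcd_single_candidate(self):
        gp = make("TPILPQ", 134, [134])
        spectrum = spectrum_with_ions(gp, [(Series.Y, 5, GlycanRetention.NONE)])
        [assignment] = localize_spectrum(gp, matched(gp, spectrum, "HCD"), mode="HCD")
        assert assignment.protein_position == 134
        assert assignment.residue == "T"
        assert assignment.evidence is EvidenceTier.SINGLE_CANDIDATE

    def test_hcd_remnant_localized(self):
        gp = make("SLPSP", 121, [121])
        spectrum = spectrum_with_ions(gp, [(Series.B, 2, GlycanRetention.HEXNAC_REMNANT)])
        [assignment] = localize_spectrum(gp, matched(gp, spectrum, "HCD"), mode="HCD")
        assert assignment.protein_position == 121
        assert assignment.evidence is EvidenceTier.REMNANT_LOCALIZED

    def test_hcd_enzyme_inferred_without_discriminating_ions(self):
        gp = make("SSKAPPP", 114, [114, 115])
        assignments = localize_spectrum(gp, [], mode="HCD")
        tiers = {a.protein_position: a.evidence for a in assignments}
        assert tiers[114] is EvidenceTier.ENZYME_INFERRED
        assert tiers[115] is EvidenceTier.AMBIGUOUS

    def test_ethcd_direct_bracketing_via_z6(self):
        # a glycan-free z6 covers the only alternative candidate (T at the
        # third residue), confining the single glycan to the N-terminal serine
        gp = make("SDTPILPQ", 132, [132])
        spectrum = spectrum_with_ions(gp, [(Series.Z_DOT, 6, GlycanRetention.NONE)])
        [assignment] = localize_spectrum(gp, matched(gp, spectrum, "EThcD"), mode="EThcD")
        assert assignment.protein_position == 132
        assert assignment.evidence is EvidenceTier.DIRECT_BRACKETING

    def test_ethcd_z6_pins_both_adjacent_serines(self):
        gp = make("SSKAPPP", 114, [114, 115])
        spectrum = spectrum_with_ions(gp, [(Series.Z_DOT, 6, GlycanRetention.FULL)])
        assignments = localize_spectrum(gp, matched(gp, spectrum, "EThcD"), mode="EThcD")
        tiers = {a.protein_position: a.evidence for a in assignments}
        assert tiers[114] is EvidenceTier.DIRECT_BRACKETING
        assert tiers[115] is EvidenceTier.DIRECT_BRACKETING

    def test_all_ambiguous_without_matches_and_enzyme_rule(self):
        gp = make("SSKAPPP", 114, [114, 115])
        assignments = localize_spectrum(gp, [], mode="EThcD", enzyme_rule=False)
        assert all(a.evidence is EvidenceTier.AMBIGUOUS for a in assignments)

    def test_precursor_alone_never_brackets(self):
        # even when every candidate S/T is occupied, zero matched ions must
        # not yield bracketing evidence
        gp = make("SSKAPPP", 114, [114, 115])
        assignments = localize_spectrum(gp, [], mode="EThcD", enzyme_rule=True)
        tiers = {a.protein_position: a.evidence for a in assignments}
        assert tiers[114] is EvidenceTier.ENZYME_INFERRED
        assert tiers[115] is EvidenceTier.AMBIGUOUS

    def test_inconsistent_matches_rejected(self):
        gp = make("SLPSP", 121, [121])
        other = make("SRLPGPSDTPILPQ", 126, [126])
        bad = matched(
            other, spectrum_with_ions(other, [(Series.Z_DOT, 13, GlycanRetention.NONE)]),
            "EThcD",
        )
        with pytest.raises(ValueError):
            localize_spectrum(gp, bad, mode="EThcD")


class TestEvidenceTierOrder:
    def test_total_order(self):
        assert (
            EvidenceTier.DIRECT_BRACKETING
            > EvidenceTier.SINGLE_CANDIDATE
            > EvidenceTier.REMNANT_LOCALIZED
            > EvidenceTier.ENZYME_INFERRED
            > EvidenceTier.AMBIGUOUS
        )


def assignment(position, residue="S", tier=EvidenceTier.ENZYME_INFERRED, key=("k",)):
    return SiteAssignment(position, residue, CORE1, tier, (), "spec1", key)


class TestAggregateSites:
    def test_six_known_sites(self):
        assignments = [assignment(p) for p in DEFAULT_PRIOR_SITES]
        # position 134 is a threonine
        assignments[-1] = assignment(134, "T")
        table = aggregate_sites(assignments, DEFAULT_PRIOR_SITES)
        assert len(table) == 6
        assert not table["novel"].any()

    def test_novel_flag(self):
        assignments = [assignment(p) for p in DEFAULT_PRIOR_SITES if p != 134]
        assignments.append(assignment(134, "T"))
        assignments.append(assignment(124))
        table = aggregate_sites(assignments, DEFAULT_PRIOR_SITES)
        assert len(table) == 7
        novel = table[table["novel"]]["position"].tolist()
        assert novel == [124]

    def test_empty_input(self):
        table = aggregate_sites([])
        assert len(table) == 0

    def test_best_tier_wins_and_order_independent(self):
        weak = assignment(121, tier=EvidenceTier.ENZYME_INFERRED, key=("a",))
        strong = assignment(121, tier=EvidenceTier.DIRECT_BRACKETING, key=("b",))
        for order in ([weak, strong], [strong, weak]):
            table = aggregate_sites(order, DEFAULT_PRIOR_SITES)
            assert table.loc[0, "evidence"] == "direct_bracketing"
            assert table.loc[0, "n_glycopeptides"] == 2

    def test_idempotent(self):
        rows = [assignment(121), assignment(126)]
        once = aggregate_sites(rows, DEFAULT_PRIOR_SITES)
        twice = aggregate_sites(rows + rows, DEFAULT_PRIOR_SITES)
        assert once.equals(twice)

    def test_conflicting_residues_rejected(self):
        with pytest.raises(ValueError, match="121"):
            aggregate_sites([assignment(121, "S"), assignment(121, "T")])


class TestPipelineRecovery:
    def test_noiseless_full_ladders_all_bracketed(self, candidate_space):
        """Noiseless EThcD with complete c/z ladders: every planted site is
        recovered as direct bracketing and nothing else is reported."""
        truth = fsh_ctp_truth(seed=11)
        spectra, _ = simulate_spectra(truth)
        identifications = identify(spectra, candidate_space, mode="EThcD")
        assert len(identifications) == len(spectra)
        for ident, (planted, _) in zip(identifications, truth.glycoforms):
            assert ident.glycopeptide.key() == planted.key()
            assignments = localize_identifications([ident], mode="EThcD")
            assert {a.protein_position for a in assignments} == set(planted.sites)
            assert all(
                a.evidence is EvidenceTier.DIRECT_BRACKETING for a in assignments
            )

    def test_noisy_recall_and_zero_false_localization(self, candidate_space):
        """5 ppm fragment noise, 50% ion coverage, 200 spectra: planted-site
        recall >= 0.9 with zero false localizations at 20 ppm tolerance."""
        n_spectra = planted_total = recovered = false_localized = 0
        rep = 0
        while n_spectra < 200:
            truth = fsh_ctp_truth(
                seed=4000 + rep,
                spectra_params=SpectraParams(coverage=0.5, ppm_error_sd=5.0),
            )
            spectra, _ = simulate_spectra(truth)
            for spectrum, (planted, _) in zip(spectra, truth.glycoforms):
                if n_spectra >= 200:
                    break
                n_spectra += 1
                planted_sites = set(planted.sites)
                planted_total += len(planted_sites)
                ident = identify_spectrum(spectrum, candidate_space, mode="EThcD")
                if ident is None:
                    continue
                for a in localize_identifications([ident], mode="EThcD"):
                    if a.evidence > EvidenceTier.AMBIGUOUS:
                        if a.protein_position in planted_sites:
                            recovered += 1
                        else:
                            false_localized += 1
            rep += 1
        assert false_localized == 0
        assert recovered / planted_total >= 0.9
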