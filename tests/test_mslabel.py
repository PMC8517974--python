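"""Per-Cys label fractions, proteoform masses, species assignment,
difference spectra."""

import numpy as np
import pandas as pd
import pytest

from znmt.errors import GridMismatchError, ValidationError
from znmt.mslabel import (
    PeptideRecord,
    Proteoform,
    assign_species,
    increment_difference_spectra,
    metal_adduct_mass,
    modification_mass,
    per_cys_label_fractions,
    proteoform_mass,
    species_name,
)

APO = 6042.0  # synthetic apo mass, Da


class TestLabelFractions:
    def test_direct_ratio(self, sequence):
        records = [
            PeptideRecord(44, 51, 44, "NEM", 80.0),
            PeptideRecord(44, 51, 44, "IAM", 20.0),
        ]
        prof = per_cys_label_fractions(records, sequence)
        assert prof.loc[44, "fraction_NEM"] == pytest.approx(0.8)
        assert prof.loc[44, "fraction_IAM"] == pytest.approx(0.2)

    def test_iam_only_residue(self, sequence):
        prof = per_cys_label_fractions(
            [PeptideRecord(1, 20, 5, "IAM", 33.0)], sequence)
        assert prof.loc[5, "fraction_IAM"] == 1.0

    def test_fractions_sum_to_one_where_covered(self, sequence, rng):
        records = []
        for pos in (5, 7, 44):
            records.append(PeptideRecord(1, 61, pos, "NEM",
                                         float(rng.uniform(1, 100))))
            records.append(PeptideRecord(1, 61, pos, "IAM",
                                         float(rng.uniform(1, 100))))
        prof = per_cys_label_fractions(records, sequence)
        covered = prof[prof["covered"]]
        assert np.allclose(covered["fraction_NEM"] + covered["fraction_IAM"],
                           1.0)

    def test_uncovered_cys_flagged_not_imputed(self, sequence):
        prof = per_cys_label_fractions(
            [PeptideRecord(44, 51, 44, "NEM", 10.0)], sequence)
        assert not prof.loc[5, "covered"]
        assert np.isnan(prof.loc[5, "fraction_NEM"])

    def test_non_cys_position_rejected(self, sequence):
        with pytest.raises(ValidationError):
            per_cys_label_fractions(
                [PeptideRecord(1, 20, 6, "IAM", 1.0)], sequence)


class TestMasses:
    def test_nominal_shifts_match_reported_values(self):
        assert modification_mass("IAM", "nominal") == 57.0
        assert modification_mass("NEM", "nominal") == 125.0

    def test_monoisotopic_values(self):
        assert modification_mass("IAM") == pytest.approx(57.02146)
        assert modification_mass("NEM") == pytest.approx(125.04767)
        assert modification_mass("NEM") - modification_mass("IAM") == (
            pytest.approx(68.026, abs=1e-3)
        )

    def test_zinc_adduct_displaces_two_protons(self):
        assert metal_adduct_mass("Zn") == pytest.approx(61.91348, abs=1e-4)
        assert metal_adduct_mass("Zn", charge_neutral=False) == (
            pytest.approx(63.92914, abs=1e-4)
        )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            modification_mass("TMT")


class TestProteoformMass:
    def test_bare_apo(self):
        assert proteoform_mass(APO, 0, 0, 0) == APO

    def test_fully_iam_labelled(self):
        assert proteoform_mass(APO, 20, 0, 0) == pytest.approx(
            APO + 20 * 57.02146
        )

    def test_affine_in_each_count(self):
        base = proteoform_mass(APO, 3, 2, 1)
        assert proteoform_mass(APO, 4, 2, 1) - base == pytest.approx(
            modification_mass("IAM"))
        assert proteoform_mass(APO, 3, 3, 1) - base == pytest.approx(
            modification_mass("NEM"))
        assert proteoform_mass(APO, 3, 2, 2) - base == pytest.approx(
            metal_adduct_mass("Zn"))

    def test_label_swap_shift(self):
        m1 = proteoform_mass(APO, 10, 2, 0)
        m2 = proteoform_mass(APO, 9, 3, 0)
        assert m2 - m1 == pytest.approx(68.026, abs=1e-3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            proteoform_mass(APO, -1, 0, 0)


class TestAssignSpecies:
    def test_round_trip_identity_on_grid(self):
        """assign_species o proteoform_mass is the identity at a tolerance
        below half the minimum grid spacing (small grid keeps that spacing
        resolvable)."""
        combos = [(nm, ni, nn) for nm in range(3) for ni in range(5)
                  for nn in range(5 - ni)]
        masses = [proteoform_mass(APO, ni, nn, nm) for nm, ni, nn in combos]
        ledger = assign_species(masses, APO, tolerance=0.01, total_cys=4,
                                max_metal=2)
        for (nm, ni, nn), (_, row) in zip(combos, ledger.iterrows()):
            assert (row["n_metal"], row["n_iam"], row["n_nem"]) == (nm, ni, nn)
            assert not row["ambiguous"]
            assert row["mass_error"] == pytest.approx(0.0, abs=1e-9)

    def test_zn4_iam9_species(self):
        obs = proteoform_mass(APO, 9, 0, 4)
        ledger = assign_species([obs], APO, tolerance=0.02)
        assert ledger.loc[0, "species"] == "Zn_4_IAM_9_MT2"

    def test_far_mass_unassigned(self):
        ledger = assign_species([APO + 31000.0], APO, tolerance=0.02)
        assert ledger.loc[0, "species"] is None

    def test_wide_tolerance_flags_ambiguity(self):
        obs = proteoform_mass(APO, 1, 0, 0)
        ledger = assign_species([obs], APO, tolerance=60.0, total_cys=2,
                                max_metal=1)
        assert bool(ledger.loc[0, "ambiguous"])
        assert len(ledger.loc[0, "candidates"]) >= 2


class TestSpeciesName:
    @pytest.mark.parametrize("p,expect", [
        (Proteoform(9, 0, 4), "Zn_4_IAM_9_MT2"),
        (Proteoform(17, 3, 0), "IAM_17_NEM_3_MT2"),
        (Proteoform(0, 0, 0), "IAM_0_MT2"),
    ])
    def test_ledger_names(self, p, expect):
        assert species_name(p) == expect


class TestDifferenceSpectra:
    def test_identical_spectra_zero_increment(self):
        wl = np.linspace(220, 320, 51)
        a = np.vstack([np.exp(-(wl - 250) ** 2 / 400)] * 3)
        out = increment_difference_spectra(a, wl, 1.0, 1e-5)
        assert np.abs(out.to_numpy()).max() == 0.0

    def test_constant_step_recovers_coefficient(self):
        wl = np.linspace(220, 320, 21)
        c, ell, k = 2e-5, 1.0, 4500.0
        a0 = np.zeros_like(wl)
        spectra = np.vstack([a0, a0 + c * ell * k, a0 + 2 * c * ell * k])
        out = increment_difference_spectra(spectra, wl, ell, c)
        assert np.allclose(out["step_1"], k)
        assert np.allclose(out["step_2"], k)

    def test_shrinking_increments_mirror_cluster_formation(self):
        """Per-step molar-absorbance increments that decrease mark cluster
        formation rather than new independent ZnCys4 sites."""
        wl = np.linspace(220, 320, 41)
        band = np.exp(-(wl - 245) ** 2 / 300)
        c, ell = 1e-5, 1.0
        steps = [5000.0, 3000.0, 1500.0]
        spectra = [np.zeros_like(wl)]
        for k in steps:
            spectra.append(spectra[-1] + c * ell * k * band)
        out = increment_difference_spectra(np.vstack(spectra), wl, ell, c)
        maxima = out.max(axis=0).to_numpy()
        assert np.all(np.diff(maxima) < 0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            increment_difference_spectra(np.zeros((2, 10)),
                                         np.linspace(0, 1, 11), 1.0, 1e-5)
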