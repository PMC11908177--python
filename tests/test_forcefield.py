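"""Force-field unit tests: solvent model, electrostatics, pair potentials,
temperature scaling, parameter I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgtherm import constants
from cgtherm.constants import COULOMB, T_REF
from cgtherm.forcefield import (
    ElectrostaticsParams,
    PairParams,
    TempScalingParams,
    dielectric,
    epsilon_ij,
    fit_d_coefficients,
    inverse_debye_length,
    mu_X,
    pair_energy,
    pair_force,
    water_density,
    wf_energy,
    wf_r_star,
    wf_repulsive_energy,
    yukawa_energy,
)
from cgtherm.forcefield.electrostatics import TemperatureRangeError
from cgtherm.forcefield.parameters import ForceFieldError, ForceFieldParameters, ResidueParams
from cgtherm.forcefield.potentials import (
    effective_epsilon,
    numerical_r_star,
    wf_force,
    wf_repulsive_force,
)
from cgtherm import fixtures


# ------------------------------------------------------------- water & dielectric

class TestWaterDensity:
    def test_density_maximum_near_277K(self):
        grid = np.linspace(273.0, 373.0, 1001)
        rho = water_density(grid)
        t_max = grid[np.argmax(rho)]
        assert abs(t_max - 277.0) < 0.5

    def test_value_at_277K(self):
        assert water_density(277.0) == pytest.approx(0.99997, abs=5e-5)

    def test_thermal_expansion(self):
        assert water_density(373.0) < water_density(277.0)

    @pytest.mark.parametrize("T", [272.9, 373.1, 0.0, 500.0])
    def test_out_of_range(self, T):
        with pytest.raises(TemperatureRangeError):
            water_density(T)


class TestDielectric:
    def test_vacuum_limit(self):
        # rho -> 0 makes eps -> 1: emulate by zero d coefficients
        assert dielectric(300.0, (0.0, 0.0)) == pytest.approx(1.0)

    def test_ambient_value_tracks_fit(self):
        # the packaged d coefficients are the least-squares fit; re-derive them
        d = fit_d_coefficients()
        assert d[0] == pytest.approx(constants.DEFAULT_D_COEFFICIENTS[0], rel=1e-9)
        assert d[1] == pytest.approx(constants.DEFAULT_D_COEFFICIENTS[1], rel=1e-9)
        assert dielectric(298.15) == pytest.approx(78.4, abs=0.5)

    def test_monotone_decreasing(self):
        grid = np.linspace(273.0, 373.0, 401)
        eps = dielectric(grid)
        assert np.all(np.diff(eps) < 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ForceFieldError):
            ElectrostaticsParams(d_coefficients=(-500.0, 0.0))


class TestInverseDebyeLength:
    def test_pure_water(self):
        es = ElectrostaticsParams(ionic_species=((1, 0.0), (-1, 0.0)))
        assert inverse_debye_length(300.0, es) == 0.0

    def test_kappa_squared_linear_in_concentration(self):
        es1 = ElectrostaticsParams(ionic_species=((1, 0.1), (-1, 0.1)))
        es2 = ElectrostaticsParams(ionic_species=((1, 0.2), (-1, 0.2)))
        k1 = inverse_debye_length(310.0, es1)
        k2 = inverse_debye_length(310.0, es2)
        assert k2**2 / k1**2 == pytest.approx(2.0, rel=1e-12)

    def test_physiological_debye_length(self):
        # independent hand evaluation with CODATA constants at eps = 78.4
        ec, eps0, kb, na = 1.602176634e-19, 8.8541878128e-12, 1.380649e-23, 6.02214076e23
        dens = 2 * 0.150 * 1000.0 * na
        kappa_ref = np.sqrt(ec**2 / (78.4 * eps0 * kb * 298.15) * dens) * 1e-10
        es = ElectrostaticsParams(ionic_species=((1, 0.15), (-1, 0.15)))
        kappa = inverse_debye_length(298.15, es)
        assert 7.8 <= 1.0 / kappa_ref <= 8.0
        # package value uses its own eps(T); agree within 2%
        assert kappa == pytest.approx(kappa_ref, rel=0.02)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ForceFieldError):
            ElectrostaticsParams(ionic_species=((1, -0.1),))


class TestYukawa:
    ES = ElectrostaticsParams(ionic_species=((1, 0.15), (-1, 0.15)), yukawa_cutoff=30.0)

    def test_zero_charge(self):
        assert yukawa_energy(5.0, 0.0, 1.0, 300.0, self.ES) == 0.0

    def test_coulomb_limit_at_zero_salt(self):
        es = ElectrostaticsParams(ionic_species=(), yukawa_cutoff=30.0, shift_at_cutoff=False)
        r = 7.0
        expected = COULOMB * 1.0 * -1.0 / (dielectric(300.0) * r)
        assert yukawa_energy(r, 1.0, -1.0, 300.0, es) == pytest.approx(expected, rel=1e-12)

    def test_zero_at_cutoff_with_shift(self):
        assert yukawa_energy(30.0, 1.0, 1.0, 300.0, self.ES) == 0.0
        assert yukawa_energy(29.999999, 1.0, 1.0, 300.0, self.ES) == pytest.approx(0.0, abs=1e-9)

    def test_singularity(self):
        with pytest.raises(ZeroDivisionError):
            yukawa_energy(0.0, 1.0, 1.0, 300.0, self.ES)


# ---------------------------------------------------------------- well depths

class TestMuX:
    def test_constant(self):
        s = TempScalingParams(a=0.0, b=0.0, c=5.0)
        for T in (280.0, 300.0, 350.0):
            assert mu_X(T, s) == 5.0

    def test_hand_arithmetic(self):
        s = TempScalingParams(a=1e-4, b=-0.05, c=6.0)
        assert mu_X(300.0, s) == pytest.approx(0.0, abs=1e-12)


class TestEpsilonIJ:
    def test_reference_temperature_identity(self, repulsive_ff):
        ff = repulsive_ff
        for i, j in [("A", "A"), ("M", "G"), ("V", "L"), ("I", "Y")]:
            expected = 0.5 * (ff.residue(i).epsilon_mpipi + ff.residue(j).epsilon_mpipi)
            assert epsilon_ij(T_REF, i, j, ff) == pytest.approx(expected, abs=1e-14)

    def test_alpha_zero_is_temperature_independent(self, neutral_ff):
        vals = {epsilon_ij(T, "A", "G", neutral_ff) for T in (280.0, 310.0, 360.0)}
        assert len(vals) == 1

    def test_sign_change_at_high_temperature(self, repulsive_ff):
        assert epsilon_ij(280.0, "M", "M", repulsive_ff) > 0
        assert epsilon_ij(360.0, "M", "M", repulsive_ff) < 0

    def test_non_hydrophobic_pair_rejected(self, neutral_ff):
        with pytest.raises(ForceFieldError):
            epsilon_ij(300.0, "G", "S", neutral_ff)

    def test_symmetry(self, repulsive_ff):
        for T in (280.0, 330.0, 365.0):
            assert epsilon_ij(T, "A", "G", repulsive_ff) == pytest.approx(
                epsilon_ij(T, "G", "A", repulsive_ff), abs=1e-15
            )


# ---------------------------------------------------------------- WF potential

@st.composite
def wf_pairs(draw):
    sigma = draw(st.floats(3.0, 8.0))
    mu = draw(st.sampled_from([1.0, 1.5, 2.0, 3.0]))
    nu = draw(st.sampled_from([1.0, 1.5, 2.0]))
    return PairParams(sigma_ij=sigma, epsilon_ij_ref=0.5, mu_ij=mu, nu_ij=nu)


class TestWangFrenkel:
    def test_zero_at_sigma_and_cutoff(self):
        p = PairParams(sigma_ij=5.0, epsilon_ij_ref=0.5)
        assert wf_energy(5.0, p, 1.0) == 0.0
        assert wf_energy(15.0, p, 1.0) == 0.0
        assert wf_energy(20.0, p, 1.0) == 0.0

    @settings(max_examples=30, deadline=None)
    @given(wf_pairs())
    def test_minimum_depth_equals_epsilon(self, p):
        rs = wf_r_star(p)
        grid = np.linspace(p.sigma_ij, p.r_cut * 0.999999, 20001)
        vals = np.array([wf_energy(r, p, 1.0) for r in grid])
        assert vals.min() == pytest.approx(-1.0, rel=1e-6)
        assert wf_energy(rs, p, 1.0) == pytest.approx(-1.0, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(wf_pairs())
    def test_r_star_closed_form_matches_brute_force(self, p):
        assert wf_r_star(p) == pytest.approx(numerical_r_star(p), abs=1e-7 * p.sigma_ij)

    def test_r_star_bounds_and_scaling(self):
        p1 = PairParams(sigma_ij=4.0, epsilon_ij_ref=0.5, mu_ij=2.0, nu_ij=1.0)
        p2 = PairParams(sigma_ij=8.0, epsilon_ij_ref=0.5, mu_ij=2.0, nu_ij=1.0)
        assert p1.sigma_ij < wf_r_star(p1) < p1.r_cut
        assert wf_r_star(p2) == pytest.approx(2.0 * wf_r_star(p1), rel=1e-12)

    def test_requires_positive_epsilon(self):
        p = PairParams(sigma_ij=5.0, epsilon_ij_ref=0.5)
        with pytest.raises(ForceFieldError):
            wf_energy(6.0, p, -0.5)


class TestRepulsiveVariant:
    P = PairParams(sigma_ij=5.0, epsilon_ij_ref=0.5, mu_ij=2.0, nu_ij=1.0)

    def test_zero_at_and_beyond_r_star(self):
        rs = wf_r_star(self.P)
        assert wf_repulsive_energy(rs, self.P, -0.4) == 0.0
        assert wf_repulsive_energy(1.1 * rs, self.P, -0.4) == 0.0

    def test_continuity_at_branch_point(self):
        rs = wf_r_star(self.P)
        for delta in (1e-4, 1e-6, 1e-8):
            assert abs(wf_repulsive_energy(rs - delta, self.P, -0.4)) < 1e-4

    @settings(max_examples=30, deadline=None)
    @given(wf_pairs(), st.floats(-2.0, -0.01))
    def test_monotone_repulsive_below_r_star(self, p, eps):
        rs = wf_r_star(p)
        grid = np.linspace(0.3 * p.sigma_ij, rs, 500)
        vals = np.array([wf_repulsive_energy(r, p, eps) for r in grid])
        assert np.all(vals >= 0)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_rejects_positive_epsilon(self):
        with pytest.raises(ForceFieldError):
            wf_repulsive_energy(4.0, self.P, 0.4)


class TestPairDispatch:
    def test_symmetry(self, repulsive_ff):
        for r in (4.0, 6.0, 9.0):
            for i, j in [("A", "G"), ("M", "K"), ("D", "R")]:
                assert pair_energy(r, i, j, 320.0, repulsive_ff) == pytest.approx(
                    pair_energy(r, j, i, 320.0, repulsive_ff), abs=1e-15
                )

    def test_non_hydrophobic_pair_temperature_independent_short_range(self, neutral_ff):
        # uncharged pair: no electrostatics, no scaling -> identical at any T
        e1 = pair_energy(6.0, "G", "S", 280.0, neutral_ff)
        e2 = pair_energy(6.0, "G", "S", 360.0, neutral_ff)
        assert e1 == pytest.approx(e2, abs=1e-15)

    def test_repulsive_branch_nonnegative(self, repulsive_ff):
        assert epsilon_ij(360.0, "M", "M", repulsive_ff) < 0
        for r in np.linspace(2.0, 20.0, 100):
            assert pair_energy(r, "M", "M", 360.0, repulsive_ff) >= 0.0

    def test_three_bead_hand_sum(self, neutral_ff):
        # energies are pairwise additive by construction; verify on a triangle
        r12, r13, r23 = 6.0, 7.5, 5.5
        total = (
            pair_energy(r12, "A", "G", 300.0, neutral_ff)
            + pair_energy(r13, "A", "S", 300.0, neutral_ff)
            + pair_energy(r23, "G", "S", 300.0, neutral_ff)
        )
        parts = [
            pair_energy(r12, "A", "G", 300.0, neutral_ff),
            pair_energy(r13, "A", "S", 300.0, neutral_ff),
            pair_energy(r23, "G", "S", 300.0, neutral_ff),
        ]
        assert total == pytest.approx(sum(parts), abs=1e-15)

    @pytest.mark.parametrize("i,j,T", [("A", "A", 300.0), ("M", "G", 350.0),
                                       ("D", "K", 310.0), ("M", "M", 365.0)])
    def test_force_matches_finite_difference(self, repulsive_ff, i, j, T):
        sigma = repulsive_ff.pair(i, j).sigma_ij
        for r in (1.2 * sigma, 1.5 * sigma, 2.0 * sigma):
            h = 1e-6
            fd = -(pair_energy(r + h, i, j, T, repulsive_ff)
                   - pair_energy(r - h, i, j, T, repulsive_ff)) / (2 * h)
            f = pair_force(r, i, j, T, repulsive_ff)
            assert f == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_force_zero_at_minimum_and_beyond_cutoff(self, neutral_ff):
        p = neutral_ff.pair("G", "G")
        rs = wf_r_star(p)
        eps = effective_epsilon(300.0, "G", "G", neutral_ff)
        assert wf_force(rs, p, eps) == pytest.approx(0.0, abs=1e-12)
        assert pair_force(p.r_cut * 1.01, "G", "G", 300.0, neutral_ff) == 0.0

    def test_branch_point_continuity_across_fixture_sets(self, repulsive_ff):
        for code in "AVILM":
            p = repulsive_ff.pair(code, code)
            eps = epsilon_ij(365.0, code, code, repulsive_ff)
            if eps >= 0:
                continue
            rs = wf_r_star(p)
            assert abs(wf_repulsive_energy(rs * (1 - 1e-10), p, eps)) < 1e-8

    def test_repulsive_force_matches_finite_difference(self, repulsive_ff):
        p = repulsive_ff.pair("M", "M")
        eps = epsilon_ij(365.0, "M", "M", repulsive_ff)
        assert eps < 0
        rs = wf_r_star(p)
        for r in (0.8 * rs, 0.9 * rs, 0.99 * rs):
            h = 1e-7
            fd = -(wf_repulsive_energy(r + h, p, eps)
                   - wf_repulsive_energy(r - h, p, eps)) / (2 * h)
            assert wf_repulsive_force(r, p, eps) == pytest.approx(fd, rel=1e-5, abs=1e-9)


# ------------------------------------------------------------------- parameters

class TestParameterValidation:
    def test_hydrophobic_flag(self, neutral_ff):
        for code, res in neutral_ff.residues.items():
            assert res.is_hydrophobic == (code in set("AVILM"))

    def test_bad_residue_params(self):
        with pytest.raises(ForceFieldError):
            ResidueParams(code="X", mass=100.0, charge=0.0, sigma=5.0, epsilon_mpipi=0.2)
        with pytest.raises(ForceFieldError):
            ResidueParams(code="A", mass=-1.0, charge=0.0, sigma=5.0, epsilon_mpipi=0.2)

    def test_pair_defaults_rcut(self):
        p = PairParams(sigma_ij=5.0, epsilon_ij_ref=0.3)
        assert p.r_cut == pytest.approx(15.0)

    def test_completeness(self, neutral_ff):
        neutral_ff.validate()

    def test_missing_pair_reported(self, neutral_ff):
        import copy

        ff = copy.deepcopy(neutral_ff)
        del ff.pairs[("A", "C")]
        with pytest.raises(ForceFieldError):
            ff.validate()


class TestParameterIO:
    def test_roundtrip_lossless(self, tmp_path):
        ff = fixtures.make_param_set(seed=42, style="repulsive_at_high_T")
        manifest = ff.save(tmp_path)
        ff2 = ForceFieldParameters.load(manifest)
        assert ff2.residues == ff.residues
        assert ff2.pairs == ff.pairs
        assert ff2.scaling == ff.scaling
        assert ff2.electrostatics == ff.electrostatics
        assert ff2.t_ref == ff.t_ref

    def test_yaml_manifest(self, tmp_path):
        import yaml, json

        ff = fixtures.make_param_set(seed=1)
        manifest = ff.save(tmp_path)
        data = json.loads(manifest.read_text())
        ypath = tmp_path / "forcefield.yaml"
        ypath.write_text(yaml.safe_dump(data))
        ff2 = ForceFieldParameters.load(ypath)
        assert ff2.pairs == ff.pairs
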