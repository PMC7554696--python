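"""Wiseman single-site ITC simulation, fitting, and decomposition."""

import numpy as np
import pytest

from dnaintercal import synthetic as syn
from dnaintercal.exceptions import InvalidInputError
from dnaintercal.itc import (
    ITCData,
    InjectionSchedule,
    SingleSiteModel,
    dilute_concentrations,
    fit_single_site,
    integrate_thermogram,
    paper_like_schedule,
    thermodynamic_decomposition,
    wiseman_heats,
)
from oracles import bound_ligand_bisection

DOX_MODEL = SingleSiteModel(n=7.29, K=10.0 ** 6.03, dH=-9.52)


class TestDecomposition:
    def test_published_free_energy(self):
        dG, _ = thermodynamic_decomposition(10.0 ** 4.24, -5.84, 298.0)
        assert dG == pytest.approx(-5.78, abs=0.02)

    def test_published_entropy_term(self):
        """dH - dG for the stronger binder: -9.52 - (-8.26) = -1.3."""
        TdS = -9.52 - (-8.26)
        assert TdS == pytest.approx(-1.3, abs=0.05)

    def test_identity_holds_exactly(self):
        dG, TdS = thermodynamic_decomposition(2.5e5, -7.0)
        assert dG == pytest.approx(-7.0 - TdS, abs=1e-12)

    def test_dH_equals_dG_gives_zero_entropy(self):
        dG, TdS = thermodynamic_decomposition(1e6, 0.0)
        _, TdS2 = thermodynamic_decomposition(1e6, dG)
        assert TdS2 == pytest.approx(0.0, abs=1e-12)

    def test_invalid_K(self):
        with pytest.raises(InvalidInputError):
            thermodynamic_decomposition(-1.0, 0.0)


class TestDilution:
    def test_single_small_injection(self):
        sched = InjectionSchedule(
            injection_volumes_uL=np.array([1.0]),
            syringe_conc_mM=0.174,
            cell_conc_mM=0.002,
            cell_volume_mL=1.400,
        )
        M_t, L_t = dilute_concentrations(sched)
        r = 1.0 / 1400.0
        assert L_t[0] == pytest.approx(0.174e-3 * r / (1 + r / 2), rel=1e-12)
        assert M_t[0] == pytest.approx(0.002e-3 * (1 - r / 2) / (1 + r / 2), rel=1e-12)

    def test_matches_continuous_mixing_at_small_volumes(self):
        """The overflow formulas track the exact continuous-mixing
        integration (M = M0 e^{-v/V0}, L = L_syr (1 - e^{-v/V0})) to
        <= 0.1 % while cumulative volume stays below 10 % of the cell."""
        vols = np.full(14, 10.0)
        sched = InjectionSchedule(
            injection_volumes_uL=vols,
            syringe_conc_mM=0.174,
            cell_conc_mM=0.002,
            cell_volume_mL=1.400,
        )
        M_t, L_t = dilute_concentrations(sched)
        v = np.cumsum(vols) * 1e-6
        x = v / 1.4e-3
        np.testing.assert_allclose(M_t, 0.002e-3 * np.exp(-x), rtol=1e-3)
        np.testing.assert_allclose(L_t, 0.174e-3 * (1 - np.exp(-x)), rtol=1e-3)

    def test_large_volume_warns(self):
        with pytest.warns(UserWarning, match="cumulative"):
            InjectionSchedule(
                injection_volumes_uL=np.full(29, 10.0),
                syringe_conc_mM=0.174,
                cell_conc_mM=0.002,
                cell_volume_mL=1.400,
            )


class TestWisemanHeats:
    def test_zero_enthalpy_gives_zero_heats(self):
        model = SingleSiteModel(n=7.29, K=1e6, dH=0.0)
        assert np.allclose(wiseman_heats(model, paper_like_schedule()), 0.0)

    @staticmethod
    def _chemical_total(model, sched):
        """Cumulative bound-ligand heat: injection heats summed with the
        displaced-volume correction removed again."""
        heats = wiseman_heats(model, sched)
        from dnaintercal.itc import _bound_ligand

        M_t, L_t = dilute_concentrations(sched)
        V0 = sched.cell_volume_mL * 1e-3
        Q = _bound_ligand(model.n, model.K, M_t, L_t) * model.dH * V0 * 1e9
        Qprev = np.concatenate([[0.0], Q[:-1]])
        dV = sched.injection_volumes_uL * 1e-6
        corr = (dV / V0) * (Q + Qprev) / 2.0
        return heats, Q, corr

    def test_saturation_mass_balance(self):
        """At a strongly saturating molar ratio (~100x the stoichiometry)
        the cumulative chemical heat approaches n * dH * M_cell * V0."""
        sched = paper_like_schedule(syringe_conc_mM=0.87)
        heats, Q, corr = self._chemical_total(DOX_MODEL, sched)
        M_t, _ = dilute_concentrations(sched)
        V0 = sched.cell_volume_mL * 1e-3
        expected = DOX_MODEL.n * DOX_MODEL.dH * M_t[-1] * V0 * 1e9
        assert heats.sum() - corr.sum() == pytest.approx(expected, rel=0.02)

    def test_stoichiometric_limit_is_step(self):
        """K -> inf: every pre-step injection releases dH per mole injected."""
        sched = paper_like_schedule()
        model = SingleSiteModel(n=7.29, K=1e12, dH=-9.52)
        heats = wiseman_heats(model, sched)
        moles = sched.injection_volumes_uL * 1e-6 * sched.syringe_conc_mM * 1e-3
        molar_heats = heats / (moles * 1e9)
        M_t, L_t = dilute_concentrations(sched)
        pre_step = L_t / M_t < 0.8 * model.n
        assert np.allclose(molar_heats[pre_step], model.dH, rtol=5e-3)

    def test_agrees_with_bisection_oracle(self):
        """Closed-form bound ligand matches brute-force equilibrium solving
        on 1000 random parameter draws."""
        rng = np.random.default_rng(123)
        from dnaintercal.itc import _bound_ligand

        for _ in range(1000):
            n = rng.uniform(0.5, 10)
            K = 10.0 ** rng.uniform(3, 9)
            M = 10.0 ** rng.uniform(-7, -4)
            L = 10.0 ** rng.uniform(-7, -3)
            closed = float(_bound_ligand(n, K, np.array([M]), np.array([L]))[0])
            brute = bound_ligand_bisection(n, K, M, L)
            assert closed == pytest.approx(brute, rel=1e-8, abs=1e-20)

    def test_heat_conservation(self):
        """Summed injection heats equal dH * V0 * L_b,final exactly once
        the displaced-volume correction is accounted for, and that
        correction is bounded by the injected volume fraction."""
        sched = paper_like_schedule()
        heats, Q, corr = self._chemical_total(DOX_MODEL, sched)
        assert heats.sum() == pytest.approx(Q[-1] + corr.sum(), abs=1e-8)
        V0 = sched.cell_volume_mL * 1e-3
        v_tot = sched.injection_volumes_uL.sum() * 1e-6
        assert abs(corr.sum()) <= (v_tot / V0) * np.max(np.abs(Q))

    def test_isotherm_sharpens_with_K(self):
        sched = paper_like_schedule()
        M_t, L_t = dilute_concentrations(sched)
        ratio = L_t / M_t
        prev = 0.0
        for K in (1e4, 1e5, 1e6, 1e7):
            heats = wiseman_heats(SingleSiteModel(n=7.29, K=K, dH=-9.52), sched)
            steep = np.max(np.abs(np.diff(heats) / np.diff(ratio)))
            assert steep >= prev * 0.999
            prev = steep


class TestFit:
    def test_noiseless_round_trip(self):
        sched = paper_like_schedule()
        data = syn.gen_itc_experiment(DOX_MODEL, sched, dilution_heat=-0.5)
        fit = fit_single_site(data, sched)
        assert fit.model.n == pytest.approx(7.29, rel=1e-4)
        assert fit.model.logK == pytest.approx(6.03, abs=1e-4)
        assert fit.model.dH == pytest.approx(-9.52, rel=1e-4)
        assert fit.dG == pytest.approx(fit.model.dH - fit.TdS, abs=1e-10)

    def test_weak_binder_round_trip(self):
        sched = paper_like_schedule(syringe_conc_mM=0.470, cell_conc_mM=0.005)
        model = SingleSiteModel(n=7.98, K=10.0 ** 4.24, dH=-5.84)
        with pytest.warns(UserWarning, match="c ="):
            fit = fit_single_site(
                syn.gen_itc_experiment(model, sched), sched
            )
        assert fit.model.logK == pytest.approx(4.24, abs=1e-3)

    def test_noisy_recovery_median(self):
        sched = paper_like_schedule()
        scale = 0.01 * np.max(np.abs(wiseman_heats(DOX_MODEL, sched)))
        errs = []
        for seed in range(10):
            data = syn.gen_itc_experiment(
                DOX_MODEL,
                sched,
                dilution_heat=-0.5,
                noise=syn.NoiseSpec("gaussian_additive", scale, seed),
            )
            fit = fit_single_site(data, sched)
            errs.append(abs(fit.model.logK - 6.03))
        assert np.median(errs) <= 0.05

    def test_pure_dilution_has_no_resolvable_enthalpy(self):
        sched = paper_like_schedule()
        rng = np.random.default_rng(5)
        heats = rng.normal(-0.5, 0.05, sched.n_injections)
        from dnaintercal.exceptions import FitFailureError

        try:
            fit = fit_single_site(ITCData(heats=heats), sched)
        except FitFailureError:
            return
        assert abs(fit.model.dH) <= max(2 * fit.std_errors["dH"], 0.5)


def test_blank_subtraction_and_csv_round_trip(tmp_path):
    sched = paper_like_schedule()
    data = syn.gen_itc_experiment(
        DOX_MODEL,
        sched,
        dilution_heat=-2.0,
        noise=syn.NoiseSpec("gaussian_additive", 0.5, seed=3),
    )
    path = tmp_path / "itc.csv"
    data.to_csv(path)
    back = ITCData.from_csv(path)
    np.testing.assert_allclose(back.net_heats(), data.net_heats())
    # blank carries only dilution heat (plus noise around it)
    assert np.abs(np.mean(back.blank_heats) + 2.0) < 0.5


def test_thermogram_integration_recovers_pulse_heats():
    t = np.arange(0.0, 1200.0, 0.5)
    inj = np.array([100.0, 400.0, 700.0])
    true = np.array([-12.0, -8.0, -3.0])
    power = np.full_like(t, 1.5)     # constant instrument baseline
    for t0, q in zip(inj, true):
        on = (t >= t0) & (t < t0 + 20.0)
        power[on] += q / 20.0
    heats = integrate_thermogram(t, power, inj)
    assert np.allclose(heats, true, atol=0.15)
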