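"""PBPK core: partition coefficients, mass balance, linearity, descriptors."""

import numpy as np
import pandas as pd
import pytest

from aeropk import pbpk
from aeropk.pbpk import (
    DrugParams,
    PKProfile,
    SimpleDeposition,
    build_model,
    kp_perfusion_limited,
    load_tissue_composition,
    pk_descriptors,
    simulate,
)


class TestPartitionCoefficients:
    def test_no_lipophilicity_no_ionization_limit(self):
        # partitioning vanishes: Kp tends to the tissue water fractions
        # (extra- + intracellular water plus the aqueous 0.7*f_np share of
        # the phospholipid term), scaled by fup
        drug = DrugParams(logP=-20.0, pKa=(0.0,))
        comp = load_tissue_composition()
        kps = kp_perfusion_limited(drug, comp)
        for tissue, kp in kps.items():
            row = comp.loc[tissue]
            water = row["f_ew"] + row["f_iw"] + 0.7 * row["f_np"]
            assert kp == pytest.approx(drug.Fup * water, rel=1e-3)

    def test_monotone_in_logp(self):
        comp = load_tissue_composition()
        kp_lo = kp_perfusion_limited(DrugParams(logP=0.5), comp)
        kp_hi = kp_perfusion_limited(DrugParams(logP=2.5), comp)
        assert all(kp_hi[t] >= kp_lo[t] for t in kp_lo)

    def test_straight_line_reimplementation_oracle(self):
        # independent single-expression recomputation of the base equations
        drug = DrugParams()
        comp = load_tissue_composition()
        kps = kp_perfusion_limited(drug, comp)
        P = 10.0**drug.logP
        pKa1, pKa2 = drug.pKa

        def ion(pH):
            return 10.0 ** (pKa1 - pH) + 10.0 ** (pKa1 + pKa2 - 2 * pH)

        Y = 1.0 + ion(7.4)
        bc = comp.loc["blood_cells"]
        kpu_bc = (drug.B2P - 0.55) / (0.45 * drug.Fup)
        ka = max(
            (kpu_bc - (1 + ion(7.22)) / Y * bc["f_iw"] - (P * bc["f_nl"] + (0.3 * P + 0.7) * bc["f_np"]) / Y)
            * Y
            / (bc["ap_mg_g"] * ion(7.22)),
            0.0,
        )
        for t in kps:
            row = comp.loc[t]
            kpu = (
                row["f_ew"]
                + (1 + ion(7.0)) / Y * row["f_iw"]
                + ka * row["ap_mg_g"] * ion(7.0) / Y
                + (P * row["f_nl"] + (0.3 * P + 0.7) * row["f_np"]) / Y
            )
            assert kps[t] == pytest.approx(kpu * drug.Fup, rel=1e-12)

    def test_all_positive_for_default_drug(self):
        assert all(v > 0 for v in kp_perfusion_limited(DrugParams()).values())


class TestModel:
    def test_zero_dose_gives_zero_concentration(self, default_params):
        drug, lungp, sysp = default_params
        m = build_model(SimpleDeposition(0.792, 0.03, 0.096), 0.0, drug, lungp, sysp)
        prof = simulate(m, duration=2.0)
        assert np.all(prof.plasma_conc == 0.0)

    def test_dose_linearity(self, default_params):
        drug, lungp, sysp = default_params
        dep = SimpleDeposition(0.792, 0.03, 0.096)
        d1 = pk_descriptors(simulate(build_model(dep, 300.0, drug, lungp, sysp)), sysp.plasma_volume)
        d2 = pk_descriptors(simulate(build_model(dep, 600.0, drug, lungp, sysp)), sysp.plasma_volume)
        assert d2.Cmax == pytest.approx(2 * d1.Cmax, rel=1e-6)
        assert d2.AUC_0_12 == pytest.approx(2 * d1.AUC_0_12, rel=1e-6)
        assert d2.ConcU_30min == pytest.approx(2 * d1.ConcU_30min, rel=1e-6)

    def test_mass_conservation(self, validation_run):
        model, profile, _ = validation_run
        deposited = model.y0.sum()
        audit = pbpk.mass_audit(profile, model)
        assert np.max(np.abs(audit - deposited)) / deposited < 1e-6

    def test_urine_bounded_by_renal_share(self, validation_run):
        model, profile, _ = validation_run
        sysp = model.sysp
        share = sysp.CL_renal / (sysp.CL_renal + sysp.CL_hepatic)
        assert profile.cumulative_urine[-1] <= share * model.dose

    def test_renal_share_at_completion(self, default_params):
        # all absorbed drug eventually eliminated: renal share = CLr/(CLr+CLh)
        drug, lungp, sysp = default_params
        m = build_model(SimpleDeposition(0.792, 0.03, 0.096), 600.0, drug, lungp, sysp)
        prof = simulate(m, duration=400.0, grid=np.linspace(0, 400.0, 400))
        urine = prof.amounts["urine"].iloc[-1]
        hepatic = prof.amounts["hepatic_eliminated"].iloc[-1]
        share = sysp.CL_renal / (sysp.CL_renal + sysp.CL_hepatic)
        assert urine / (urine + hepatic) == pytest.approx(share, abs=1e-4)

    def test_cumulative_urine_nondecreasing(self, validation_run):
        _, profile, _ = validation_run
        assert np.all(np.diff(profile.cumulative_urine) >= -1e-12)

    def test_solver_tolerance_convergence(self, default_params):
        drug, lungp, sysp = default_params
        dep = SimpleDeposition(0.792, 0.03, 0.096)
        m = build_model(dep, 600.0, drug, lungp, sysp)
        c1 = pk_descriptors(simulate(m, rtol=1e-8, atol=1e-12), sysp.plasma_volume).Cmax
        c2 = pk_descriptors(simulate(m, rtol=1e-10, atol=1e-14), sysp.plasma_volume).Cmax
        assert c1 == pytest.approx(c2, rel=1e-6)

    def test_overfull_fractions_rejected(self, default_params):
        drug, lungp, sysp = default_params
        with pytest.raises(Exception):
            build_model(SimpleDeposition(0.9, 0.2, 0.2), 600.0, drug, lungp, sysp)


class TestDescriptors:
    @staticmethod
    def _profile(times, conc, urine=None):
        n = len(times)
        urine = np.zeros(n) if urine is None else urine
        amounts = pd.DataFrame({"venous": conc}, index=times)
        return PKProfile(times=np.asarray(times, float), plasma_conc=np.asarray(conc, float),
                         cumulative_urine=np.asarray(urine, float), amounts=amounts)

    def test_triangular_peak(self):
        t = np.linspace(0, 12, 241)
        c = np.interp(t, [0, 2, 12], [0, 3.0, 0])
        d = pk_descriptors(self._profile(t, c))
        assert d.Cmax == pytest.approx(3.0, rel=1e-9)
        assert d.tmax == pytest.approx(2.0, abs=0.05)

    def test_constant_concentration_auc(self):
        t = np.linspace(0, 12, 121)
        d = pk_descriptors(self._profile(t, np.full_like(t, 1.5)))
        assert d.AUC_0_12 == pytest.approx(18.0, rel=1e-12)

    def test_urine_ratio_definition(self):
        t = np.linspace(0, 12, 121)
        c = np.full_like(t, 2.0)
        urine = np.linspace(0, 120, 121)  # 10 ug/h
        d = pk_descriptors(self._profile(t, c, urine), plasma_volume_L=3.78)
        assert d.ConcU_30min == pytest.approx(5.0)
        assert d.urine_to_cmax_ratio == pytest.approx(5.0 / (2.0 * 3780.0), rel=1e-9)
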