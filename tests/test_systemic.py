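import numpy as np
import pytest

from abzpbpk import fold_error, hepatic_clearance, nca, run_trial, simulate_subject
from abzpbpk.errors import InsufficientDataError, InvalidInputError
from abzpbpk.gi import GIOptions
from abzpbpk.systemic import TrialDesign, interpolated_tmax


def profile_metrics(subject, analyte):
    p = subject.profile[subject.profile["analyte"] == analyte]
    return nca(p["t_h"].to_numpy(), p["conc_ng_per_mL"].to_numpy())


class TestHepaticClearance:
    def test_linear_limit_per_pmol(self, abz):
        # CYP3A4 alone: CLint per pmol enzyme = Vmax/Km = 369/10.1 µL/min/pmol
        cyp = [e for e in abz.parent.hepatic_enzymes if e.name == "CYP3A4"][0]
        per_pmol = cyp.vmax_pmol_min_pmol / cyp.km_uM
        assert per_pmol == pytest.approx(36.5, abs=0.1)

    def test_pathway_ratio_from_printed_kinetics(self, abz):
        cyp, fmo = abz.parent.hepatic_enzymes
        ratio = (fmo.vmax_pmol_min_pmol / fmo.km_uM) / (cyp.vmax_pmol_min_pmol / cyp.km_uM)
        assert ratio == pytest.approx(3.15, abs=0.01)

    def test_saturation_reduces_clint(self, abz):
        lo = hepatic_clearance(abz.parent, c_unbound_uM=0.0)
        hi = hepatic_clearance(abz.parent, c_unbound_uM=1000.0)
        assert hi.clint_u_L_h < 0.05 * lo.clint_u_L_h  # far above both Km values

    def test_high_extraction_drug(self, abz):
        h = hepatic_clearance(abz.parent)
        assert h.extraction > 0.9          # extensive first-pass loss
        assert h.fh == pytest.approx(1 - h.extraction)
        assert h.cl_blood_L_h < abz.parent.hepatic_blood_flow_L_h


class TestSimulateSubject:
    def test_mass_balance_and_fractions(self, mean_subject):
        assert mean_subject.mass_balance_error_mg < 1e-6 * 400.0
        assert 0 < mean_subject.fa < 1
        assert 0 < mean_subject.fg <= 1
        assert 0 < mean_subject.fh < 0.05   # extensively metabolized parent
        assert mean_subject.F == pytest.approx(
            mean_subject.fa * mean_subject.fg * mean_subject.fh)
        assert mean_subject.F < 0.05        # low absolute oral bioavailability

    def test_metabolite_impulse_half_life(self, abz):
        """A unit impulse into the metabolite compartment decays
        mono-exponentially with t1/2 = ln2 * V / CL = 2.79 h (70 kg)."""
        v = abz.metabolite.vss_L_kg * 70.0
        cl = abz.metabolite.cl_systemic_L_h
        assert np.log(2) * v / cl == pytest.approx(2.79, abs=0.01)

    def test_zero_dose_profiles_are_zero(self, abz):
        sub = simulate_subject(0.0, abz.physiology, abz.solubility, abz.ion,
                               abz.formulation, abz.dlm, abz.precip, abz.absorb,
                               abz.parent, abz.metabolite, 70.0,
                               options=GIOptions(t_end_h=6.0))
        assert (sub.profile["conc_ng_per_mL"] == 0).all()

    def test_metabolite_auc_mass_balance_identity(self, abz):
        """AUC0-inf x CL equals the MW-corrected mass of metabolite formed."""
        sub = simulate_subject(400.0, abz.physiology, abz.solubility, abz.ion,
                               abz.formulation, abz.dlm, abz.precip, abz.absorb,
                               abz.parent, abz.metabolite, 70.0,
                               options=GIOptions(t_end_h=120.0, n_eval=601))
        m = profile_metrics(sub, "metabolite")
        mass_from_auc = m.auc0_inf * 1e-3 * abz.metabolite.cl_systemic_L_h  # ng/mL*h -> mg
        assert mass_from_auc == pytest.approx(sub.metabolite_formed_mg, rel=0.01)


class TestNCA:
    def test_triangle_profile_linear_trapezoid(self):
        m = nca([0.0, 1.0, 2.0], [0.0, 10.0, 0.0], extrapolate=False)
        assert m.auc0_t == pytest.approx(10.0)
        assert m.cmax == 10.0
        assert m.tmax_h == 1.0

    def test_monoexponential_extrapolation(self):
        t = np.linspace(0, 12, 121)
        c = 100 * np.exp(-0.5 * t)
        m = nca(t, c)
        assert m.auc0_inf == pytest.approx(200.0, rel=5e-3)
        assert m.lambda_z_per_h == pytest.approx(0.5, rel=1e-3)

    def test_cmax_is_max_sample(self):
        rng = np.random.default_rng(3)
        c = rng.random(20)
        m = nca(np.arange(20.0), c, extrapolate=False)
        assert m.cmax == c.max()

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            nca([0, 1], [1, 2])

    def test_interpolated_tmax_refines_grid(self):
        t = np.linspace(0, 10, 11)
        c = -(t - 3.3) ** 2
        assert interpolated_tmax(t, c) == pytest.approx(3.3, abs=1e-9)


class TestFoldError:
    @pytest.mark.parametrize("pred, obs, expected", [
        (59.7, 53.0, 1.13),
        (195.1, 193.5, 1.01),
        (5.0, 5.0, 1.0),
    ])
    def test_values(self, pred, obs, expected):
        assert fold_error(pred, obs) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(InvalidInputError):
            fold_error(1.0, 0.0)


class TestRunTrial:
    def _mini_design(self, seed=42, **kw):
        return TrialDesign(n_subjects=2, n_male=1, seed=seed, **kw)

    def test_same_seed_is_bit_identical(self, abz):
        kw = dict(physiology=abz.physiology, sol=abz.solubility, ion=abz.ion,
                  formulation=abz.formulation, dlm=abz.dlm, precip=abz.precip,
                  absorb=abz.absorb, parent=abz.parent, met=abz.metabolite,
                  options=GIOptions(t_end_h=24.0))
        a_ = run_trial(self._mini_design(), **kw)
        b_ = run_trial(self._mini_design(), **kw)
        assert a_.subjects.equals(b_.subjects)

    def test_zero_cv_subjects_differ_only_by_sex_weight(self, abz):
        design = TrialDesign(n_subjects=2, n_male=2, seed=7, bw_cv=0.0,
                             cv_hepatic_clint=0.0, cv_vss_parent=0.0,
                             cv_vss_metabolite=0.0, cv_cl_metabolite=0.0,
                             cv_gastric_mrt=0.0)
        res = run_trial(design, abz.physiology, abz.solubility, abz.ion,
                        abz.formulation, abz.dlm, abz.precip, abz.absorb,
                        abz.parent, abz.metabolite, options=GIOptions(t_end_h=24.0))
        for _, grp in res.subjects.groupby("analyte"):
            assert grp["cmax_ng_mL"].nunique() == 1  # identical male subjects
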