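import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abzpbpk.errors import InvalidInputError, UnderdeterminedError, UnderdeterminedWarning
from abzpbpk.solubility import (Medium, SolubilityParams, SolubilityTable,
                                aqueous_solubility, fit_bile_partition,
                                fit_intrinsic_solubility, total_solubility)


class TestAqueousSolubility:
    @pytest.mark.parametrize("pH, expected", [
        (1.2, 0.4897286),    # strong ionization of the basic centre
        (6.8, 0.01200536),   # essentially neutral
    ])
    def test_henderson_hasselbalch_values(self, abz_ion, pH, expected):
        assert aqueous_solubility(pH, abz_ion, 0.012) == pytest.approx(expected, rel=1e-6)

    def test_half_ionization_point_doubles_intrinsic(self, abz_ion):
        s = aqueous_solubility(abz_ion.pka_base, abz_ion, 0.05)
        assert s == pytest.approx(2 * 0.05, rel=1e-3)

    def test_approaches_intrinsic_four_log_units_above_basic_pka(self, abz_ion):
        s = aqueous_solubility(abz_ion.pka_base + 4.0, abz_ion, 0.012)
        assert abs(s - 0.012) / 0.012 < 5e-4

    @given(pH=st.floats(0.5, 13.5), s0=st.floats(1e-6, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_never_below_intrinsic(self, abz_ion, pH, s0):
        assert aqueous_solubility(pH, abz_ion, s0) >= s0

    def test_nonfinite_inputs_rejected(self, abz_ion):
        with pytest.raises(InvalidInputError):
            aqueous_solubility(float("nan"), abz_ion, 0.012)
        with pytest.raises(InvalidInputError):
            aqueous_solubility(6.5, abz_ion, -1.0)


class TestTotalSolubility:
    def test_fessif_matches_hand_evaluation(self, abz_ion, abz_sol):
        s = total_solubility(Medium("FeSSIF", 5.0, 15.0), abz_ion, abz_sol)
        assert s == pytest.approx(0.020223, rel=1e-3)

    def test_fassif_matches_hand_evaluation(self, abz_ion, abz_sol):
        s = total_solubility(Medium("FaSSIF", 6.5, 3.0), abz_ion, abz_sol)
        assert s == pytest.approx(0.012613, rel=1e-3)

    def test_zero_bile_reduces_to_aqueous(self, abz_ion, abz_sol):
        s = total_solubility(None, abz_ion, abz_sol, pH=5.0, bile_salt_mM=0.0)
        assert s == aqueous_solubility(5.0, abz_ion, abz_sol.S0)

    @given(b1=st.floats(0, 30), b2=st.floats(0, 30), pH=st.floats(1.5, 8.0))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_bile(self, abz_ion, abz_sol, b1, b2, pH):
        lo, hi = sorted([b1, b2])
        s_lo = total_solubility(None, abz_ion, abz_sol, pH=pH, bile_salt_mM=lo)
        s_hi = total_solubility(None, abz_ion, abz_sol, pH=pH, bile_salt_mM=hi)
        assert s_hi >= s_lo - 1e-15

    def test_negative_bile_rejected(self, abz_ion, abz_sol):
        with pytest.raises(InvalidInputError):
            total_solubility(None, abz_ion, abz_sol, pH=6.5, bile_salt_mM=-1.0)


class TestIntrinsicSolubilityFit:
    def test_reference_table_closed_form(self, abz_ion):
        fit = fit_intrinsic_solubility(SolubilityTable.reference_abz().bile_free(), abz_ion)
        assert fit.S0 == pytest.approx(0.012326, abs=1e-5)
        assert fit.r_squared == pytest.approx(0.97649, abs=1e-4)
        assert round(fit.S0, 3) == 0.012

    def test_closed_form_matches_grid_search_oracle(self, abz_ion):
        """Independent oracle: dense 1-D grid over S0 on the reference data."""
        table = SolubilityTable.reference_abz().bile_free()
        data = table.collapsed()
        f = 1.0 + abz_ion.ionized_ratio(data["pH"].to_numpy())
        y = data["solubility_mg_per_mL"].to_numpy()
        grid = np.linspace(1e-4, 0.05, 10_000)
        sse = ((y[None, :] - grid[:, None] * f[None, :]) ** 2).sum(axis=1)
        s0_grid = grid[np.argmin(sse)]
        fit = fit_intrinsic_solubility(table, abz_ion)
        assert fit.S0 == pytest.approx(s0_grid, rel=5e-4)

    def test_noiseless_recovery_is_exact(self, abz_ion):
        s0_true = 0.05
        rows = [(f"pH {p}", p, 0.0, aqueous_solubility(p, abz_ion, s0_true), 0.0)
                for p in (1.5, 3.0, 5.0, 7.0)]
        fit = fit_intrinsic_solubility(SolubilityTable.from_rows(rows), abz_ion)
        assert fit.S0 == pytest.approx(s0_true, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_log_scale_gives_different_estimate(self, abz_ion):
        table = SolubilityTable.reference_abz().bile_free()
        fit = fit_intrinsic_solubility(table, abz_ion, scale="log")
        assert fit.S0 == pytest.approx(0.00641, rel=2e-2)

    def test_rejects_bile_media_and_underdetermined(self, abz_ion):
        with pytest.raises(InvalidInputError):
            fit_intrinsic_solubility(SolubilityTable.reference_abz(), abz_ion)
        one_row = SolubilityTable.from_rows([("x", 1.2, 0.0, 0.5, 0.0)])
        with pytest.raises(UnderdeterminedError):
            fit_intrinsic_solubility(one_row, abz_ion)

    def test_r_squared_never_exceeds_one(self, abz_ion):
        fit = fit_intrinsic_solubility(SolubilityTable.reference_abz().bile_free(), abz_ion)
        assert fit.r_squared <= 1.0


class TestBilePartitionFit:
    def test_noiseless_recovery(self, abz_ion):
        truth = SolubilityParams(S0=0.012, logKmw_neutral=3.0, logKmw_ion=5.0)
        rows = [(n, p, b, total_solubility(Medium(n, p, b), abz_ion, truth), 0.0)
                for n, p, b in (("FaSSGF", 1.6, 0.08), ("FaSSIF", 6.5, 3.0),
                                ("FeSSIF", 5.0, 15.0))]
        fit = fit_bile_partition(SolubilityTable.from_rows(rows), abz_ion, 0.012)
        assert fit.logKmw_neutral == pytest.approx(3.0, abs=1e-6)
        assert fit.logKmw_ion == pytest.approx(5.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_single_bile_level_warns_and_fits_neutral_only(self, abz_ion):
        truth = SolubilityParams(S0=0.012, logKmw_neutral=3.0, logKmw_ion=-np.inf)
        rows = [(n, p, 3.0, total_solubility(Medium(n, p, 3.0), abz_ion, truth), 0.0)
                for n, p in (("a", 6.5), ("b", 5.5))]
        with pytest.warns(UnderdeterminedWarning):
            fit = fit_bile_partition(SolubilityTable.from_rows(rows), abz_ion, 0.012)
        assert fit.logKmw_ion is None
        assert fit.logKmw_neutral == pytest.approx(3.0, abs=1e-6)

    def test_replicates_collapse_to_mean(self, abz_ion, abz_sol):
        table = SolubilityTable.from_rows([
            ("FaSSIF", 6.5, 3.0, 0.010, 0.0),
            ("FaSSIF", 6.5, 3.0, 0.014, 0.0),
            ("FeSSIF", 5.0, 15.0, 0.021, 0.0),
        ])
        collapsed = table.collapsed()
        assert len(collapsed) == 2
        assert collapsed.loc[collapsed.medium == "FaSSIF",
                             "solubility_mg_per_mL"].iloc[0] == pytest.approx(0.012)


def test_table_csv_round_trip(tmp_path):
    table = SolubilityTable.reference_abz()
    path = tmp_path / "sol.csv"
    table.to_csv(path)
    back = SolubilityTable.read_csv(path)
    assert np.allclose(back.frame["solubility_mg_per_mL"],
                       table.frame["solubility_mg_per_mL"])
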