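"""Titration profile, MS coefficient, energy decomposition and plots."""

from __future__ import annotations

import numpy as np
import pytest

from ttmd.analysis import (
    TitrationProfile,
    energy_decomposition,
    most_contacted_residues,
    ms_coefficient,
    per_residue_energy,
    render_plots,
    titration_profile,
    COULOMB_CONSTANT,
)
from ttmd.errors import ParameterError, UsageError
from ttmd.protocol import TemperatureRamp, TTMDRunResult, run_ttmd
from ttmd.synthetic import SyntheticEngine, SyntheticScenario

from conftest import build_system


def profile_from(points, t_start=300.0):
    return TitrationProfile(points=points, t_start=t_start)


class TestProfile:
    def test_one_point_per_step(self, toy_system):
        run = run_ttmd(
            toy_system,
            SyntheticEngine(SyntheticScenario("stable"), frames_per_window=10),
            TemperatureRamp(300, 320, 10, 10),
            seed=1,
            store_trajectories=False,
        )
        profile = titration_profile(run)
        assert len(profile.points) == len(run.steps)
        assert profile.initial_value == -1.0 and profile.t_start == 300.0
        assert np.array_equal(profile.temperatures, run.step_temperatures)
        assert profile.final_mean < 0  # stable binder keeps contacts

    def test_empty_run_rejected(self, toy_system, toy_reference):
        empty = TTMDRunResult(
            steps=[], terminated_early=False, last_temperature=300.0, seed=0,
            ramp=TemperatureRamp(), reference=toy_reference,
        )
        with pytest.raises(UsageError):
            titration_profile(empty)

    def test_non_monotone_temperatures_rejected(self):
        with pytest.raises(ValueError):
            profile_from([(310.0, -0.9), (310.0, -0.8)])


class TestMsCoefficient:
    def test_fully_retained_binding_gives_zero(self):
        ms = ms_coefficient(profile_from([(450.0, -1.0)]))
        assert ms.value == 0.0

    def test_total_loss_over_full_ramp(self):
        ms = ms_coefficient(profile_from([(450.0, 0.0)]))
        assert ms.value == pytest.approx(1.0 / 150.0, rel=1e-12)

    def test_early_termination_hand_value(self):
        ms = ms_coefficient(profile_from([(310.0, 0.0)]))
        assert ms.value == pytest.approx(0.1, rel=1e-12)

    def test_intermediate_hand_value(self):
        ms = ms_coefficient(profile_from([(350.0, -0.4)]))
        assert ms.value == pytest.approx(0.6 / 50.0, rel=1e-12)

    def test_undefined_slope_rejected(self):
        with pytest.raises(UsageError):
            ms_coefficient(profile_from([(300.0, -0.5)]))

    def test_strictly_increasing_in_final_mean(self):
        finals = np.linspace(-1.0, 0.0, 11)
        values = [ms_coefficient(profile_from([(450.0, f)])).value for f in finals]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(v >= 0 for v in values)


class TestEnergy:
    def test_lj_zero_at_sigma(self):
        entries = [
            ("C1", "C", "GLY", 1, (0.0, 0.0, 0.0), "protein", 0.0, 3.32, 0.1),
            ("C1", "C", "LIG", 90, (3.32, 0.0, 0.0), "ligand", 0.0, 3.32, 0.1),
        ]
        system = build_system(entries)
        df = per_residue_energy(system.coords0, system)
        assert df["e_lj"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert df["e_elec"].iloc[0] == 0.0

    def test_coulomb_hand_value(self):
        entries = [
            ("N1", "N", "GLY", 1, (0.0, 0.0, 0.0), "protein", 1.0, 3.0, 0.0),
            ("C1", "C", "LIG", 90, (3.32, 0.0, 0.0), "ligand", -1.0, 3.0, 0.0),
        ]
        df = per_residue_energy(build_system(entries).coords0, build_system(entries))
        assert df["e_elec"].iloc[0] == pytest.approx(-COULOMB_CONSTANT / 3.32, rel=1e-12)
        assert df["e_elec"].iloc[0] == pytest.approx(-100.0, abs=0.1)

    def test_beyond_cutoff_contributes_nothing(self):
        entries = [
            ("C1", "C", "GLY", 1, (0.0, 0.0, 0.0), "protein", 0.5, 3.3, 0.1),
            ("C1", "C", "LIG", 90, (20.0, 0.0, 0.0), "ligand", -0.5, 3.3, 0.1),
        ]
        system = build_system(entries)
        df = per_residue_energy(system.coords0, system, cutoff=9.0)
        assert len(df) == 0

    def test_missing_parameters_reported(self, peptide_benzene_pdb):
        from ttmd.core import read_structure

        system = read_structure(peptide_benzene_pdb, "BNZ")
        with pytest.raises(ParameterError, match="serial"):
            per_residue_energy(system.coords0, system)

    def test_decomposition_sums_to_total(self, toy_system):
        """Residue-wise sums must equal the undecomposed whole-protein
        ligand interaction energy (independent brute-force pair loop)."""
        rng = np.random.default_rng(8)
        coords = toy_system.coords0 + rng.normal(scale=0.1, size=(toy_system.n_atoms, 3))
        df = per_residue_energy(coords, toy_system, cutoff=9.0)
        decomposed = df["e_lj"].sum() + df["e_elec"].sum()

        total = 0.0
        for i, a in enumerate(toy_system.atoms):
            if a.role not in ("protein", "ion"):
                continue
            for j in toy_system.ligand_atoms:
                b = toy_system.atoms[j]
                r = float(np.linalg.norm(coords[i] - coords[j]))
                if r > 9.0:
                    continue
                sig = 0.5 * (a.lj_params[0] + b.lj_params[0])
                eps = np.sqrt(a.lj_params[1] * b.lj_params[1])
                sr6 = (sig / r) ** 6
                total += 4 * eps * (sr6**2 - sr6)
                total += COULOMB_CONSTANT * a.partial_charge * b.partial_charge / r
        assert decomposed == pytest.approx(total, abs=1e-8)


class TestContactsAndPlots:
    def _run(self, toy_system, frames=8):
        return run_ttmd(
            toy_system,
            SyntheticEngine(SyntheticScenario("stable"), frames_per_window=frames),
            TemperatureRamp(300, 320, 10, 10),
            seed=4,
        )

    def test_most_contacted_ranking_and_ties(self, toy_system, toy_calculator):
        fps = [toy_calculator.compute(toy_system.coords0)] * 3
        ranked = most_contacted_residues(fps, n=25)
        # only the five engineered pocket residues are ever contacted
        assert set(ranked) == {("A", i, "") for i in range(1, 6)}
        # equal counts: ties broken by residue order
        assert ranked == sorted(ranked, key=lambda k: k[1])

    def test_render_plots_files_and_slope_legend(self, toy_system, tmp_path):
        run = self._run(toy_system)
        profile = titration_profile(run)
        energies = energy_decomposition(run, toy_system)
        from ttmd.model import TTMD, TTMDResults

        res = TTMDResults(model=TTMD(toy_system), run=run)
        paths = render_plots(
            profile,
            res.timeseries(),
            tmp_path,
            energy_table=energies.to_frame(),
            contact_order=res.most_contacted(),
            fmt="svg",
        )
        assert len(paths) == 3
        assert all(p.exists() and p.stat().st_size > 0 for p in paths)
        ms = ms_coefficient(profile)
        svg = (tmp_path / "titration_profile.svg").read_text()
        assert f"{ms.value:.4f}" in svg  # legend slope matches to 4 decimals

    def test_heatmap_with_few_contacts_shows_all(self, toy_system, tmp_path):
        run = self._run(toy_system, frames=4)
        profile = titration_profile(run)
        from ttmd.model import TTMD, TTMDResults

        res = TTMDResults(model=TTMD(toy_system), run=run)
        contacted = res.most_contacted()
        assert 0 < len(contacted) < 25
        paths = render_plots(
            profile,
            res.timeseries(),
            tmp_path,
            energy_table=res.energies().to_frame(),
            contact_order=contacted,
            fmt="svg",
        )
        svg = (tmp_path / "energy_heatmap.svg").read_text()
        for label in contacted:
            assert label in svg
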