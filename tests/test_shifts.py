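"""Referencing, methyl/ensemble averaging, frame planning, RMSD scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from nmrcsp.errors import ShiftDataError
from nmrcsp.shifts import (
    ShieldingTable,
    ShiftAssignment,
    ShiftTable,
    average_methyl_protons,
    compute_sigma_ref,
    ensemble_average,
    molecule_map_by_order,
    plan_frames,
    read_assignment_tsv,
    read_magres,
    read_shieldings_tsv,
    rmsd_shifts,
    shieldings_to_shifts,
    split_molecules,
    write_assignment_tsv,
    write_shieldings_tsv,
)


def table(rows, sid="s", **kwargs):
    return ShieldingTable(structure_id=sid, records=rows, **kwargs)


def assignment(rows):
    return ShiftAssignment(
        records=pd.DataFrame(rows, columns=["label", "element", "delta_exp_ppm"])
    )


def sigma_ref_oracle(sigmas, deltas):
    """Numeric slope-unity least squares: minimize Σ(δ − (c − σ))² over c."""
    sigmas = np.asarray(sigmas)
    deltas = np.asarray(deltas)

    def loss(c):
        return np.sum((deltas - (c - sigmas)) ** 2)

    res = minimize_scalar(loss, bounds=(0.0, 500.0), method="bounded",
                          options={"xatol": 1e-12})
    return res.x


class TestComputeSigmaRef:
    def test_single_point(self):
        ref = compute_sigma_ref(
            table([("C1", "C", 100.0)]), assignment([("C1", "C", 10.0)]), "C"
        )
        assert ref.sigma_ref == pytest.approx(110.0)
        assert ref.n_points == 1

    def test_three_point_closed_form(self):
        t = table([("C1", "C", 165.0), ("C2", "C", 170.0), ("C3", "C", 175.0)])
        a = assignment([("C1", "C", 5.0), ("C2", "C", 1.0), ("C3", "C", -4.0)])
        ref = compute_sigma_ref(t, a, "C")
        assert ref.sigma_ref == pytest.approx(170.0 + 2.0 / 3.0, abs=1e-9)

    def test_residuals_sum_to_zero(self):
        t = table([("C1", "C", 163.2), ("C2", "C", 171.8), ("C3", "C", 149.0)])
        a = assignment([("C1", "C", 7.1), ("C2", "C", -2.0), ("C3", "C", 21.4)])
        ref = compute_sigma_ref(t, a, "C")
        shifts = shieldings_to_shifts(t, {"C": ref})
        merged = shifts.records.merge(a.records, on=["label", "element"])
        resid = merged["delta_ppm"] - merged["delta_exp_ppm"]
        assert resid.mean() == pytest.approx(0.0, abs=1e-9)

    def test_pooling_across_candidates(self):
        t1 = table([("C1", "C", 100.0)], sid="a")
        t2 = table([("C1", "C", 120.0)], sid="b")
        a = assignment([("C1", "C", 10.0)])
        ref = compute_sigma_ref([t1, t2], a, "C")
        assert ref.sigma_ref == pytest.approx(120.0)  # mean of 110 and 130
        assert ref.n_points == 2

    def test_no_match_errors(self):
        with pytest.raises(ShiftDataError):
            compute_sigma_ref(
                table([("C1", "C", 100.0)]), assignment([("C9", "C", 1.0)]), "C"
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_closed_form_matches_numeric_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        sigmas = 100.0 + 80.0 * rng.random(n)
        deltas = 40.0 * rng.random(n) - 10.0
        rows = [(f"C{i}", "C", s) for i, s in enumerate(sigmas)]
        exp = [(f"C{i}", "C", d) for i, d in enumerate(deltas)]
        ref = compute_sigma_ref(table(rows), assignment(exp), "C")
        assert ref.sigma_ref == pytest.approx(
            sigma_ref_oracle(sigmas, deltas), abs=1e-6
        )


class TestShieldingsToShifts:
    def test_basic_and_fixed_point(self):
        t = table([("C1", "C", 100.0), ("C2", "C", 110.0)])
        out = shieldings_to_shifts(t, {"C": 110.0})
        assert list(out.records["delta_ppm"]) == pytest.approx([10.0, 0.0])

    def test_literature_reference_value(self):
        # MD-averaged 13C reference shielding of the tailored force field
        out = shieldings_to_shifts(table([("C1", "C", 100.0)]), {"C": 167.9})
        assert out.records["delta_ppm"][0] == pytest.approx(67.9)

    def test_missing_element_reference(self):
        with pytest.raises(ShiftDataError, match="H"):
            shieldings_to_shifts(table([("H1", "H", 30.0)]), {"C": 170.0})


class TestMethylAveraging:
    def _topology(self):
        from nmrcsp.crystio import Topology

        return Topology(
            bonds=set(),
            molecules=[["C1", "H1", "H2", "H3", "H4", "C2"]],
            methyl_groups=[("C1", ("H1", "H2", "H3"))],
        )

    def test_mean_and_locality(self):
        t = ShiftTable(
            structure_id="s",
            records=[
                ("H1", "H", 1.0),
                ("H2", "H", 2.0),
                ("H3", "H", 3.0),
                ("H4", "H", 5.0),
                ("C1", "C", 20.0),
            ],
        )
        out = average_methyl_protons(t, self._topology())
        values = dict(zip(out.records["label"], out.records["delta_ppm"]))
        assert values["H1"] == values["H2"] == values["H3"] == pytest.approx(2.0)
        assert values["H4"] == 5.0 and values["C1"] == 20.0

    def test_idempotent_and_mean_conserving(self):
        t = ShiftTable(
            structure_id="s",
            records=[("H1", "H", 0.3), ("H2", "H", 1.1), ("H3", "H", 2.2)],
        )
        once = average_methyl_protons(t, self._topology())
        twice = average_methyl_protons(once, self._topology())
        assert np.allclose(once.records["delta_ppm"], twice.records["delta_ppm"])
        assert once.records["delta_ppm"].mean() == pytest.approx(
            t.records["delta_ppm"].mean()
        )

    def test_partial_methyl_errors(self):
        t = ShiftTable(structure_id="s", records=[("H1", "H", 1.0), ("H2", "H", 2.0)])
        with pytest.raises(ShiftDataError, match="H3"):
            average_methyl_protons(t, self._topology())

    def test_commutes_with_referencing(self):
        rows = [("H1", "H", 29.0), ("H2", "H", 30.0), ("H3", "H", 31.5)]
        t = table(rows)
        top = self._topology()
        path_a = shieldings_to_shifts(average_methyl_protons(t, top), {"H": 31.0})
        path_b = average_methyl_protons(shieldings_to_shifts(t, {"H": 31.0}), top)
        assert np.allclose(path_a.records["delta_ppm"], path_b.records["delta_ppm"])


class TestPlanFrames:
    @pytest.mark.parametrize(
        "z,rep,n_frames,interval",
        [(2, (1, 1, 1), 24, 4.0), (4, (1, 1, 1), 12, 8.0), (1, (2, 2, 2), 6, 16.0)],
    )
    def test_standard_cases_give_48_spectra(self, z, rep, n_frames, interval):
        plan = plan_frames(z, rep)
        assert plan.n_frames == n_frames
        assert plan.interval_ps == pytest.approx(interval)
        assert plan.n_spectra == 48
        assert plan.n_frames * plan.interval_ps <= 100.0

    def test_generic_mode(self):
        plan = plan_frames(6)
        assert (plan.n_frames, plan.interval_ps) == (8, 12.0)
        assert plan.n_spectra == 48

    def test_non_dividing_molecule_count(self):
        with pytest.raises(ValueError, match="divide"):
            plan_frames(5)


class TestEnsembleAverage:
    def test_constant_tables(self):
        t = table([("C1", "C", 100.0)], frame_index=0, molecule_index=0)
        out = ensemble_average([t, t, t])
        assert out.records["sigma_ppm"][0] == pytest.approx(100.0)

    def test_hand_mean(self):
        tables = [
            table([("C1", "C", v)], frame_index=f, molecule_index=m)
            for v, (f, m) in zip(
                [100.0, 102.0, 101.0, 103.0],
                [(0, 0), (0, 1), (1, 0), (1, 1)],
            )
        ]
        out = ensemble_average(tables)
        assert out.records["sigma_ppm"][0] == pytest.approx(101.5)

    def test_single_table_identity(self):
        t = table([("C1", "C", 123.4), ("H1", "H", 28.0)])
        out = ensemble_average([t])
        assert np.allclose(out.records["sigma_ppm"], t.records["sigma_ppm"])

    def test_ragged_errors(self):
        t1 = table([("C1", "C", 100.0)])
        t2 = table([("C2", "C", 100.0)])
        with pytest.raises(ShiftDataError, match="ragged"):
            ensemble_average([t1, t2])

    def test_molecule_map_and_split(self):
        full = table(
            [("C1", "C", 100.0), ("C1_2", "C", 104.0)], sid="cand"
        )
        molecules = [["C1"], ["C1_2"]]
        parts = split_molecules(full, molecules)
        assert [p.molecule_index for p in parts] == [0, 1]
        mapping = molecule_map_by_order(["C1"], molecules)
        out = ensemble_average(parts, mapping)
        assert list(out.records["label"]) == ["C1"]
        assert out.records["sigma_ppm"][0] == pytest.approx(102.0)

    @pytest.mark.parametrize("n_frames", [4, 16, 64])
    def test_noise_shrinks_as_sqrt_n(self, n_frames):
        rng = np.random.default_rng(42)
        errors = []
        for _ in range(20):
            tables = [
                table([("C1", "C", 100.0 + rng.normal(0, 1.0))], frame_index=i)
                for i in range(n_frames)
            ]
            out = ensemble_average(tables)
            errors.append(abs(out.records["sigma_ppm"][0] - 100.0))
        rms = np.sqrt(np.mean(np.square(errors)))
        assert rms == pytest.approx(1.0 / np.sqrt(n_frames), rel=0.5)


class TestRmsdShifts:
    def _calc(self, rows):
        return ShiftTable(structure_id="s", records=rows)

    def test_exact_match_zero(self):
        calc = self._calc([("C1", "C", 10.0), ("C2", "C", 20.0)])
        a = assignment([("C1", "C", 10.0), ("C2", "C", 20.0)])
        res = rmsd_shifts(calc, a, "C")
        assert res.value == 0.0 and res.n_matched == 2

    def test_uniform_offset(self):
        calc = self._calc([(f"C{i}", "C", 10.0 + i + 1.0) for i in range(5)])
        a = assignment([(f"C{i}", "C", 10.0 + i) for i in range(5)])
        assert rmsd_shifts(calc, a, "C").value == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        calc = self._calc([("C1", "C", 10.0), ("C2", "C", 20.0), ("C3", "C", 30.0)])
        a = assignment([("C1", "C", 12.0), ("C2", "C", 19.0), ("C3", "C", 30.0)])
        assert rmsd_shifts(calc, a, "C").value == pytest.approx(
            np.sqrt(5.0 / 3.0), abs=1e-9
        )

    def test_order_and_extras_invariance(self):
        calc = self._calc([("C2", "C", 20.0), ("C1", "C", 10.0), ("H9", "H", 3.0)])
        a = assignment([("C1", "C", 12.0), ("C2", "C", 19.0), ("C7", "C", 99.0)])
        res = rmsd_shifts(calc, a, "C")
        assert res.n_matched == 2
        assert res.value == pytest.approx(np.sqrt(5.0 / 2.0))

    def test_no_match_errors(self):
        with pytest.raises(ShiftDataError):
            rmsd_shifts(self._calc([("C1", "C", 1.0)]), assignment([("H1", "H", 1.0)]), "H")


MAGRES = """#$magres-abinitio-v1.0
[atoms]
units lattice Angstrom
lattice 10 0 0 0 10 0 0 0 10
units atom Angstrom
atom C C 1 0.0 0.0 0.0
atom H H 1 1.0 0.0 0.0
[/atoms]
[magres]
units ms ppm
ms C 1 150.0 1.0 2.0 1.0 160.0 3.0 2.0 3.0 170.0
ms H 1 29.0 0.0 0.0 0.0 30.0 0.0 0.0 0.0 31.0
[/magres]
"""


class TestFileFormats:
    def test_magres_isotropic_is_trace_third(self):
        t = read_magres(MAGRES, structure_id="m")
        values = dict(zip(t.records["label"], t.records["sigma_ppm"]))
        assert values["C1"] == pytest.approx(160.0)
        assert values["H1"] == pytest.approx(30.0)
        assert list(t.records["element"]) == ["C", "H"]

    def test_magres_without_ms_errors(self):
        with pytest.raises(ShiftDataError):
            read_magres("[atoms]\n[/atoms]\n")

    def test_shielding_tsv_round_trip(self):
        tables = [
            table([("C1", "C", 100.123456)], sid="a", frame_index=0, molecule_index=0),
            table([("C1", "C", 101.0)], sid="a", frame_index=1, molecule_index=0),
            table([("C1", "C", 99.0)], sid="b"),
        ]
        back = read_shieldings_tsv(write_shieldings_tsv(tables))
        assert len(back) == 3
        assert back[0].structure_id == "a" and back[0].frame_index == 0
        assert back[2].frame_index is None
        assert back[0].records["sigma_ppm"][0] == pytest.approx(100.123456, abs=1e-6)

    def test_assignment_tsv_round_trip(self):
        a = assignment([("C1", "C", 12.3), ("H1", "H", 1.23)])
        back = read_assignment_tsv(write_assignment_tsv(a))
        assert np.allclose(back.records["delta_exp_ppm"], [12.3, 1.23])

    def test_bad_columns_rejected(self):
        with pytest.raises(ShiftDataError):
            read_assignment_tsv("a\tb\n1\t2\n")
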