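"""Generators: base crystal, forward model, trajectories, campaigns."""

import math
from dataclasses import replace

import numpy as np
import pytest

from nmrcsp.crystio import molecule_cart_coords, perceive_bonds
from nmrcsp.errors import CampaignError, TopologyError
from nmrcsp.shifts import ensemble_average, molecule_map_by_order, split_molecules
from nmrcsp.synthetic import (
    DESIGNATED_TORSION,
    SIGMA_REF_TRUE,
    CampaignConfig,
    DriftSchedule,
    JitterModel,
    PackingPerturbation,
    build_campaign,
    clean_asu_shifts,
    crystal_density,
    dihedral_angle,
    flip_torsion,
    forward_shieldings,
    forward_true_shifts,
    generate_candidates,
    generate_trajectory,
    make_campaign,
)
from nmrcsp.synthetic import _min_intermolecular_distance


class TestBaseCrystal:
    def test_topology(self, base, base_topology):
        assert base.z_value == 2 and base.z_prime == 1
        assert [len(m) for m in base_topology.molecules] == [23, 23]
        assert len(base_topology.methyl_groups) == 4

    def test_no_collisions(self, base, base_topology):
        assert _min_intermolecular_distance(base, base_topology) > 2.0

    def test_density_physical_range(self, base):
        assert 0.3 < crystal_density(base) < 2.0


class TestForwardModel:
    def test_zero_coefficients_zero_noise_gives_base_shifts(self, base, forward_model):
        model = replace(
            forward_model,
            conformation_terms=(),
            packing_coeff_h=0.0,
            noise_sd_h=0.0,
            noise_sd_c=0.0,
        )
        table = forward_shieldings(base, model)
        for _, row in table.records.iterrows():
            stem = row["label"].split("_")[0]
            expected = SIGMA_REF_TRUE[row["element"]] - model.base_shifts[stem]
            assert row["sigma_ppm"] == pytest.approx(expected, abs=1e-12)

    def test_same_seed_bit_identical(self, base, forward_model):
        t1 = forward_shieldings(base, forward_model)
        t2 = forward_shieldings(base, forward_model)
        assert (t1.records["sigma_ppm"] == t2.records["sigma_ppm"]).all()

    def test_noise_independent_of_frame_index(self, base, base_topology, forward_model):
        t0 = forward_shieldings(base, forward_model, frame_index=0, topology=base_topology)
        t9 = forward_shieldings(base, forward_model, frame_index=9, topology=base_topology)
        assert np.allclose(t0.records["sigma_ppm"], t9.records["sigma_ppm"])

    def test_symmetry_copies_share_model_error(self, base, base_topology, forward_model):
        noisy = forward_shieldings(base, forward_model, topology=base_topology)
        clean = forward_shieldings(
            base,
            replace(forward_model, noise_sd_h=0.0, noise_sd_c=0.0),
            topology=base_topology,
        )
        eps = dict(
            zip(noisy.records["label"], noisy.records["sigma_ppm"] - clean.records["sigma_ppm"])
        )
        for label in ("C1", "H21", "H51"):
            assert eps[label] == pytest.approx(eps[f"{label}_2"], abs=1e-12)

    def test_torsion_flip_moves_designated_carbon_9ppm(self, base, forward_model):
        flipped = flip_torsion(base)
        d0 = forward_true_shifts(base, forward_model)
        d1 = forward_true_shifts(flipped, forward_model)
        assert abs(d1["C1"] - d0["C1"]) == pytest.approx(
            forward_model.conformation_terms[0].coeff_ppm_per_rad * math.pi, abs=0.05
        )

    def test_flip_changes_torsion_by_pi(self, base, base_topology):
        flipped = flip_torsion(base)
        w0 = molecule_cart_coords(base, base_topology)
        w1 = molecule_cart_coords(flipped, perceive_bonds(flipped))
        phi0 = dihedral_angle(*(w0[a] for a in DESIGNATED_TORSION))
        phi1 = dihedral_angle(*(w1[a] for a in DESIGNATED_TORSION))
        delta = abs((phi1 - phi0 + math.pi) % (2 * math.pi) - math.pi)
        assert delta == pytest.approx(math.pi, abs=1e-6)

    def test_round_trip_identity_with_zero_noise(self, base, base_topology):
        """A perfect engine plus the averaging pipeline returns sigma_ref and
        zero RMSD exactly."""
        from nmrcsp.shifts import compute_sigma_ref, rmsd_shifts, shieldings_to_shifts
        from nmrcsp.shifts import average_methyl_protons
        from nmrcsp.synthetic import default_forward_model
        import pandas as pd
        from nmrcsp.shifts import ShiftAssignment

        model = replace(default_forward_model(seed=3), noise_sd_h=0.0, noise_sd_c=0.0)
        truth = clean_asu_shifts(base, model, base_topology)
        assignment = ShiftAssignment(
            records=pd.DataFrame(
                [(l, "H" if l.startswith("H") else "C", v) for l, v in truth.items()],
                columns=["label", "element", "delta_exp_ppm"],
            )
        )
        table = forward_shieldings(base, model, topology=base_topology)
        asu = ensemble_average(
            split_molecules(table, base_topology.molecules),
            molecule_map_by_order(base_topology.molecules[0], base_topology.molecules),
        )
        for el in ("H", "C"):
            ref = compute_sigma_ref(asu, assignment, el)
            assert ref.sigma_ref == pytest.approx(SIGMA_REF_TRUE[el], abs=1e-9)
        shifts = average_methyl_protons(
            shieldings_to_shifts(asu, SIGMA_REF_TRUE), base_topology
        )
        assert rmsd_shifts(shifts, assignment, "H").value == pytest.approx(0.0, abs=1e-9)
        assert rmsd_shifts(shifts, assignment, "C").value == pytest.approx(0.0, abs=1e-9)


class TestTrajectories:
    def test_all_zero_model_constant(self, base, base_topology):
        model = JitterModel(amplitude={"*": 0.0}, methyl_rotor_rate=0.0, n_frames=4)
        traj = generate_trajectory(base, model, topology=base_topology)
        for frame in traj.frames:
            assert np.allclose(
                frame.cart_coords(), base.cart_coords(), atol=1e-9
            ) or np.allclose(frame.frac_coords() % 1, base.frac_coords() % 1, atol=1e-9)

    def test_rotor_only_heavy_atoms_fixed_bonds_conserved(self, base, base_topology):
        model = JitterModel(
            amplitude={"*": 0.0}, methyl_rotor_rate=2.0, n_frames=6, seed=4
        )
        traj = generate_trajectory(base, model, topology=base_topology)
        base_whole = molecule_cart_coords(base, base_topology)
        labels = base.labels
        heavy = [l for l, e in zip(labels, base.elements) if e != "H"]
        methyl_h = {h for _, hs in base_topology.methyl_groups for h in hs}
        moved_any = False
        for frame in traj.frames:
            whole = molecule_cart_coords(frame, base_topology)
            for l in heavy:
                assert np.allclose(whole[l], base_whole[l], atol=1e-9)
            for carbon, hs in base_topology.methyl_groups:
                for h in hs:
                    d_frame = np.linalg.norm(whole[h] - whole[carbon])
                    d_base = np.linalg.norm(base_whole[h] - base_whole[carbon])
                    assert d_frame == pytest.approx(d_base, abs=1e-9)
                    if not np.allclose(whole[h], base_whole[h], atol=1e-6):
                        moved_any = True
        assert moved_any  # the rotor actually hopped at this rate
        assert methyl_h  # sanity: rotors exist

    def test_rotor_without_methyls_errors(self, cubic_cell):
        from conftest import make_crystal

        crystal = make_crystal(cubic_cell, [("C1", "C", (0.1, 0.1, 0.1))])
        with pytest.raises(TopologyError):
            generate_trajectory(crystal, JitterModel(methyl_rotor_rate=1.0))

    def test_rotor_averaging_converges_methyl_spread(self, base, base_topology):
        """Motional averaging drives the three methyl-H shieldings together."""
        from nmrcsp.synthetic import default_forward_model

        clean = replace(
            default_forward_model(seed=5), noise_sd_h=0.0, noise_sd_c=0.0
        )
        spreads = []
        for n_frames in (2, 8, 32):
            model = JitterModel(
                amplitude={"*": 0.0},
                methyl_rotor_rate=2.0,
                n_frames=n_frames,
                timestep_ps=4.0,
                seed=6,
            )
            traj = generate_trajectory(base, model, topology=base_topology)
            spectra = []
            for t, frame in enumerate(traj.frames):
                tab = forward_shieldings(
                    frame, clean, frame_index=t, topology=base_topology,
                    structure_id="conv",
                )
                spectra.extend(split_molecules(tab, base_topology.molecules))
            avg = ensemble_average(
                spectra,
                molecule_map_by_order(
                    base_topology.molecules[0], base_topology.molecules
                ),
                structure_id="conv",
            )
            values = dict(zip(avg.records["label"], avg.records["sigma_ppm"]))
            spread = max(
                np.ptp([values[h] for h in hs])
                for _, hs in base_topology.methyl_groups[:2]
            )
            spreads.append(spread)
        assert spreads[-1] < spreads[0]

    def test_drift_direction_default_separates_molecules(self, base, base_topology):
        model = JitterModel(
            amplitude={"*": 0.0},
            methyl_rotor_rate=0.0,
            n_frames=10,
            drift=DriftSchedule(displacement=1.0),
            seed=1,
        )
        traj = generate_trajectory(base, model, topology=base_topology)
        first = traj.frames[0].cart_coords()
        last = traj.frames[-1].cart_coords()
        moved = np.linalg.norm(last - first, axis=1)
        n_mol0 = len(base_topology.molecules[0])
        assert np.allclose(moved[:n_mol0], 1.0, atol=1e-9)
        assert np.allclose(moved[n_mol0:], 0.0, atol=1e-9)


class TestGenerateCandidates:
    def test_zero_perturbation_copies(self, base):
        cands = generate_candidates(
            base, 3, perturbation=PackingPerturbation(0.0, 0.0, 0.0), seed=0
        )
        assert len(cands) == 3
        for c in cands:
            assert np.allclose(c.frac_coords(), base.frac_coords(), atol=1e-12)

    def test_truth_is_unperturbed_and_decoys_differ(self, base):
        cands = generate_candidates(base, 4, seed=1)
        assert np.allclose(cands[0].frac_coords(), base.frac_coords())
        from nmrcsp.overlay import rmscd_crystals

        for decoy in cands[1:]:
            assert rmscd_crystals(cands[0], decoy).rmscd > 0.05

    def test_candidates_collision_free_with_intact_topology(self, base):
        cands = generate_candidates(base, 5, seed=2, n_torsion_flips=1)
        for c in cands:
            top = perceive_bonds(c)
            assert len(top.molecules) == 2
            assert len(top.methyl_groups) == 4
            assert _min_intermolecular_distance(c, top) >= 1.5

    def test_seeded_reproducibility(self, base):
        a = generate_candidates(base, 3, seed=3)
        b = generate_candidates(base, 3, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.frac_coords(), y.frac_coords())


class TestCampaign:
    def test_small_campaign_structure(self, small_campaign):
        camp = small_campaign
        assert len(camp.candidates) == 6
        assert camp.truth_id == "cand_00"
        assert camp.frame_plan.n_spectra == 48
        for c in camp.candidates:
            spectra = camp.frame_tables[("md", c.name)]
            assert len(spectra) == 48

    def test_decoys_meet_separation_floor(self, small_campaign):
        from nmrcsp.synthetic import _h_separation, default_forward_model

        camp = small_campaign
        model = default_forward_model(
            seed=camp.seed,
            noise_sd_h=camp.config.noise_sd_h,
            noise_sd_c=camp.config.noise_sd_c,
        )
        truth = clean_asu_shifts(camp.candidates[0], model)
        for decoy in camp.candidates[1:]:
            sep = _h_separation(clean_asu_shifts(decoy, model), truth)
            assert sep >= camp.config.min_h_separation_ppm

    def test_truth_lowest_energy_with_configured_gap(self, small_campaign):
        records = small_campaign.energies["reference"]
        energies = {r.structure_id: r.lattice_energy for r in records}
        assert min(energies, key=energies.get) == "cand_00"
        gap = sorted(energies.values())[1] - sorted(energies.values())[0]
        assert gap == pytest.approx(small_campaign.config.energy_gap)

    def test_make_campaign_writes_and_is_deterministic(self, tmp_path):
        config = CampaignConfig(n_candidates=3, n_torsion_flips=0, with_md=False)
        make_campaign(tmp_path / "a", config=config, seed=2)
        make_campaign(tmp_path / "b", config=config, seed=2)
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert "candidates.cif" in files and "manifest.yaml" in files
        for name in files:
            pa, pb = tmp_path / "a" / name, tmp_path / "b" / name
            if pa.is_file():
                assert pa.read_bytes() == pb.read_bytes()

    def test_make_campaign_refuses_existing_dir(self, tmp_path):
        out = tmp_path / "camp"
        config = CampaignConfig(n_candidates=2, n_torsion_flips=0, with_md=False)
        make_campaign(out, config=config, seed=0)
        with pytest.raises(CampaignError):
            make_campaign(out, config=config, seed=0)
        make_campaign(out, config=config, seed=0, overwrite=True)
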