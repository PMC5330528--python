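"""Synthetic study generator: candidate packings, forward-model shieldings,
assignments with a planted truth, and jitter/methyl-rotor trajectories.

This module stands in for the expensive physics of a real campaign (CSP
search, force-field MD, plane-wave DFT shielding calculations) with declared
statistical surrogates, so every pipeline stage is exercisable end to end:

* a small ester-like molecular crystal (two methyl rotors, an ester-linkage
  torsion) provides the structural substrate;
* the forward shift model makes ¹³C shifts conformation-dominated (a torsion
  term) and ¹H shifts packing-sensitive (an inverse-cube intermolecular
  proximity term), the qualitative physics that lets ¹H discriminate packings
  while ¹³C mostly cannot;
* per-nucleus Gaussian noise at benchmark scale emulates the systematic model
  error of the shielding calculation — it is drawn per (structure, nucleus)
  and held fixed across trajectory frames, since a model error does not
  average away under motional averaging;
* trajectories are harmonic jitter plus Poisson 120° methyl hops, with an
  optional coherent molecular slip as a phase-transition surrogate.

All generators are pure functions of (inputs, seed).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .crystio import (
    AtomSite,
    Crystal,
    Topology,
    UnitCell,
    min_image_vectors,
    molecule_cart_coords,
    perceive_bonds,
)
from .errors import CampaignError, TopologyError
from .shifts import ShieldingTable
from .trajectory import Trajectory

__all__ = [
    "base_crystal",
    "ASU_LABELS",
    "ForwardShiftModel",
    "ConformationTerm",
    "default_forward_model",
    "forward_shieldings",
    "JitterModel",
    "DriftSchedule",
    "generate_trajectory",
    "PackingPerturbation",
    "generate_candidates",
    "flip_torsion",
    "dihedral_angle",
    "forward_true_shifts",
    "crystal_density",
    "SIGMA_REF_TRUE",
]

#: atomic masses (u) for density bookkeeping
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

#: true reference shieldings used by the forward model (ppm)
SIGMA_REF_TRUE = {"H": 30.98, "C": 167.9}

#: minimum allowed intermolecular contact in generated packings, Å
MIN_CONTACT = 1.5


# ---------------------------------------------------------------------------
# Base molecule and crystal
# ---------------------------------------------------------------------------

# z-matrix of a methyl-hexanoate-like molecule: an ester head (carbonyl +
# O-methyl), four backbone CH2 groups and an end methyl. That gives ten
# spectroscopically distinct proton environments and seven carbons, a
# complexity scale comparable to a small pharmaceutical. Entries: label,
# element, then (distance ref, Å), (angle ref, deg), (dihedral ref, deg).
_ZMATRIX = [
    ("C6", "C", None, None, None),
    ("C5", "C", ("C6", 1.52), None, None),
    ("O2", "O", ("C6", 1.34), ("C5", 111.0), None),
    ("O1", "O", ("C6", 1.22), ("C5", 125.0), ("O2", 180.0)),
    ("C7", "C", ("O2", 1.44), ("C6", 116.0), ("C5", 180.0)),
    ("C4", "C", ("C5", 1.53), ("C6", 112.5), ("O2", 180.0)),
    ("C3", "C", ("C4", 1.53), ("C5", 112.5), ("C6", 180.0)),
    ("C2", "C", ("C3", 1.53), ("C4", 112.5), ("C5", 180.0)),
    ("C1", "C", ("C2", 1.53), ("C3", 112.5), ("C4", 180.0)),
    ("H51", "H", ("C5", 1.09), ("C6", 109.0), ("O2", 60.0)),
    ("H52", "H", ("C5", 1.09), ("C6", 109.0), ("O2", -60.0)),
    ("H41", "H", ("C4", 1.09), ("C5", 109.0), ("C6", 60.0)),
    ("H42", "H", ("C4", 1.09), ("C5", 109.0), ("C6", -60.0)),
    ("H31", "H", ("C3", 1.09), ("C4", 109.0), ("C5", 60.0)),
    ("H32", "H", ("C3", 1.09), ("C4", 109.0), ("C5", -60.0)),
    ("H21", "H", ("C2", 1.09), ("C3", 109.0), ("C4", 60.0)),
    ("H22", "H", ("C2", 1.09), ("C3", 109.0), ("C4", -60.0)),
    ("H11", "H", ("C1", 1.09), ("C2", 109.5), ("C3", 60.0)),
    ("H12", "H", ("C1", 1.09), ("C2", 109.5), ("C3", 180.0)),
    ("H13", "H", ("C1", 1.09), ("C2", 109.5), ("C3", 300.0)),
    ("H71", "H", ("C7", 1.09), ("O2", 109.5), ("C6", 60.0)),
    ("H72", "H", ("C7", 1.09), ("O2", 109.5), ("C6", 180.0)),
    ("H73", "H", ("C7", 1.09), ("O2", 109.5), ("C6", 300.0)),
]

#: canonical asymmetric-unit site order
ASU_LABELS = [
    "C1", "C2", "C3", "C4", "C5", "C6", "C7", "O1", "O2",
    "H11", "H12", "H13", "H21", "H22", "H31", "H32",
    "H41", "H42", "H51", "H52", "H71", "H72", "H73",
]

#: the backbone torsion that dominates the ¹³C response of the end methyl
DESIGNATED_TORSION = ("C1", "C2", "C3", "C4")


def _place_zmatrix(entries) -> dict[str, np.ndarray]:
    """Natural-extension-reference-frame placement of a z-matrix."""
    pos: dict[str, np.ndarray] = {}
    for i, (label, _el, dist, ang, dih) in enumerate(entries):
        if i == 0:
            pos[label] = np.zeros(3)
        elif i == 1:
            ref, r = dist
            pos[label] = pos[ref] + np.array([r, 0.0, 0.0])
        else:
            ref_c, r = dist
            ref_b, theta = ang
            if dih is None:
                # place in the xy-plane
                c, b = pos[ref_c], pos[ref_b]
                bc = (c - b) / np.linalg.norm(c - b)
                t = math.radians(theta)
                perp = np.array([-bc[1], bc[0], 0.0])
                if np.linalg.norm(perp) < 1e-12:
                    perp = np.array([0.0, 1.0, 0.0])
                perp /= np.linalg.norm(perp)
                pos[label] = c + r * (-bc * math.cos(t) + perp * math.sin(t))
            else:
                ref_a, phi = dih
                a, b, c = pos[ref_a], pos[ref_b], pos[ref_c]
                t, p = math.radians(theta), math.radians(phi)
                bc = (c - b) / np.linalg.norm(c - b)
                ab = b - a
                n = np.cross(ab, bc)
                n /= np.linalg.norm(n)
                m = np.cross(n, bc)
                d_local = np.array(
                    [-r * math.cos(t), r * math.sin(t) * math.cos(p), r * math.sin(t) * math.sin(p)]
                )
                pos[label] = c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
    return pos


def molecule_coords() -> tuple[list[str], list[str], np.ndarray]:
    """Labels, elements and Cartesian coordinates of the base molecule,
    centred on its centroid, in canonical site order."""
    pos = _place_zmatrix(_ZMATRIX)
    elem = {label: el for label, el, *_ in _ZMATRIX}
    coords = np.array([pos[l] for l in ASU_LABELS])
    coords -= coords.mean(axis=0)
    return list(ASU_LABELS), [elem[l] for l in ASU_LABELS], coords


def base_crystal() -> Crystal:
    """The reference packing: Z = 2, Z' = 1, monoclinic-like P1 cell.

    Molecule 2 is the 180°-rotated copy of molecule 1 at the body-diagonal
    offset, a screw-axis-like motif. Site labels of the second molecule carry
    the ``_2`` suffix, mirroring symmetry-expansion naming.
    """
    labels, elements, coords = molecule_coords()
    cell = UnitCell(13.2, 9.0, 7.8, 90.0, 96.0, 90.0)
    m = cell.matrix
    inv = np.linalg.inv(m)
    sites = []
    rot_x = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), math.pi)
    placements = [
        (np.array([0.25, 0.27, 0.25]), np.eye(3), ""),
        (np.array([0.75, 0.77, 0.75]), rot_x, "_2"),
    ]
    for cen_frac, rot, suffix in placements:
        cart = coords @ rot.T + cen_frac @ m
        frac = cart @ inv
        for l, e, f in zip(labels, elements, frac):
            sites.append(AtomSite(label=l + suffix, element=e, frac=f))
    return Crystal(cell=cell, sites=sites, z_value=2, z_prime=1, name="base")


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in radians (IUPAC convention)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.atan2(y, x)


# ---------------------------------------------------------------------------
# Forward shift model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConformationTerm:
    """Torsion-driven shift contribution on designated nuclei.

    The listed nuclei acquire ``coeff_ppm_per_rad × |wrap(φ − φ_ref)|`` ppm,
    so a 180° conformational flip at ~2.9 ppm/rad moves them by ≈ 9 ppm —
    the scale of an axial/equatorial N-methyl carbon change.
    """

    torsion: tuple[str, str, str, str]
    nuclei: tuple[str, ...]
    coeff_ppm_per_rad: float
    reference_angle_rad: float


@dataclass(frozen=True)
class ForwardShiftModel:
    """Declared statistical forward model from structure to chemical shift.

    δ(nucleus) = base + conformation terms (¹³C-dominant) + packing term
    (¹H only) and σ = σ_ref_true − δ + systematic per-nucleus noise.
    """

    base_shifts: dict[str, float]
    conformation_terms: tuple[ConformationTerm, ...] = ()
    packing_coeff_h: float = 12.0  # ppm·Å³ on Σ 1/r³ over intermolecular contacts
    packing_cutoff: float = 6.0  # Å
    noise_sd_h: float = 0.3
    noise_sd_c: float = 1.5
    seed: int = 0


# typical solution-state values for an aliphatic methyl ester, ppm
_BASE_SHIFTS = {
    "C1": 14.0, "C2": 22.4, "C3": 31.4, "C4": 24.7, "C5": 34.1,
    "C6": 174.3, "C7": 51.4,
    "H11": 0.86, "H12": 0.89, "H13": 0.92,
    "H21": 1.28, "H22": 1.32,
    "H31": 1.27, "H32": 1.31,
    "H41": 1.60, "H42": 1.64,
    "H51": 2.28, "H52": 2.32,
    "H71": 3.63, "H72": 3.66, "H73": 3.69,
}


def default_forward_model(seed: int = 0, **overrides) -> ForwardShiftModel:
    """Model with the default ester shifts and the designated torsion term.

    The torsion reference is the base molecule's own geometry, so the truth
    conformation carries no conformational penalty by construction.
    """
    labels, _els, coords = molecule_coords()
    pos = dict(zip(labels, coords))
    ref = dihedral_angle(*(pos[a] for a in DESIGNATED_TORSION))
    term = ConformationTerm(
        torsion=DESIGNATED_TORSION,
        nuclei=("C1",),
        coeff_ppm_per_rad=2.9,
        reference_angle_rad=ref,
    )
    kwargs = dict(
        base_shifts=dict(_BASE_SHIFTS),
        conformation_terms=(term,),
        seed=seed,
    )
    kwargs.update(overrides)
    return ForwardShiftModel(**kwargs)


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode())


def _asu_label_of(label: str) -> str:
    """Strip molecule-copy suffixes (C1_2 → C1)."""
    return label.split("_", 1)[0]


def _packing_sums(crystal: Crystal, topology: Topology, cutoff: float) -> np.ndarray:
    """Σ 1/r³ over intermolecular contacts within the cutoff, per site.

    Periodic images are included (a molecule's own image in a neighbouring
    cell is an intermolecular contact).
    """
    m = crystal.cell.matrix
    inv = np.linalg.inv(m)
    whole = molecule_cart_coords(crystal, topology)
    index_of = {l: i for i, l in enumerate(crystal.labels)}
    n = len(index_of)
    cart = np.empty((n, 3))
    mol_of = np.empty(n, dtype=int)
    span = 0.0
    for k, comp in enumerate(topology.molecules):
        coords = np.array([whole[l] for l in comp])
        cen_frac = coords.mean(axis=0) @ inv
        coords = coords + (cen_frac % 1.0 - cen_frac) @ m
        span = max(span, float(np.ptp(coords, axis=0).max()))
        for l, c in zip(comp, coords):
            cart[index_of[l]] = c
            mol_of[index_of[l]] = k
    widths = crystal.cell.perpendicular_widths()
    nshift = np.maximum(1, np.ceil((cutoff + span) / widths).astype(int))
    shifts = np.array(
        [
            [i, j, k]
            for i in range(-nshift[0], nshift[0] + 1)
            for j in range(-nshift[1], nshift[1] + 1)
            for k in range(-nshift[2], nshift[2] + 1)
        ],
        dtype=float,
    )
    sums = np.zeros(n)
    for s in shifts:
        offset = s @ m
        dmat = cart[None, :, :] + offset - cart[:, None, :]
        r = np.linalg.norm(dmat, axis=2)
        same_mol = mol_of[:, None] == mol_of[None, :]
        zero_shift = not s.any()
        mask = (r < cutoff) & (r > 1e-6)
        if zero_shift:
            mask &= ~same_mol
        contrib = np.where(mask, 1.0 / np.maximum(r, 1e-6) ** 3, 0.0)
        sums += contrib.sum(axis=1)
    return sums


def forward_true_shifts(
    crystal: Crystal,
    model: ForwardShiftModel,
    topology: Topology | None = None,
) -> dict[str, float]:
    """Noise-free forward-model shifts per site label of the (P1) crystal."""
    if topology is None:
        topology = perceive_bonds(crystal)
    whole = molecule_cart_coords(crystal, topology)
    deltas: dict[str, float] = {}
    elem_of = dict(zip(crystal.labels, crystal.elements))

    for label in crystal.labels:
        base = model.base_shifts.get(_asu_label_of(label))
        if base is None:
            if elem_of[label] in ("H", "C"):
                raise TopologyError(f"no base shift for nucleus {label}")
            continue  # unscored elements (O, N, ...) carry no shift
        deltas[label] = base

    # conformation terms, evaluated per molecule copy
    label_set_of_mol = [set(c) for c in topology.molecules]
    for term in model.conformation_terms:
        for comp, labels_set in zip(topology.molecules, label_set_of_mol):
            names = {}
            for l in comp:
                names.setdefault(_asu_label_of(l), l)
            try:
                quad = [names[a] for a in term.torsion]
            except KeyError:
                continue
            phi = dihedral_angle(*(whole[q] for q in quad))
            dev = abs(_wrap_angle(phi - term.reference_angle_rad))
            for nuc in term.nuclei:
                if nuc in names:
                    deltas[names[nuc]] += term.coeff_ppm_per_rad * dev

    # packing term on hydrogens, centred per molecule copy: the bulk
    # (density-like) component of the proximity sum is taken as absorbed
    # into the base shift, so only the differential packing pattern remains
    if model.packing_coeff_h != 0.0:
        sums = dict(zip(crystal.labels, _packing_sums(crystal, topology, model.packing_cutoff)))
        for comp in topology.molecules:
            h_labels = [l for l in comp if elem_of[l] == "H"]
            if not h_labels:
                continue
            mean_sum = float(np.mean([sums[l] for l in h_labels]))
            for l in h_labels:
                deltas[l] += model.packing_coeff_h * (sums[l] - mean_sum)
    return deltas


def _wrap_angle(x: float) -> float:
    return (x + math.pi) % (2 * math.pi) - math.pi


def forward_shieldings(
    crystal: Crystal,
    model: ForwardShiftModel,
    sigma_ref_true: dict[str, float] | None = None,
    frame_index: int | None = None,
    topology: Topology | None = None,
    structure_id: str | None = None,
) -> ShieldingTable:
    """Per-nucleus shieldings σ = σ_ref_true − δ_true + noise for one structure.

    The Gaussian noise is systematic: drawn per (structure id, nucleus, model
    seed) and independent of ``frame_index``, so the frames of one structure
    carry the same model error. ``structure_id`` defaults to the crystal name
    and is what the noise is keyed on (pass the parent candidate's id when
    shielding individual trajectory frames). Bit-identical for identical
    (structure, seed).
    """
    sigma_ref_true = sigma_ref_true or SIGMA_REF_TRUE
    structure_id = structure_id or crystal.name
    deltas = forward_true_shifts(crystal, model, topology=topology)
    elem_of = dict(zip(crystal.labels, crystal.elements))
    rng = np.random.default_rng([model.seed, _stable_hash(structure_id or "anon")])
    # one systematic error per spectroscopically distinct nucleus: symmetry
    # copies see the same environment, and the three protons of a methyl
    # rotor exchange into a single distinct shift, so both share one error
    # draw. Draw in sorted key order so the draw is geometry-independent.
    if topology is None:
        topology = perceive_bonds(crystal)
    methyl_key: dict[str, str] = {}
    for c_label, hs in topology.methyl_groups:
        for h in hs:
            methyl_key[_asu_label_of(h)] = f"{_asu_label_of(c_label)}@methylH"
    asu_of = {
        l: methyl_key.get(_asu_label_of(l), _asu_label_of(l))
        for l in crystal.labels
    }
    eps_of: dict[str, float] = {}
    for asu in sorted(set(asu_of.values())):
        eps_of[asu] = rng.normal(0.0, 1.0)
    rows = []
    for label in crystal.labels:
        el = elem_of[label]
        if el not in sigma_ref_true:
            continue
        noise_sd = model.noise_sd_h if el == "H" else model.noise_sd_c
        eps = eps_of[asu_of[label]] * noise_sd
        rows.append((label, el, sigma_ref_true[el] - deltas[label] + eps))
    return ShieldingTable(
        structure_id=structure_id,
        records=rows,
        frame_index=frame_index,
    )


# ---------------------------------------------------------------------------
# Trajectories: jitter + methyl rotors + optional drift
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DriftSchedule:
    """Coherent molecular slip, the phase-transition surrogate.

    ``displacement`` Å are applied to one molecule, ramped linearly over the
    first ``ramp_fraction`` of the run and then held. The default direction
    (None) is along the centroid-separation axis from that molecule to the
    rest of the cell — a packing slip that a rigid overlay cannot absorb.
    """

    displacement: float = 1.0
    molecule_index: int = 0
    direction: tuple[float, float, float] | None = None
    ramp_fraction: float = 0.1


@dataclass(frozen=True)
class JitterModel:
    """Statistical motional sampler (no forces, no thermostat).

    ``amplitude`` maps element symbol to the Gaussian sd of the Cartesian
    displacement; the ``*`` entry is the default. Methyl rotors hop ±120°
    as a Poisson process of the given rate.
    """

    amplitude: dict[str, float] = field(
        default_factory=lambda: {"H": 0.15, "*": 0.08}
    )
    methyl_rotor_rate: float = 0.1  # jumps/ps
    n_frames: int = 24
    timestep_ps: float = 4.0
    drift: DriftSchedule | None = None
    seed: int = 0

    def sd_of(self, element: str) -> float:
        return self.amplitude.get(element, self.amplitude.get("*", 0.0))


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def generate_trajectory(
    crystal: Crystal,
    model: JitterModel,
    topology: Topology | None = None,
) -> Trajectory:
    """Generate frames: base structure + methyl hops + drift + Gaussian jitter.

    With zero amplitude, zero rotor rate and no drift, all frames equal the
    input structure. The cell is held fixed (small-cell constant-volume
    sampling).
    """
    if topology is None:
        topology = perceive_bonds(crystal)
    if model.methyl_rotor_rate > 0 and not topology.methyl_groups:
        raise TopologyError("methyl rotor requested but no methyl groups perceived")

    whole = molecule_cart_coords(crystal, topology)
    labels = crystal.labels
    elements = crystal.elements
    base = np.array([whole[l] for l in labels])
    index_of = {l: i for i, l in enumerate(labels)}
    inv = np.linalg.inv(crystal.cell.matrix)
    rng = np.random.default_rng([model.seed, _stable_hash(crystal.name or "anon")])

    # methyl rotor geometry: axis from the single heavy neighbour to the carbon
    rotors = []
    neighbour_of = {}
    for c_label, hs in topology.methyl_groups:
        heavies = [
            nb for nb in topology.neighbours(c_label)
            if dict(zip(labels, elements))[nb] != "H"
        ]
        neighbour_of[c_label] = heavies[0]
        rotors.append((c_label, hs, heavies[0]))

    drift_vec = np.zeros(3)
    drift_atoms: list[int] = []
    if model.drift is not None and model.drift.displacement != 0.0:
        comp = topology.molecules[model.drift.molecule_index]
        drift_atoms = [index_of[l] for l in comp]
        if model.drift.direction is not None:
            direction = np.asarray(model.drift.direction, dtype=float)
        else:
            cen_mol = base[drift_atoms].mean(axis=0)
            others = [i for i in range(len(labels)) if i not in set(drift_atoms)]
            cen_rest = base[others].mean(axis=0) if others else cen_mol + np.array([1.0, 0, 0])
            direction = cen_mol - cen_rest
            if np.linalg.norm(direction) < 1e-9:
                direction = np.array([1.0, 0.0, 0.0])
        direction = direction / np.linalg.norm(direction)
        drift_vec = model.drift.displacement * direction

    sds = np.array([model.sd_of(e) for e in elements])
    rotor_state = np.zeros(len(rotors))  # cumulative hop count (signed)
    frames = []
    for t in range(model.n_frames):
        coords = base.copy()
        # methyl hops accumulated between frames (none before frame 0)
        if t > 0 and model.methyl_rotor_rate > 0:
            hops = rng.poisson(model.methyl_rotor_rate * model.timestep_ps, size=len(rotors))
            signs = rng.choice([-1, 1], size=len(rotors))
            rotor_state += signs * hops
        for (c_label, hs, heavy), k in zip(rotors, rotor_state):
            if k == 0:
                continue
            c_pos = base[index_of[c_label]]
            axis = c_pos - base[index_of[heavy]]
            rot = _rotation_about_axis(axis, k * 2.0 * math.pi / 3.0)
            for h in hs:
                i = index_of[h]
                coords[i] = c_pos + rot @ (base[i] - c_pos)
        if drift_atoms:
            frac_done = 1.0 if model.n_frames == 1 else t / (model.n_frames - 1)
            factor = min(1.0, frac_done / max(model.drift.ramp_fraction, 1e-9))
            coords[drift_atoms] += factor * drift_vec
        if sds.any():
            coords = coords + rng.normal(0.0, 1.0, size=coords.shape) * sds[:, None]
        frac = coords @ inv
        sites = [
            AtomSite(label=l, element=e, frac=f)
            for l, e, f in zip(labels, elements, frac)
        ]
        frames.append(
            Crystal(cell=crystal.cell, sites=sites, name=f"{crystal.name}_f{t}")
        )
    return Trajectory(
        frames=frames, timestep_ps=model.timestep_ps, name=crystal.name
    )


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PackingPerturbation:
    """Rigid-molecule packing perturbation amplitudes."""

    translation: float = 1.2  # Å, Gaussian sd per molecule
    rotation_deg: float = 30.0  # Gaussian sd of the rotation-vector magnitude
    cell_frac: float = 0.04  # uniform relative cell-length perturbation


def _min_intermolecular_distance(crystal: Crystal, topology: Topology) -> float:
    """Smallest contact between different molecules, periodic images included
    (a molecule's own image in a neighbouring cell counts as intermolecular)."""
    # whole-molecule coordinates with centroids wrapped into the cell, so a
    # molecule straddling the boundary is not split into spurious "images"
    whole = molecule_cart_coords(crystal, topology)
    m = crystal.cell.matrix
    inv = np.linalg.inv(m)
    cart_list, mols = [], []
    for k, comp in enumerate(topology.molecules):
        c = np.array([whole[l] for l in comp])
        cen_frac = c.mean(axis=0) @ inv
        c = c + (cen_frac % 1.0 - cen_frac) @ m
        cart_list.append(c)
        mols.extend([k] * len(comp))
    cart = np.vstack(cart_list)
    mol_of = np.array(mols)
    same_mol = mol_of[:, None] == mol_of[None, :]
    eye = np.eye(len(cart), dtype=bool)
    # shift range must cover molecules longer than a cell axis
    span = max(float(np.ptp(c, axis=0).max()) for c in cart_list)
    widths = crystal.cell.perpendicular_widths()
    nmax = np.maximum(1, np.ceil((span + 3.0) / widths).astype(int))
    best = np.inf
    for sa in range(-nmax[0], nmax[0] + 1):
        for sb in range(-nmax[1], nmax[1] + 1):
            for sc in range(-nmax[2], nmax[2] + 1):
                offset = np.array([sa, sb, sc], dtype=float) @ m
                r = np.linalg.norm(cart[None, :, :] + offset - cart[:, None, :], axis=2)
                skip = eye | same_mol if (sa, sb, sc) == (0, 0, 0) else eye & False
                r = np.where(skip, np.inf, r)
                best = min(best, float(r.min()))
    return best


def _perturb_crystal(
    crystal: Crystal,
    topology: Topology,
    perturbation: PackingPerturbation,
    rng: np.random.Generator,
    name: str,
) -> Crystal:
    whole = molecule_cart_coords(crystal, topology)
    labels = crystal.labels
    old_m = crystal.cell.matrix
    inv_old = np.linalg.inv(old_m)
    scale = 1.0 + rng.uniform(-perturbation.cell_frac, perturbation.cell_frac, size=3)
    cell = UnitCell(
        crystal.cell.a * scale[0],
        crystal.cell.b * scale[1],
        crystal.cell.c * scale[2],
        *crystal.cell.angles,
    )
    m = cell.matrix
    inv = np.linalg.inv(m)
    new_frac: dict[str, np.ndarray] = {}
    for comp in topology.molecules:
        coords = np.array([whole[l] for l in comp])
        cen = coords.mean(axis=0)
        cen_frac = cen @ inv_old
        rotvec = rng.normal(0.0, math.radians(perturbation.rotation_deg), size=3)
        angle = np.linalg.norm(rotvec)
        rot = (
            _rotation_about_axis(rotvec, angle) if angle > 1e-12 else np.eye(3)
        )
        shift = rng.normal(0.0, perturbation.translation, size=3)
        new_cen = cen_frac @ m + shift
        new_coords = (coords - cen) @ rot.T + new_cen
        for l, c in zip(comp, new_coords):
            new_frac[l] = c @ inv
    sites = [
        AtomSite(label=s.label, element=s.element, frac=new_frac[s.label])
        for s in crystal.sites
    ]
    return replace(crystal, cell=cell, sites=sites, name=name)


def flip_torsion(
    crystal: Crystal,
    torsion: tuple[str, str, str, str] = DESIGNATED_TORSION,
    angle_deg: float = 180.0,
    topology: Topology | None = None,
) -> Crystal:
    """Rotate, in every molecule copy, the subtree on the near side of the
    torsion's central bond about that bond (a conformational flip)."""
    if topology is None:
        topology = perceive_bonds(crystal)
    whole = molecule_cart_coords(crystal, topology)
    new_cart = dict(whole)
    inv = np.linalg.inv(crystal.cell.matrix)
    for comp in topology.molecules:
        names = {}
        for l in comp:
            names.setdefault(_asu_label_of(l), l)
        try:
            a, b, c, d = (names[x] for x in torsion)
        except KeyError:
            continue
        # component containing b once the b-c bond is cut
        adjacency = {l: topology.neighbours(l) for l in comp}
        moving = {b}
        stack = [b]
        while stack:
            cur = stack.pop()
            for nb in adjacency.get(cur, []):
                if nb == c or nb in moving or nb not in adjacency:
                    continue
                moving.add(nb)
                stack.append(nb)
        axis = whole[c] - whole[b]
        rot = _rotation_about_axis(axis, math.radians(angle_deg))
        origin = whole[b]
        for l in moving:
            new_cart[l] = origin + rot @ (whole[l] - origin)
    sites = [
        AtomSite(label=s.label, element=s.element, frac=new_cart[s.label] @ inv)
        for s in crystal.sites
    ]
    return replace(crystal, sites=sites)


def generate_candidates(
    base: Crystal,
    n: int,
    perturbation: PackingPerturbation | None = None,
    seed: int = 0,
    n_torsion_flips: int = 0,
    max_attempts: int = 100,
    accept=None,
) -> list[Crystal]:
    """Emulate a CSP candidate list: ``n`` distinct packings of one molecule.

    Candidate 0 is the unperturbed truth. The remaining candidates are
    rigid-molecule rotations/translations with cell perturbations; the last
    ``n_torsion_flips`` of them additionally have the designated torsion
    flipped by 180° (conformational decoys). Packings with intermolecular
    contacts below 1.5 Å, with broken bond topology, or rejected by the
    optional ``accept(crystal)`` predicate are resampled.
    """
    if not base.is_p1():
        raise CampaignError("base crystal must be P1")
    perturbation = perturbation or PackingPerturbation()
    topology = perceive_bonds(base)
    ref_counts = (len(topology.molecules), len(topology.methyl_groups))
    rng = np.random.default_rng([seed, _stable_hash("candidates")])
    out = [base.with_name("cand_00")]
    for i in range(1, n):
        flip = i >= n - n_torsion_flips
        name = f"cand_{i:02d}"
        for attempt in range(max_attempts):
            cand = _perturb_crystal(base, topology, perturbation, rng, name)
            if flip:
                # flip along the reference bond graph: re-perceiving bonds on
                # a perturbed packing can pick up contact bonds that corrupt
                # the moving subtree
                cand = flip_torsion(cand, topology=topology)
            try:
                top_c = perceive_bonds(cand)
            except TopologyError:
                continue
            if (len(top_c.molecules), len(top_c.methyl_groups)) != ref_counts:
                continue
            if _min_intermolecular_distance(cand, top_c) < MIN_CONTACT:
                continue
            if accept is not None and not accept(cand):
                continue
            out.append(cand)
            break
        else:
            raise CampaignError(
                f"could not generate a collision-free packing for {name} "
                f"after {max_attempts} attempts"
            )
    return out


def crystal_density(crystal: Crystal) -> float:
    """Density in g/cm³ from the embedded atomic masses."""
    mass = sum(ATOMIC_MASSES[e] for e in crystal.elements)
    # 1 u / Å³ = 1.66053906660 g/cm³
    return 1.66053906660 * mass / crystal.cell.volume


# ---------------------------------------------------------------------------
# Full campaigns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CampaignConfig:
    """Study conditions for a synthetic candidate-selection campaign."""

    n_candidates: int = 26
    n_torsion_flips: int = 3
    perturbation: PackingPerturbation = field(default_factory=PackingPerturbation)
    min_h_separation_ppm: float = 0.5
    noise_sd_h: float = 0.3
    noise_sd_c: float = 1.5
    # experimental-side noise on the assignment, chosen so the correct
    # candidate's total expected RMSD lands at the benchmark-window mean
    # (0.33 ppm ¹H, 1.9 ppm ¹³C) together with the calculation noise above
    assignment_noise_h: float = 0.137
    assignment_noise_c: float = 1.166
    energy_gap: float = 4.43  # kJ/mol between landscape ranks 1 and 2
    md_approaches: tuple[str, ...] = ("md",)
    energy_ff_error_sds: tuple[float, ...] = (1.3, 2.5)
    with_md: bool = True


@dataclass
class Campaign:
    """Everything the scoring pipeline consumes, with a planted truth."""

    config: CampaignConfig
    seed: int
    candidates: list[Crystal]
    truth_id: str
    assignment: "ShiftAssignment"
    topologies: dict[str, Topology]
    asu_labels: list[str]
    static_tables: dict[str, ShieldingTable]
    trajectories: dict[tuple[str, str], Trajectory]
    frame_tables: dict[tuple[str, str], list[ShieldingTable]]
    energies: dict[str, list]
    frame_plan: "FramePlan"
    manifest: dict


def clean_asu_shifts(
    crystal: Crystal,
    model: ForwardShiftModel,
    topology: Topology | None = None,
) -> dict[str, float]:
    """Noise-free asymmetric-unit shifts: copy-averaged and methyl-averaged.

    This is what a perfect shielding engine plus the standard averaging
    pipeline would report for the structure.
    """
    from .shifts import (
        average_methyl_protons,
        ensemble_average,
        molecule_map_by_order,
        shieldings_to_shifts,
        split_molecules,
    )

    if topology is None:
        topology = perceive_bonds(crystal)
    clean = replace(model, noise_sd_h=0.0, noise_sd_c=0.0)
    table = forward_shieldings(crystal, clean, topology=topology)
    asu = topology.molecules[0]
    mapping = molecule_map_by_order(asu, topology.molecules)
    averaged = ensemble_average(
        split_molecules(table, topology.molecules), mapping
    )
    shifts = shieldings_to_shifts(averaged, SIGMA_REF_TRUE)
    shifts = average_methyl_protons(shifts, topology)
    return dict(
        zip(shifts.records["label"], shifts.records["delta_ppm"])
    )


def _h_separation(shifts_a: dict[str, float], shifts_b: dict[str, float]) -> float:
    hs = [l for l in shifts_a if l.startswith("H")]
    dev = [shifts_a[l] - shifts_b[l] for l in hs]
    return float(np.sqrt(np.mean(np.square(dev))))


def build_campaign(
    config: CampaignConfig | None = None, seed: int = 0
) -> Campaign:
    """Generate a full in-memory campaign.

    Candidate 0 is the planted truth; the experimental assignment is the
    truth's clean forward shifts. Every decoy is resampled until its clean
    ¹H shifts are at least ``min_h_separation_ppm`` RMS away from the truth,
    so packings are distinguishable in principle. Pure function of
    (config, seed).
    """
    from .shifts import ShiftAssignment, plan_frames

    config = config or CampaignConfig()
    base = base_crystal()
    model = default_forward_model(
        seed=seed, noise_sd_h=config.noise_sd_h, noise_sd_c=config.noise_sd_c
    )
    clean_truth = clean_asu_shifts(base, model)

    def separated(cand: Crystal) -> bool:
        return (
            _h_separation(clean_asu_shifts(cand, model), clean_truth)
            >= config.min_h_separation_ppm
        )

    candidates = generate_candidates(
        base,
        config.n_candidates,
        perturbation=config.perturbation,
        seed=seed,
        n_torsion_flips=config.n_torsion_flips,
        accept=separated,
    )
    truth = candidates[0]
    topologies = {c.name: perceive_bonds(c) for c in candidates}
    asu_labels = list(topologies[truth.name].molecules[0])

    # experimental assignment: truth's clean shifts plus experiment-side noise,
    # drawn per spectroscopically distinct nucleus (methyl protons share one
    # observed shift, hence one draw)
    top_truth = topologies[truth.name]
    methyl_key = {}
    for c_label, hs in top_truth.methyl_groups:
        for h in hs:
            methyl_key[_asu_label_of(h)] = f"{_asu_label_of(c_label)}@methylH"
    rng_assign = np.random.default_rng([seed, _stable_hash("assignment")])
    eps_assign: dict[str, float] = {}
    keys = sorted({methyl_key.get(l, l) for l in clean_truth})
    for key in keys:
        eps_assign[key] = rng_assign.normal(0.0, 1.0)
    rows = []
    for l, v in clean_truth.items():
        el = "H" if l.startswith("H") else "C"
        sd = config.assignment_noise_h if el == "H" else config.assignment_noise_c
        rows.append((l, el, v + sd * eps_assign[methyl_key.get(l, l)]))
    import pandas as pd

    assignment = ShiftAssignment(
        records=pd.DataFrame(rows, columns=["label", "element", "delta_exp_ppm"]),
        source="synthetic truth + experiment-scale noise",
    )

    # static shieldings: one full-cell table per candidate per approach tag
    # one shielding model for every approach: static and MD-averaged runs share
    # the same shielding protocol, so a structure's systematic per-nucleus
    # model error is common to all approaches (only the geometry sampling
    # differs between them)
    static_tables = {
        c.name: forward_shieldings(c, model, topology=topologies[c.name])
        for c in candidates
    }

    plan = plan_frames(base.z_value or 2)
    trajectories: dict[tuple[str, str], Trajectory] = {}
    frame_tables: dict[tuple[str, str], list[ShieldingTable]] = {}
    if config.with_md:
        from .shifts import split_molecules

        for tag in config.md_approaches:
            approach_model = model
            for c in candidates:
                top = topologies[c.name]
                jitter = JitterModel(
                    n_frames=plan.n_frames,
                    timestep_ps=plan.interval_ps,
                    seed=_mix_seed(seed, f"{tag}:{c.name}"),
                )
                traj = generate_trajectory(c, jitter, topology=top)
                trajectories[(tag, c.name)] = traj
                spectra: list[ShieldingTable] = []
                for t, frame in enumerate(traj.frames):
                    table = forward_shieldings(
                        frame,
                        approach_model,
                        frame_index=t,
                        topology=top,
                        structure_id=c.name,
                    )
                    spectra.extend(split_molecules(table, top.molecules))
                frame_tables[(tag, c.name)] = spectra

    energies = _campaign_energies(config, seed, candidates)

    manifest = {
        "seed": seed,
        "n_candidates": config.n_candidates,
        "n_torsion_flips": config.n_torsion_flips,
        "truth_id": truth.name,
        "noise_sd_h": config.noise_sd_h,
        "noise_sd_c": config.noise_sd_c,
        "min_h_separation_ppm": config.min_h_separation_ppm,
        "energy_gap": config.energy_gap,
        "md_approaches": list(config.md_approaches),
        "frame_plan": {
            "n_frames": plan.n_frames,
            "interval_ps": plan.interval_ps,
            "molecules_per_frame": plan.molecules_per_frame,
        },
    }
    return Campaign(
        config=config,
        seed=seed,
        candidates=candidates,
        truth_id=truth.name,
        assignment=assignment,
        topologies=topologies,
        asu_labels=asu_labels,
        static_tables=static_tables,
        trajectories=trajectories,
        frame_tables=frame_tables,
        energies=energies,
        frame_plan=plan,
        manifest=manifest,
    )


def _mix_seed(seed: int, tag: str) -> int:
    return (seed * 1_000_003 + _stable_hash(tag)) % (2**31 - 1)


def _campaign_energies(config: CampaignConfig, seed: int, candidates) -> dict:
    """Reference lattice energies (truth lowest, configured rank-1/2 gap)
    plus per-force-field energies with method-specific error."""
    from .ranking import EnergyRecord

    rng = np.random.default_rng([seed, _stable_hash("energies")])
    ids = [c.name for c in candidates]
    e0 = -100.0
    e_ref = {ids[0]: e0}
    if len(ids) > 1:
        e_ref[ids[1]] = e0 + config.energy_gap
        extra = np.sort(rng.uniform(0.5, 12.0, size=len(ids) - 2))
        for name, de in zip(ids[2:], extra):
            e_ref[name] = e0 + config.energy_gap + float(de)
    densities = {c.name: crystal_density(c) for c in candidates}
    out = {
        "reference": [
            EnergyRecord(i, e_ref[i], density=densities[i], method="reference")
            for i in ids
        ]
    }
    for tag, sd in zip(config.md_approaches, config.energy_ff_error_sds):
        offset = rng.uniform(20.0, 60.0)
        noise = rng.normal(0.0, sd, size=len(ids))
        out[tag] = [
            EnergyRecord(
                i, e_ref[i] + offset + float(n), density=densities[i], method=tag
            )
            for i, n in zip(ids, noise)
        ]
    return out


def make_campaign(
    out_dir,
    config: CampaignConfig | None = None,
    seed: int = 0,
    overwrite: bool = False,
) -> Campaign:
    """Generate a campaign and write every input format the pipeline reads.

    Writes candidates.cif, assignment.tsv, static_shieldings.tsv, one
    md_shieldings_<tag>.tsv per approach, trajectories/<tag>/<id>.xyz,
    energies_<method>.tsv and manifest.yaml. Same (config, seed) twice gives
    byte-identical output.
    """
    import pathlib

    import yaml

    from .crystio import write_cif
    from .shifts import write_assignment_tsv, write_shieldings_tsv
    from .trajectory import write_extxyz

    out = pathlib.Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise CampaignError(f"output directory {out} exists; pass overwrite=True")
    campaign = build_campaign(config, seed)
    out.mkdir(parents=True, exist_ok=True)
    (out / "candidates.cif").write_text(write_cif(campaign.candidates))
    (out / "assignment.tsv").write_text(write_assignment_tsv(campaign.assignment))
    (out / "static_shieldings.tsv").write_text(
        write_shieldings_tsv(list(campaign.static_tables.values()))
    )
    for tag in campaign.config.md_approaches:
        tables = []
        for c in campaign.candidates:
            tables.extend(campaign.frame_tables.get((tag, c.name), []))
        if tables:
            (out / f"md_shieldings_{tag}.tsv").write_text(
                write_shieldings_tsv(tables)
            )
        tdir = out / "trajectories" / tag
        tdir.mkdir(parents=True, exist_ok=True)
        for c in campaign.candidates:
            traj = campaign.trajectories.get((tag, c.name))
            if traj is not None:
                (tdir / f"{c.name}.xyz").write_text(write_extxyz(traj))
    for method, records in campaign.energies.items():
        rows = "\n".join(
            f"{r.structure_id}\t{r.lattice_energy:.6f}\t"
            f"{'' if r.density is None else f'{r.density:.6f}'}"
            for r in records
        )
        (out / f"energies_{method}.tsv").write_text(
            "structure_id\tlattice_energy\tdensity\n" + rows + "\n"
        )
    (out / "manifest.yaml").write_text(
        yaml.safe_dump(campaign.manifest, sort_keys=True)
    )
    return campaign
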