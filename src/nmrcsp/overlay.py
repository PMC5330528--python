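"""Rigid superposition, RMSCD between crystals, trajectory averages.

The packing-similarity currency is the root-mean-square Cartesian
displacement (RMSCD) over matched non-hydrogen atoms after an optimal proper
rigid-body overlay. Trajectory average structures unwrap fractional
coordinates frame-to-frame before averaging, since averaging wrapped
coordinates across a periodic boundary is the classic failure mode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .crystio import (
    Crystal,
    Topology,
    UnitCell,
    molecule_cart_coords,
    perceive_bonds,
    read_cif,
)
from .errors import NmrCspError, TrajectoryError
from .trajectory import Trajectory

__all__ = [
    "OverlayResult",
    "AverageStructure",
    "PhaseTransitionReport",
    "superpose",
    "rmscd_crystals",
    "rmscd_from_cif_files",
    "average_structure",
    "flag_phase_transition",
]

#: exact molecule-assignment search is used up to this many molecules per cell
EXACT_ASSIGNMENT_LIMIT = 8

#: default threshold separating stable from transitioned average structures, Å
RMSCD_TRANSITION_THRESHOLD = 0.35

#: default relative cell-length drift threshold for transition flagging
CELL_DRIFT_THRESHOLD = 0.05


@dataclass(frozen=True)
class OverlayResult:
    """Optimal rigid overlay of two matched coordinate sets.

    ``rotation`` and ``translation`` map the second set onto the first
    (row-vector convention: ``b @ rotation + translation ≈ a``).
    """

    rmscd: float
    rotation: np.ndarray
    translation: np.ndarray
    n_atoms: int
    mode: str = "coords"


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> OverlayResult:
    """Least-squares rigid superposition (Kabsch with reflection guard).

    Both inputs are (n, 3) Cartesian arrays already in correspondence
    (row i of one matches row i of the other). Returns the proper rotation
    and translation minimizing the RMS displacement, and that minimum.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"matched (n,3) coordinate sets required, got {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n == 0:
        raise ValueError("cannot superpose empty coordinate sets")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    ac = a - cen_a
    bc = b - cen_b
    h = bc.T @ ac
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    moved = bc @ rot
    rmscd = float(np.sqrt(np.mean(np.sum((moved - ac) ** 2, axis=1))))
    translation = cen_a - cen_b @ rot
    return OverlayResult(rmscd=rmscd, rotation=rot, translation=translation, n_atoms=n)


# ---------------------------------------------------------------------------
# RMSCD between crystals
# ---------------------------------------------------------------------------


def _wrapped_molecule_coords(
    crystal: Crystal, topology: Topology
) -> list[tuple[list[str], list[str], np.ndarray]]:
    """Per-molecule (labels, elements, cart coords) with centroids wrapped to [0,1).

    Wrapping molecule centroids makes the comparison invariant to moving any
    molecule by a full lattice vector.
    """
    whole = molecule_cart_coords(crystal, topology)
    elem_of = dict(zip(crystal.labels, crystal.elements))
    inv = np.linalg.inv(crystal.cell.matrix)
    out = []
    for comp in topology.molecules:
        coords = np.array([whole[l] for l in comp])
        cen_frac = coords.mean(axis=0) @ inv
        shift = (cen_frac % 1.0 - cen_frac) @ crystal.cell.matrix
        out.append((comp, [elem_of[l] for l in comp], coords + shift))
    return out


def rmscd_crystals(
    a: Crystal,
    b: Crystal,
    mode: str = "cell_cluster",
    label_map: dict[str, str] | None = None,
) -> OverlayResult:
    """RMSCD between two crystals over matched non-hydrogen atoms.

    ``mode='molecule'`` overlays a single molecule (the first of each
    structure); ``mode='cell_cluster'`` overlays all molecules of one unit
    cell, choosing the molecule-to-molecule assignment that minimizes the
    RMSCD (exhaustive up to ``EXACT_ASSIGNMENT_LIMIT`` molecules, greedy
    centroid matching beyond). Atoms correspond by identical labels, by
    ``label_map`` (a → b), or by site order within matched molecules.
    """
    if mode not in ("molecule", "cell_cluster"):
        raise ValueError(f"unknown mode {mode!r}")
    top_a = perceive_bonds(a)
    top_b = perceive_bonds(b)
    mols_a = _wrapped_molecule_coords(a, top_a)
    mols_b = _wrapped_molecule_coords(b, top_b)

    if label_map is not None:
        coords_b_of = {}
        for labels, elements, coords in mols_b:
            for l, e, c in zip(labels, elements, coords):
                coords_b_of[l] = (e, c)
        sel_a, sel_b = [], []
        for labels, elements, coords in mols_a if mode == "cell_cluster" else mols_a[:1]:
            for l, e, c in zip(labels, elements, coords):
                if e == "H":
                    continue
                if l not in label_map or label_map[l] not in coords_b_of:
                    continue
                sel_a.append(c)
                sel_b.append(coords_b_of[label_map[l]][1])
        if not sel_a:
            raise NmrCspError("label_map matches no common non-H atoms")
        res = superpose(np.array(sel_a), np.array(sel_b))
        return replace(res, mode=mode)

    def heavy(labels, elements, coords):
        keep = [i for i, e in enumerate(elements) if e != "H"]
        return [elements[i] for i in keep], coords[keep]

    heavy_a = [heavy(*m) for m in mols_a]
    heavy_b = [heavy(*m) for m in mols_b]

    if mode == "molecule":
        ea, ca = heavy_a[0]
        eb, cb = heavy_b[0]
        if ea != eb:
            raise NmrCspError("first molecules have different non-H element sequences")
        return replace(superpose(ca, cb), mode=mode)

    if len(heavy_a) != len(heavy_b):
        raise NmrCspError(
            f"cell_cluster mode needs equal molecule counts ({len(heavy_a)} vs {len(heavy_b)})"
        )
    keys_a = [tuple(e) for e, _ in heavy_a]
    keys_b = [tuple(e) for e, _ in heavy_b]
    if sorted(keys_a) != sorted(keys_b):
        raise NmrCspError("molecules of the two cells have different compositions")

    n_mol = len(heavy_a)
    if n_mol <= EXACT_ASSIGNMENT_LIMIT:
        best: OverlayResult | None = None
        for perm in itertools.permutations(range(n_mol)):
            if any(keys_a[i] != keys_b[perm[i]] for i in range(n_mol)):
                continue
            ca = np.vstack([heavy_a[i][1] for i in range(n_mol)])
            cb = np.vstack([heavy_b[perm[i]][1] for i in range(n_mol)])
            res = superpose(ca, cb)
            if best is None or res.rmscd < best.rmscd:
                best = res
        assert best is not None
        return replace(best, mode=mode)

    # greedy centroid assignment for large clusters
    cen_a = np.array([c.mean(axis=0) for _, c in heavy_a])
    cen_b = np.array([c.mean(axis=0) for _, c in heavy_b])
    cen_a -= cen_a.mean(axis=0)
    cen_b -= cen_b.mean(axis=0)
    unused = set(range(n_mol))
    perm = []
    for i in range(n_mol):
        cand = [j for j in unused if keys_b[j] == keys_a[i]]
        j = min(cand, key=lambda j: np.linalg.norm(cen_a[i] - cen_b[j]))
        perm.append(j)
        unused.discard(j)
    ca = np.vstack([c for _, c in heavy_a])
    cb = np.vstack([heavy_b[j][1] for j in perm])
    return replace(superpose(ca, cb), mode=mode)


def rmscd_from_cif_files(
    path_a: str, path_b: str, mode: str = "cell_cluster"
) -> OverlayResult:
    """RMSCD between the first blocks of two CIF files (convenience loader)."""
    from pathlib import Path

    from .crystio import to_p1

    a = to_p1(read_cif(Path(path_a).read_text())[0])
    b = to_p1(read_cif(Path(path_b).read_text())[0])
    return rmscd_crystals(a, b, mode=mode)


# ---------------------------------------------------------------------------
# Trajectory averages and phase-transition flagging
# ---------------------------------------------------------------------------


@dataclass
class AverageStructure:
    """Arithmetic average of an unwrapped trajectory."""

    crystal: Crystal
    n_frames: int
    max_drift: float  # largest per-atom Cartesian displacement from frame 0, Å


def unwrap_frac(frac_stack: np.ndarray) -> np.ndarray:
    """Unwrap frame-to-frame: shift each coordinate by integers so every atom
    moves minimally between consecutive frames (reference is frame 0)."""
    out = np.array(frac_stack, dtype=float)
    for t in range(1, out.shape[0]):
        d = out[t] - out[t - 1]
        out[t] -= np.round(d)
    return out


def average_structure(traj: Trajectory) -> AverageStructure:
    """Mean cell parameters and mean unwrapped fractional coordinates."""
    stack = unwrap_frac(traj.frac_stack())
    mean_frac = stack.mean(axis=0)
    cells = np.array(
        [[*fr.cell.lengths, *fr.cell.angles] for fr in traj.frames]
    ).mean(axis=0)
    cell = UnitCell(*cells)
    ref = traj.frames[0]
    sites = [replace(s, frac=mean_frac[i]) for i, s in enumerate(ref.sites)]
    crystal = replace(ref, cell=cell, sites=sites, name=(traj.name or ref.name) + "_avg")
    disp = (mean_frac - stack[0]) @ cell.matrix
    max_drift = float(np.max(np.linalg.norm(disp, axis=1))) if len(sites) else 0.0
    return AverageStructure(crystal=crystal, n_frames=len(traj), max_drift=max_drift)


@dataclass(frozen=True)
class PhaseTransitionReport:
    """Diagnostics for in-run packing changes."""

    flag: bool
    rmscd: float
    max_cell_drift: float  # max relative deviation of averaged cell lengths
    rmscd_threshold: float
    cell_drift_threshold: float
    n_frames: int


def flag_phase_transition(
    traj: Trajectory,
    reference: Crystal,
    rmscd_threshold: float = RMSCD_TRANSITION_THRESHOLD,
    cell_drift_threshold: float = CELL_DRIFT_THRESHOLD,
    mode: str = "cell_cluster",
) -> PhaseTransitionReport:
    """Flag a trajectory whose average structure drifted off its reference.

    Flags when the average-structure RMSCD versus the reference exceeds the
    threshold, or when any averaged cell length deviates from the reference
    by more than the relative drift threshold.
    """
    if len(traj.frames[0].sites) != len(reference.sites):
        raise TrajectoryError("reference and trajectory frames have different atom counts")
    avg = average_structure(traj)
    res = rmscd_crystals(avg.crystal, reference, mode=mode)
    ref_len = np.array(reference.cell.lengths)
    avg_len = np.array(avg.crystal.cell.lengths)
    drift = float(np.max(np.abs(avg_len - ref_len) / ref_len))
    flag = res.rmscd > rmscd_threshold or drift > cell_drift_threshold
    return PhaseTransitionReport(
        flag=flag,
        rmscd=res.rmscd,
        max_cell_drift=drift,
        rmscd_threshold=rmscd_threshold,
        cell_drift_threshold=cell_drift_threshold,
        n_frames=len(traj),
    )
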