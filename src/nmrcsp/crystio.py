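"""Crystal data model and CIF I/O.

Crystals are stored as a unit cell plus labelled sites in fractional
coordinates. Fractional coordinates are the storage convention throughout the
package; conversion to Cartesian uses the standard lower-triangular cell
matrix with the *a* axis along x, so a single orientation convention is used
for overlays and trajectory work.

Symmetry handling is deliberately explicit: operators are taken verbatim from
the CIF operator loop (identity assumed when absent) and :func:`to_p1`
expands them. There is no space-group lookup by symbol.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .elements import covalent_radius
from .errors import CifParseError, DisorderError, SymmetryError

__all__ = [
    "UnitCell",
    "AtomSite",
    "Crystal",
    "Topology",
    "read_cif",
    "write_cif",
    "to_p1",
    "build_supercell",
    "perceive_bonds",
    "molecule_cart_coords",
    "min_image_vectors",
]

#: Å threshold below which two symmetry images of like element are one site.
DUPLICATE_SITE_TOL = 0.01

#: default bond-perception tolerance added to the covalent-radius sum, Å.
BOND_TOLERANCE = 0.40


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angles must lie in (0, 180): {self}")
        if self.volume <= 0:
            raise ValueError(f"cell has non-positive volume: {self}")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    @property
    def matrix(self) -> np.ndarray:
        """Row-vector cell matrix, lower triangular, a along x.

        Cartesian = fractional @ matrix.
        """
        al, be, ga = (math.radians(x) for x in self.angles)
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        cx = self.c * cb
        cy = self.c * (ca - cb * cg) / sg
        cz2 = self.c**2 - cx**2 - cy**2
        if cz2 <= 0:
            raise ValueError(f"degenerate cell: {self}")
        return np.array(
            [
                [self.a, 0.0, 0.0],
                [self.b * cg, self.b * sg, 0.0],
                [cx, cy, math.sqrt(cz2)],
            ]
        )

    @property
    def volume(self) -> float:
        al, be, ga = (math.radians(x) for x in self.angles)
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        arg = 1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    def perpendicular_widths(self) -> np.ndarray:
        """Perpendicular distance between opposite faces along each axis.

        width_i = V / area of the face spanned by the other two axes. This is
        the side-to-side distance of the cell, which for oblique cells is
        smaller than the axis length.
        """
        m = self.matrix
        v = abs(np.linalg.det(m))
        widths = []
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            widths.append(v / np.linalg.norm(np.cross(m[j], m[k])))
        return np.array(widths)


@dataclass
class AtomSite:
    """One labelled site: element symbol plus fractional coordinates."""

    label: str
    element: str
    frac: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float)
        if self.frac.shape != (3,):
            raise ValueError(f"site {self.label}: frac must be a 3-vector")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"site {self.label}: occupancy must be in (0, 1]")


IDENTITY_OP = "x,y,z"


@dataclass
class Crystal:
    """A crystal structure: cell, sites, explicit symmetry operators.

    ``z_value`` (molecules per cell) and ``z_prime`` (molecules per asymmetric
    unit) are metadata; they are checked against perceived topology where the
    pipeline needs them but are not enforced here.
    """

    cell: UnitCell
    sites: list[AtomSite]
    symmetry_ops: list[str] = field(default_factory=lambda: [IDENTITY_OP])
    z_value: int | None = None
    z_prime: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate site labels in {self.name!r}: {dupes}")

    # -- coordinate access -------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sites]

    @property
    def elements(self) -> list[str]:
        return [s.element for s in self.sites]

    def frac_coords(self) -> np.ndarray:
        return np.array([s.frac for s in self.sites], dtype=float)

    def cart_coords(self) -> np.ndarray:
        return self.frac_coords() @ self.cell.matrix

    def is_p1(self) -> bool:
        return len(self.symmetry_ops) == 1 and _normalize_op(
            self.symmetry_ops[0]
        ) == IDENTITY_OP

    def wrapped(self) -> "Crystal":
        """Copy with fractional coordinates canonicalized to [0, 1)."""
        sites = [replace(s, frac=s.frac % 1.0) for s in self.sites]
        return replace(self, sites=sites)

    def check_ordered(self) -> None:
        """Refuse disordered structures: the pipeline treats ordered candidates only."""
        bad = [s.label for s in self.sites if s.occupancy < 1.0]
        if bad:
            raise DisorderError(
                f"structure {self.name!r} has partial occupancies on {bad}; "
                "disordered structures are not supported"
            )

    def with_name(self, name: str) -> "Crystal":
        return replace(self, name=name)


# ---------------------------------------------------------------------------
# CIF reading and writing (gemmi does the syntax; we map to the data model)
# ---------------------------------------------------------------------------

_CELL_ITEMS = {
    "a": "_cell_length_a",
    "b": "_cell_length_b",
    "c": "_cell_length_c",
    "alpha": "_cell_angle_alpha",
    "beta": "_cell_angle_beta",
    "gamma": "_cell_angle_gamma",
}

_SYMOP_TAGS = (
    "_symmetry_equiv_pos_as_xyz",
    "_space_group_symop_operation_xyz",
)


def _cif_number(raw: str, context: str) -> float:
    """Parse a CIF numeric value, tolerating su parentheses like 1.234(5)."""
    value = raw.split("(")[0]
    try:
        return float(value)
    except ValueError:
        raise CifParseError(f"{context}: cannot parse number {raw!r}") from None


def read_cif(text: str) -> list[Crystal]:
    """Parse a (possibly multi-block) CIF document into Crystal objects.

    Each data block yields one Crystal named after the block. Symmetry
    operators are taken from the operator loop when present, otherwise the
    identity is assumed. Site labels are preserved verbatim.
    """
    try:
        doc = gemmi.cif.read_string(text)
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise CifParseError(f"malformed CIF: {exc}") from exc
    crystals = []
    for block in doc:
        crystals.append(_block_to_crystal(block))
    if not crystals:
        raise CifParseError("CIF document contains no data blocks")
    return crystals


def _block_to_crystal(block: "gemmi.cif.Block") -> Crystal:
    name = block.name
    cell_kwargs = {}
    for attr, tag in _CELL_ITEMS.items():
        raw = block.find_value(tag)
        if raw is None:
            raise CifParseError(f"block {name!r}: missing {tag}")
        cell_kwargs[attr] = _cif_number(raw, f"block {name!r} {tag}")
    cell = UnitCell(**cell_kwargs)

    table = block.find(
        "_atom_site_",
        ["label", "type_symbol", "fract_x", "fract_y", "fract_z", "?occupancy"],
    )
    if len(table) == 0:
        raise CifParseError(f"block {name!r}: missing or empty _atom_site_ loop")
    sites = []
    for row in table:
        label = gemmi.cif.as_string(row[0])
        element = gemmi.cif.as_string(row[1])
        frac = [_cif_number(row[i], f"block {name!r} site {label}") for i in (2, 3, 4)]
        occ = 1.0
        if table.has_column(5) and row[5] not in (".", "?"):
            occ = _cif_number(row[5], f"block {name!r} site {label} occupancy")
        sites.append(AtomSite(label=label, element=element, frac=frac, occupancy=occ))

    ops = []
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        ops = [gemmi.cif.as_string(v) for v in col]
        if ops:
            break
    if not ops:
        ops = [IDENTITY_OP]

    z_value = block.find_value("_cell_formula_units_Z")
    try:
        return Crystal(
            cell=cell,
            sites=sites,
            symmetry_ops=ops,
            z_value=int(z_value) if z_value not in (None, ".", "?") else None,
            name=name,
        )
    except ValueError as exc:
        raise CifParseError(f"block {name!r}: {exc}") from exc


def write_cif(crystals: Crystal | list[Crystal]) -> str:
    """Serialize one or more crystals to a multi-block CIF string."""
    if isinstance(crystals, Crystal):
        crystals = [crystals]
    doc = gemmi.cif.Document()
    for i, crystal in enumerate(crystals):
        block = doc.add_new_block(crystal.name or f"structure_{i}")
        for attr, tag in _CELL_ITEMS.items():
            block.set_pair(tag, f"{getattr(crystal.cell, attr):.6f}")
        if crystal.z_value is not None:
            block.set_pair("_cell_formula_units_Z", str(crystal.z_value))
        op_loop = block.init_loop("", ["_space_group_symop_operation_xyz"])
        for op in crystal.symmetry_ops:
            op_loop.add_row([gemmi.cif.quote(op)])
        loop = block.init_loop(
            "_atom_site_", ["label", "type_symbol", "fract_x", "fract_y", "fract_z", "occupancy"]
        )
        for s in crystal.sites:
            loop.add_row(
                [s.label, s.element]
                + [f"{x:.6f}" for x in s.frac]
                + [f"{s.occupancy:.4f}"]
            )
    return doc.as_string()


# ---------------------------------------------------------------------------
# Symmetry expansion
# ---------------------------------------------------------------------------


def _normalize_op(op: str) -> str:
    try:
        return gemmi.Op(op).triplet()
    except Exception as exc:
        raise SymmetryError(f"cannot parse symmetry operator {op!r}: {exc}") from exc


def to_p1(crystal: Crystal) -> Crystal:
    """Apply all symmetry operators, merge duplicate images, return a P1 crystal.

    Site order is operator-major (all sites under the first operator, then the
    second, ...), which keeps symmetry copies of one molecule contiguous and
    in asymmetric-unit site order. Images of like element closer than
    ``DUPLICATE_SITE_TOL`` Å (special positions) are merged.
    """
    ops = [gemmi.Op(_normalize_op(op)) for op in crystal.symmetry_ops]
    if crystal.is_p1():
        return replace(crystal, symmetry_ops=[IDENTITY_OP])

    m = crystal.cell.matrix
    new_sites: list[AtomSite] = []
    kept_frac: list[np.ndarray] = []
    kept_elem: list[str] = []
    for k, op in enumerate(ops):
        for site in crystal.sites:
            frac = np.array(op.apply_to_xyz(list(site.frac))) % 1.0
            dup = False
            for f_prev, e_prev in zip(kept_frac, kept_elem):
                if e_prev != site.element:
                    continue
                d = frac - f_prev
                d -= np.round(d)
                if np.linalg.norm(d @ m) < DUPLICATE_SITE_TOL:
                    dup = True
                    break
            if dup:
                continue
            label = site.label if k == 0 else f"{site.label}_{k + 1}"
            new_sites.append(
                AtomSite(label=label, element=site.element, frac=frac, occupancy=site.occupancy)
            )
            kept_frac.append(frac)
            kept_elem.append(site.element)
    return replace(crystal, sites=new_sites, symmetry_ops=[IDENTITY_OP])


# ---------------------------------------------------------------------------
# Supercells
# ---------------------------------------------------------------------------


def build_supercell(
    crystal: Crystal,
    min_span: float | None = None,
    replication: tuple[int, int, int] | None = None,
) -> tuple[Crystal, tuple[int, int, int]]:
    """Replicate a P1 crystal into a supercell.

    With ``min_span`` (Å), the replication triple is the smallest integer
    triple such that every perpendicular face-to-face width of the supercell
    is at least ``min_span``. An explicit ``replication`` overrides this (the
    mode used when the replication is dictated externally, e.g. a fixed
    molecule count).
    """
    if not crystal.is_p1():
        raise SymmetryError("build_supercell requires a P1 crystal; run to_p1 first")
    if crystal.cell.volume <= 0:
        raise ValueError("degenerate cell with zero volume")
    if replication is None:
        if min_span is None or min_span <= 0:
            raise ValueError("need min_span > 0 or an explicit replication")
        widths = crystal.cell.perpendicular_widths()
        replication = tuple(
            max(1, math.ceil(min_span / w - 1e-9)) for w in widths
        )
    na, nb, nc = replication
    if min(replication) < 1:
        raise ValueError(f"replication must be positive: {replication}")

    n = np.array(replication, dtype=float)
    new_cell = UnitCell(
        crystal.cell.a * na,
        crystal.cell.b * nb,
        crystal.cell.c * nc,
        *crystal.cell.angles,
    )
    sites = []
    single = replication == (1, 1, 1)
    idx = 0
    for ta in range(na):
        for tb in range(nb):
            for tc in range(nc):
                shift = np.array([ta, tb, tc], dtype=float)
                for s in crystal.sites:
                    label = s.label if single else f"{s.label}_t{idx}"
                    sites.append(
                        AtomSite(
                            label=label,
                            element=s.element,
                            frac=(s.frac + shift) / n,
                            occupancy=s.occupancy,
                        )
                    )
                idx += 1
    z = crystal.z_value * na * nb * nc if crystal.z_value is not None else None
    out = replace(crystal, cell=new_cell, sites=sites, z_value=z)
    return out, replication


# ---------------------------------------------------------------------------
# Bond perception and topology
# ---------------------------------------------------------------------------


@dataclass
class Topology:
    """Bond graph of a P1 crystal.

    ``molecules`` partitions site labels into connected components (periodic
    minimum-image bonds included, so a molecule wrapped across the boundary is
    one component). A methyl group is a carbon bonded to exactly three
    hydrogens and exactly one heavy atom.
    """

    bonds: set[frozenset[str]]
    molecules: list[list[str]]
    methyl_groups: list[tuple[str, tuple[str, str, str]]]

    def neighbours(self, label: str) -> list[str]:
        out = []
        for b in self.bonds:
            if label in b:
                (other,) = b - {label}
                out.append(other)
        return sorted(out)


def min_image_vectors(dfrac: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Minimum-image Cartesian vectors for an array of fractional differences.

    Uses the rounded-fraction convention (exact for orthogonal cells, standard
    for modestly oblique ones at bond-length scales).
    """
    d = np.asarray(dfrac, dtype=float)
    d = d - np.round(d)
    return d @ cell.matrix


def perceive_bonds(crystal: Crystal, tolerance: float = BOND_TOLERANCE) -> Topology:
    """Perceive bonds by covalent-radius sums under periodic minimum image.

    Two sites are bonded iff their minimum-image distance is at most
    r_cov(i) + r_cov(j) + tolerance.
    """
    if not crystal.is_p1():
        raise SymmetryError("perceive_bonds requires a P1 crystal; run to_p1 first")
    labels = crystal.labels
    elements = crystal.elements
    radii = np.array([covalent_radius(e) for e in elements])
    frac = crystal.frac_coords()
    n = len(labels)

    bonds: set[frozenset[str]] = set()
    adjacency: dict[str, list[str]] = {l: [] for l in labels}
    for i in range(n):
        d = min_image_vectors(frac[i + 1 :] - frac[i], crystal.cell)
        dist = np.linalg.norm(d, axis=1)
        cut = radii[i] + radii[i + 1 :] + tolerance
        for j in np.nonzero(dist <= cut)[0]:
            a, b = labels[i], labels[i + 1 + int(j)]
            bonds.add(frozenset((a, b)))
            adjacency[a].append(b)
            adjacency[b].append(a)

    # connected components; members listed in input site order (canonical,
    # independent of traversal), components ordered by first appearance
    site_index = {l: i for i, l in enumerate(labels)}
    seen: set[str] = set()
    molecules: list[list[str]] = []
    for label in labels:
        if label in seen:
            continue
        comp = set()
        queue = deque([label])
        seen.add(label)
        while queue:
            cur = queue.popleft()
            comp.add(cur)
            for nb in adjacency[cur]:
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        molecules.append(sorted(comp, key=site_index.__getitem__))

    elem_of = dict(zip(labels, elements))
    methyls: list[tuple[str, tuple[str, str, str]]] = []
    for label in labels:
        if elem_of[label] != "C":
            continue
        nbrs = adjacency[label]
        hs = sorted(nb for nb in nbrs if elem_of[nb] == "H")
        heavies = [nb for nb in nbrs if elem_of[nb] != "H"]
        if len(hs) == 3 and len(heavies) == 1:
            methyls.append((label, (hs[0], hs[1], hs[2])))

    return Topology(bonds=bonds, molecules=molecules, methyl_groups=methyls)


def molecule_cart_coords(crystal: Crystal, topology: Topology) -> dict[str, np.ndarray]:
    """Cartesian coordinates with each molecule made whole.

    Starting from the first site of each molecule, neighbours are placed at
    their minimum image relative to an already-placed bonded atom, so a
    molecule wrapped across the periodic boundary comes out contiguous.
    """
    frac_of = {s.label: s.frac for s in crystal.sites}
    adjacency: dict[str, list[str]] = {l: [] for l in crystal.labels}
    for b in topology.bonds:
        a, c = tuple(b)
        adjacency[a].append(c)
        adjacency[c].append(a)

    m = crystal.cell.matrix
    placed: dict[str, np.ndarray] = {}
    for comp in topology.molecules:
        root = comp[0]
        placed_frac = {root: np.array(frac_of[root], dtype=float)}
        queue = deque([root])
        while queue:
            cur = queue.popleft()
            for nb in adjacency[cur]:
                if nb in placed_frac:
                    continue
                d = np.asarray(frac_of[nb]) - placed_frac[cur]
                d -= np.round(d)
                placed_frac[nb] = placed_frac[cur] + d
                queue.append(nb)
        # isolated atoms of the component (no bonds) keep their own position
        for label in comp:
            placed_frac.setdefault(label, np.array(frac_of[label], dtype=float))
        for label, f in placed_frac.items():
            placed[label] = f @ m
    return placed
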