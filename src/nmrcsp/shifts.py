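"""Shielding-to-shift referencing, motional averaging, and RMSD scoring.

Calculated isotropic shieldings σ are converted to chemical shifts with

    δ_calc = σ_ref − σ_calc

where σ_ref is a per-element reference shielding obtained by a linear
regression of calculated shieldings against experimental shifts with the
slope constrained to unity. With that constraint the least-squares solution
has the closed form σ_ref = mean(σ_calc + δ_exp) over the matched nuclei,
which makes the mean signed residual exactly zero.

Motional averaging follows the two-level scheme of the study design: per
candidate, shieldings are averaged over trajectory frames and over the
symmetry-equivalent molecule copies in the cell (one asymmetric-unit value
per nucleus), then referenced, then methyl protons are averaged.
"""

from __future__ import annotations

import io

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .crystio import Topology
from .errors import ShiftDataError

__all__ = [
    "ShieldingTable",
    "ShiftTable",
    "ShiftAssignment",
    "ReferenceShielding",
    "FramePlan",
    "ShiftRmsd",
    "compute_sigma_ref",
    "shieldings_to_shifts",
    "average_methyl_protons",
    "plan_frames",
    "ensemble_average",
    "split_molecules",
    "molecule_map_by_order",
    "rmsd_shifts",
    "read_magres",
    "read_shieldings_tsv",
    "write_shieldings_tsv",
    "read_assignment_tsv",
    "write_assignment_tsv",
]

#: number of molecular spectra averaged per candidate
SPECTRA_PER_CANDIDATE = 48

#: small-cell production-run length, ps
PRODUCTION_LENGTH_PS = 100.0

_SCORED_ELEMENTS = ("H", "C")


def _records_frame(records, value_col: str) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records[["label", "element", value_col]].copy()
    else:
        df = pd.DataFrame(records, columns=["label", "element", value_col])
    df["label"] = df["label"].astype(str)
    df["element"] = df["element"].astype(str)
    df[value_col] = df[value_col].astype(float)
    return df.reset_index(drop=True)


@dataclass
class ShieldingTable:
    """Per-nucleus isotropic shieldings for one structure or one frame/copy."""

    structure_id: str
    records: pd.DataFrame  # columns: label, element, sigma_ppm
    frame_index: int | None = None
    molecule_index: int | None = None
    counts: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.records = _records_frame(self.records, "sigma_ppm")
        if self.records["label"].duplicated().any():
            dupes = sorted(self.records.loc[self.records["label"].duplicated(), "label"])
            raise ShiftDataError(
                f"{self.structure_id}: duplicate nucleus labels {dupes}"
            )


@dataclass
class ShiftTable:
    """Per-nucleus calculated chemical shifts (ppm)."""

    structure_id: str
    records: pd.DataFrame  # columns: label, element, delta_ppm
    approach: str = ""

    def __post_init__(self) -> None:
        self.records = _records_frame(self.records, "delta_ppm")


@dataclass
class ShiftAssignment:
    """Experimental shift assignment: one δ_exp per assigned nucleus label."""

    records: pd.DataFrame  # columns: label, element, delta_exp_ppm
    source: str = ""

    def __post_init__(self) -> None:
        self.records = _records_frame(self.records, "delta_exp_ppm")


@dataclass(frozen=True)
class ReferenceShielding:
    """Slope-unity reference shielding for one element under one approach."""

    element: str
    sigma_ref: float
    n_points: int
    residual_rms: float
    approach: str = ""


@dataclass(frozen=True)
class FramePlan:
    """Frame-selection plan keeping 48 molecular spectra per candidate."""

    z_value: int
    replication: tuple[int, int, int]
    n_frames: int
    interval_ps: float

    @property
    def molecules_per_frame(self) -> int:
        na, nb, nc = self.replication
        return self.z_value * na * nb * nc

    @property
    def n_spectra(self) -> int:
        return self.n_frames * self.molecules_per_frame


@dataclass(frozen=True)
class ShiftRmsd:
    """RMS deviation between calculated and experimental shifts (ppm)."""

    value: float
    n_matched: int
    element: str


# ---------------------------------------------------------------------------
# Referencing
# ---------------------------------------------------------------------------


def compute_sigma_ref(
    tables: ShieldingTable | list[ShieldingTable],
    assignment: ShiftAssignment,
    element: str,
    approach: str = "",
) -> ReferenceShielding:
    """Reference shielding from slope-unity regression over pooled candidates.

    Pools the (σ_calc, δ_exp) pairs of every table (matched by nucleus label
    and element) and returns σ_ref = mean(σ_calc + δ_exp), the closed form of
    the least-squares fit of δ_exp = σ_ref − σ_calc with unit slope.
    """
    if isinstance(tables, ShieldingTable):
        tables = [tables]
    exp = assignment.records[assignment.records["element"] == element]
    sums = []
    n = 0
    for table in tables:
        calc = table.records[table.records["element"] == element]
        merged = calc.merge(exp, on=["label", "element"], how="inner")
        sums.append(merged["sigma_ppm"] + merged["delta_exp_ppm"])
        n += len(merged)
    if n == 0:
        raise ShiftDataError(
            f"no matched {element} nuclei between calculation and assignment"
        )
    pooled = pd.concat(sums, ignore_index=True)
    sigma_ref = float(pooled.mean())
    residual_rms = float(np.sqrt(np.mean((pooled - sigma_ref) ** 2)))
    return ReferenceShielding(
        element=element,
        sigma_ref=sigma_ref,
        n_points=n,
        residual_rms=residual_rms,
        approach=approach,
    )


def shieldings_to_shifts(
    table: ShieldingTable,
    refs: dict[str, ReferenceShielding] | dict[str, float],
    approach: str = "",
) -> ShiftTable:
    """Convert shieldings to shifts: δ = σ_ref − σ, element-wise.

    ``refs`` maps element symbol to a ReferenceShielding (or a bare σ_ref in
    ppm). Every scored element (H, C) present in the table must be covered;
    other elements are carried through only if a reference is supplied,
    otherwise dropped.
    """
    values: dict[str, float] = {}
    for el, ref in refs.items():
        values[el] = ref.sigma_ref if isinstance(ref, ReferenceShielding) else float(ref)
    missing = [
        el
        for el in self_scored_elements(table)
        if el not in values
    ]
    if missing:
        raise ShiftDataError(f"no reference shielding for element(s) {missing}")
    df = table.records[table.records["element"].isin(values)].copy()
    df["delta_ppm"] = df["element"].map(values) - df["sigma_ppm"]
    return ShiftTable(
        structure_id=table.structure_id,
        records=df[["label", "element", "delta_ppm"]],
        approach=approach,
    )


def self_scored_elements(table: ShieldingTable) -> list[str]:
    present = set(table.records["element"])
    return [el for el in _SCORED_ELEMENTS if el in present]


# ---------------------------------------------------------------------------
# Methyl averaging
# ---------------------------------------------------------------------------


def average_methyl_protons(table, topology: Topology):
    """Replace each methyl's three ¹H values by their arithmetic mean.

    Works on shielding or shift tables; idempotent; every non-methyl record
    is untouched. Methyl groups none of whose hydrogens occur in the table
    (e.g. copies from other molecules of the cell) are ignored; a partially
    present methyl is an error.
    """
    value_col = "sigma_ppm" if isinstance(table, ShieldingTable) else "delta_ppm"
    df = table.records.copy()
    index_of = {l: i for i, l in enumerate(df["label"])}
    for carbon, hs in topology.methyl_groups:
        present = [h for h in hs if h in index_of]
        if not present:
            continue
        if len(present) < 3:
            missing = sorted(set(hs) - set(present))
            raise ShiftDataError(
                f"methyl group on {carbon}: hydrogens {missing} missing from table"
            )
        idx = [index_of[h] for h in hs]
        df.loc[idx, value_col] = df.loc[idx, value_col].mean()
    return replace(table, records=df)


# ---------------------------------------------------------------------------
# Frame planning and ensemble averaging
# ---------------------------------------------------------------------------


def plan_frames(z_value: int, replication: tuple[int, int, int] = (1, 1, 1)) -> FramePlan:
    """Frame-selection plan yielding exactly 48 molecular spectra.

    With m molecules per simulation cell (Z times the replication product),
    n_frames = 48 / m frames are taken at intervals of 96 / n_frames ps,
    which reproduces the standard cases: Z=2 → 24 frames at 4.0 ps, Z=4 → 12
    frames at 8.0 ps, Z=1 replicated 2×2×2 → 6 frames at 16.0 ps, all within
    the 100 ps production run.
    """
    if z_value < 1:
        raise ValueError("z_value must be >= 1")
    na, nb, nc = replication
    molecules = z_value * na * nb * nc
    if SPECTRA_PER_CANDIDATE % molecules:
        raise ValueError(
            f"{molecules} molecules per frame does not divide "
            f"{SPECTRA_PER_CANDIDATE} spectra"
        )
    n_frames = SPECTRA_PER_CANDIDATE // molecules
    interval = 96.0 / n_frames
    if n_frames * interval > PRODUCTION_LENGTH_PS + 1e-9:
        raise ValueError("frame plan exceeds the production-run length")
    return FramePlan(
        z_value=z_value,
        replication=tuple(replication),
        n_frames=n_frames,
        interval_ps=interval,
    )


def split_molecules(
    table: ShieldingTable, molecules: list[list[str]]
) -> list[ShieldingTable]:
    """Split a full-cell table into one table per molecule copy."""
    out = []
    by_label = table.records.set_index("label")
    for i, comp in enumerate(molecules):
        present = [l for l in comp if l in by_label.index]
        if not present:
            raise ShiftDataError(
                f"{table.structure_id}: molecule copy {i} has no records"
            )
        df = by_label.loc[present].reset_index()
        out.append(
            ShieldingTable(
                structure_id=table.structure_id,
                records=df,
                frame_index=table.frame_index,
                molecule_index=i,
            )
        )
    return out


def molecule_map_by_order(
    asu_labels: list[str], molecules: list[list[str]]
) -> dict[str, str]:
    """Map every molecule copy's labels to asymmetric-unit labels by site order.

    Each molecule of the cell must have as many sites as the asymmetric-unit
    molecule; frames preserve order, so position within the molecule
    identifies the nucleus.
    """
    mapping: dict[str, str] = {}
    for i, comp in enumerate(molecules):
        if len(comp) != len(asu_labels):
            raise ShiftDataError(
                f"molecule copy {i} has {len(comp)} sites, asymmetric unit has "
                f"{len(asu_labels)}"
            )
        for copy_label, asu_label in zip(comp, asu_labels):
            mapping[copy_label] = asu_label
    return mapping


def ensemble_average(
    tables: list[ShieldingTable],
    molecule_map: dict[str, str] | None = None,
    structure_id: str | None = None,
) -> ShieldingTable:
    """Average shieldings over frames × molecule copies.

    Each input table is one molecular spectrum (one molecule copy in one
    frame). ``molecule_map`` sends copy labels to asymmetric-unit labels
    (labels absent from the map are taken as already asymmetric-unit). Every
    output nucleus must be covered by every table set member: the per-nucleus
    count must equal the number of tables, otherwise the data are ragged.
    """
    if not tables:
        raise ShiftDataError("ensemble_average needs at least one table")
    frames = []
    for t in tables:
        df = t.records.copy()
        if molecule_map:
            df["label"] = df["label"].map(lambda l: molecule_map.get(l, l))
        df["_frame"] = t.frame_index if t.frame_index is not None else 0
        df["_mol"] = t.molecule_index if t.molecule_index is not None else 0
        frames.append(df)
    allrec = pd.concat(frames, ignore_index=True)
    grouped = allrec.groupby(["label", "element"], sort=False)["sigma_ppm"]
    mean = grouped.mean()
    counts = grouped.count()
    if (counts != len(tables)).any():
        bad = counts[counts != len(tables)]
        raise ShiftDataError(
            "ragged ensemble: per-nucleus counts differ from the number of "
            f"spectra ({len(tables)}): {bad.to_dict()}"
        )
    out = mean.reset_index().rename(columns={"sigma_ppm": "sigma_ppm"})
    return ShieldingTable(
        structure_id=structure_id or tables[0].structure_id,
        records=out,
        counts=counts.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def rmsd_shifts(calc: ShiftTable, assignment: ShiftAssignment, element: str) -> ShiftRmsd:
    """RMS deviation between calculated and experimental shifts of one element."""
    c = calc.records[calc.records["element"] == element]
    e = assignment.records[assignment.records["element"] == element]
    merged = c.merge(e, on=["label", "element"], how="inner")
    if merged.empty:
        raise ShiftDataError(
            f"no matched {element} nuclei between {calc.structure_id} and assignment"
        )
    dev = merged["delta_ppm"] - merged["delta_exp_ppm"]
    return ShiftRmsd(
        value=float(np.sqrt(np.mean(dev**2))),
        n_matched=len(merged),
        element=element,
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def read_magres(text: str, structure_id: str = "", frame_index: int | None = None) -> ShieldingTable:
    """Read isotropic shieldings from a magres file.

    The isotropic shielding is the trace/3 of each ``ms`` tensor. Nucleus
    labels are formed as species label + atom index (``C 17`` → ``C17``),
    matching the labelling convention of the crystal model.
    """
    records = []
    elements_of: dict[str, str] = {}
    in_atoms = in_ms = False
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("[atoms]"):
            in_atoms = True
            continue
        if line.startswith("[/atoms]"):
            in_atoms = False
            continue
        if line.startswith("[magres]"):
            in_ms = True
            continue
        if line.startswith("[/magres]"):
            in_ms = False
            continue
        parts = line.split()
        if in_atoms and parts[:1] == ["atom"]:
            # atom <element> <label> <index> x y z
            element, label, index = parts[1], parts[2], parts[3]
            elements_of[f"{label}{index}"] = element
        elif in_ms and parts[:1] == ["ms"]:
            label, index = parts[1], parts[2]
            tensor = [float(x) for x in parts[3:12]]
            if len(tensor) != 9:
                raise ShiftDataError(f"magres ms line has {len(tensor)} components: {line!r}")
            iso = (tensor[0] + tensor[4] + tensor[8]) / 3.0
            key = f"{label}{index}"
            records.append((key, elements_of.get(key, label), iso))
    if not records:
        raise ShiftDataError("magres file contains no ms entries")
    return ShieldingTable(
        structure_id=structure_id,
        records=pd.DataFrame(records, columns=["label", "element", "sigma_ppm"]),
        frame_index=frame_index,
    )


_SHIELDING_COLS = ["structure_id", "frame", "molecule", "label", "element", "sigma_ppm"]


def read_shieldings_tsv(text: str) -> list[ShieldingTable]:
    """Read the TSV shielding dialect, one table per (structure, frame, molecule)."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    missing = set(_SHIELDING_COLS) - set(df.columns)
    if missing:
        raise ShiftDataError(f"shielding TSV missing columns {sorted(missing)}")
    tables = []
    for (sid, frame, mol), group in df.groupby(
        ["structure_id", "frame", "molecule"], sort=False
    ):
        tables.append(
            ShieldingTable(
                structure_id=str(sid),
                records=group[["label", "element", "sigma_ppm"]],
                frame_index=None if frame < 0 else int(frame),
                molecule_index=int(mol),
            )
        )
    return tables


def write_shieldings_tsv(tables: list[ShieldingTable]) -> str:
    rows = []
    for t in tables:
        for _, r in t.records.iterrows():
            rows.append(
                (
                    t.structure_id,
                    -1 if t.frame_index is None else t.frame_index,
                    0 if t.molecule_index is None else t.molecule_index,
                    r["label"],
                    r["element"],
                    r["sigma_ppm"],
                )
            )
    df = pd.DataFrame(rows, columns=_SHIELDING_COLS)
    return df.to_csv(sep="\t", index=False, float_format="%.6f")


def read_assignment_tsv(text: str, source: str = "") -> ShiftAssignment:
    df = pd.read_csv(io.StringIO(text), sep="\t")
    missing = {"label", "element", "delta_exp_ppm"} - set(df.columns)
    if missing:
        raise ShiftDataError(f"assignment TSV missing columns {sorted(missing)}")
    return ShiftAssignment(records=df[["label", "element", "delta_exp_ppm"]], source=source)


def write_assignment_tsv(assignment: ShiftAssignment) -> str:
    return assignment.records.to_csv(sep="\t", index=False, float_format="%.6f")
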