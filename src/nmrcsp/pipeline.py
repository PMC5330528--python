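"""End-to-end orchestration: score candidates under every approach, select,
rank, and emit reproducible reports.

The flow mirrors the standard NMR-crystallography campaign: static shieldings
are referenced and scored first; candidates whose static ¹³C RMSD exceeds the
3σ pre-filter are excluded from the expensive MD stage; the remaining
candidates are scored again with motional averaging (one or more force-field
tags); shortlists per element and approach feed a consensus ranking, next to
the lattice-energy landscape and phase-transition diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crystio import Crystal, Topology, perceive_bonds, read_cif, to_p1
from .errors import NmrCspError, ShiftDataError
from .overlay import PhaseTransitionReport, flag_phase_transition
from .ranking import (
    C13_WINDOW,
    H1_WINDOW,
    BenchmarkWindow,
    CandidateScore,
    EnergyRecord,
    consensus_rank,
    energy_gap,
    energy_landscape,
    energy_rmsd_vs_reference,
    prefilter,
    replace_score,
    shortlist,
)
from .shifts import (
    ReferenceShielding,
    ShieldingTable,
    ShiftAssignment,
    average_methyl_protons,
    compute_sigma_ref,
    ensemble_average,
    molecule_map_by_order,
    read_assignment_tsv,
    read_shieldings_tsv,
    rmsd_shifts,
    shieldings_to_shifts,
    split_molecules,
)

__all__ = [
    "PipelineConfig",
    "Report",
    "score_approach",
    "run_campaign",
    "run_pipeline",
    "compare_approaches",
]


@dataclass
class Report:
    """Full campaign report: everything needed to audit a ranking."""

    sigma_refs: dict[str, dict[str, ReferenceShielding]]
    scores_by_approach: dict[str, list[CandidateScore]]
    prefiltered_ids: list[str]
    consensus: pd.DataFrame
    landscape: pd.DataFrame | None
    energy_rmsds: dict[str, dict[str, float]]
    phase_transitions: dict[str, dict[str, PhaseTransitionReport]]
    windows: dict[str, BenchmarkWindow]
    manifest: dict = field(default_factory=dict)

    def shortlist_sizes(self) -> dict[str, dict[str, int]]:
        """Shortlisted-candidate counts per approach and element."""
        out: dict[str, dict[str, int]] = {}
        for tag, scores in self.scores_by_approach.items():
            out[tag] = {
                "H": sum(s.shortlisted_1h for s in scores),
                "C": sum(s.shortlisted_13c for s in scores),
            }
        return out

    def approach_block(self, tag: str) -> dict:
        """σ_ref and per-candidate RMSDs of one approach, for comparisons."""
        refs = self.sigma_refs.get(tag)
        scores = self.scores_by_approach.get(tag)
        if refs is None or scores is None:
            raise KeyError(f"no approach {tag!r} in report")
        return {
            "approach": tag,
            "sigma_ref": {el: r.sigma_ref for el, r in refs.items()},
            "rmsd": {
                s.structure_id: {"H": s.rmsd_1h, "C": s.rmsd_13c} for s in scores
            },
        }

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "windows": {
                tag: asdict(w) for tag, w in self.windows.items()
            },
            "sigma_refs": {
                tag: {el: asdict(r) for el, r in refs.items()}
                for tag, refs in self.sigma_refs.items()
            },
            "prefiltered": self.prefiltered_ids,
            "scores": {
                tag: [asdict(s) for s in scores]
                for tag, scores in self.scores_by_approach.items()
            },
            "shortlist_sizes": self.shortlist_sizes(),
            "consensus": self.consensus.reset_index().to_dict(orient="records"),
            "landscape": (
                None
                if self.landscape is None
                else self.landscape.to_dict(orient="records")
            ),
            "energy_rmsds": self.energy_rmsds,
            "phase_transitions": {
                tag: {sid: asdict(r) for sid, r in by_id.items()}
                for tag, by_id in self.phase_transitions.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def asu_average(
    table: ShieldingTable, topology: Topology
) -> ShieldingTable:
    """Collapse a full-cell table to asymmetric-unit nuclei by copy averaging."""
    asu = topology.molecules[0]
    mapping = molecule_map_by_order(asu, topology.molecules)
    return ensemble_average(split_molecules(table, topology.molecules), mapping)


def score_approach(
    asu_tables: dict[str, ShieldingTable],
    assignment: ShiftAssignment,
    topologies: dict[str, Topology],
    tag: str,
    reference_pool: list[str] | None = None,
) -> tuple[dict[str, ReferenceShielding], list[CandidateScore]]:
    """Reference and score a set of per-candidate asymmetric-unit tables.

    σ_ref per element is pooled over ``reference_pool`` (default: every
    candidate with data). Shifts are methyl-averaged before scoring.
    """
    pool_ids = reference_pool or list(asu_tables)
    pool = [asu_tables[i] for i in pool_ids]
    refs: dict[str, ReferenceShielding] = {}
    for el in ("H", "C"):
        refs[el] = compute_sigma_ref(pool, assignment, el, approach=tag)
    scores = []
    for sid, table in asu_tables.items():
        shifts = shieldings_to_shifts(table, refs, approach=tag)
        shifts = average_methyl_protons(shifts, topologies[sid])
        rmsd_h = rmsd_shifts(shifts, assignment, "H")
        rmsd_c = rmsd_shifts(shifts, assignment, "C")
        scores.append(
            CandidateScore(
                structure_id=sid,
                approach=tag,
                rmsd_13c=rmsd_c.value,
                rmsd_1h=rmsd_h.value,
            )
        )
    return refs, scores


def run_campaign(
    campaign,
    window_c: BenchmarkWindow = C13_WINDOW,
    window_h: BenchmarkWindow = H1_WINDOW,
) -> Report:
    """Score a (synthetic or assembled) campaign end to end."""
    assignment = campaign.assignment
    topologies = campaign.topologies

    # --- static approach -------------------------------------------------
    static_asu = {
        sid: asu_average(table, topologies[sid])
        for sid, table in campaign.static_tables.items()
    }
    static_refs, static_scores = score_approach(
        static_asu, assignment, topologies, "static"
    )
    kept, excluded = prefilter(static_scores, window_c)
    kept_ids = [s.structure_id for s in kept]
    static_scores = shortlist(
        shortlist(kept, window_c, "C") + excluded, window_h, "H"
    )

    sigma_refs = {"static": static_refs}
    scores_by_approach: dict[str, list[CandidateScore]] = {"static": static_scores}
    transitions: dict[str, dict[str, PhaseTransitionReport]] = {}

    # --- MD approaches (pre-filtered candidates are not averaged) ---------
    crystal_of = {c.name: c for c in campaign.candidates}
    for tag in getattr(campaign.config, "md_approaches", ()):
        md_asu = {}
        for sid in kept_ids:
            spectra = campaign.frame_tables.get((tag, sid))
            if not spectra:
                continue
            mapping = molecule_map_by_order(
                topologies[sid].molecules[0], topologies[sid].molecules
            )
            md_asu[sid] = ensemble_average(spectra, mapping, structure_id=sid)
        if not md_asu:
            continue
        refs, scores = score_approach(md_asu, assignment, topologies, tag)
        scores = shortlist(shortlist(scores, window_c, "C"), window_h, "H")
        by_id: dict[str, PhaseTransitionReport] = {}
        for i, score in enumerate(scores):
            traj = campaign.trajectories.get((tag, score.structure_id))
            if traj is not None:
                rep = flag_phase_transition(traj, crystal_of[score.structure_id])
                by_id[score.structure_id] = rep
                scores[i] = replace_score(score, phase_transition=rep.flag)
        sigma_refs[tag] = refs
        scores_by_approach[tag] = scores
        transitions[tag] = by_id

    consensus = consensus_rank(scores_by_approach)

    landscape = None
    energy_rmsds: dict[str, dict[str, float]] = {}
    energies = getattr(campaign, "energies", None) or {}
    if "reference" in energies:
        landscape = energy_landscape(energies["reference"])
        for tag, records in energies.items():
            if tag == "reference":
                continue
            res = energy_rmsd_vs_reference(records, energies["reference"])
            energy_rmsds[tag] = {"centered": res.centered, "raw": res.raw}

    return Report(
        sigma_refs=sigma_refs,
        scores_by_approach=scores_by_approach,
        prefiltered_ids=[s.structure_id for s in excluded],
        consensus=consensus,
        landscape=landscape,
        energy_rmsds=energy_rmsds,
        phase_transitions=transitions,
        windows={"C": window_c, "H": window_h},
        manifest=dict(getattr(campaign, "manifest", {})),
    )


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """File-based run configuration (YAML-friendly).

    Paths are resolved relative to ``root``. MD inputs are optional: with
    static shieldings only, the report simply carries no MD approaches.
    """

    root: str = "."
    candidates_cif: str = "candidates.cif"
    assignment_tsv: str = "assignment.tsv"
    static_tsv: str = "static_shieldings.tsv"
    md_tsv: dict[str, str] = field(default_factory=dict)  # tag -> path
    trajectories_dir: dict[str, str] = field(default_factory=dict)  # tag -> dir
    energies_tsv: dict[str, str] = field(default_factory=dict)  # method -> path
    window_c: BenchmarkWindow = C13_WINDOW
    window_h: BenchmarkWindow = H1_WINDOW
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, text: str, root: str = ".") -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(text) or {}
        kwargs = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for wkey, el in (("window_c", "C"), ("window_h", "H")):
            if wkey in kwargs and isinstance(kwargs[wkey], dict):
                kwargs[wkey] = BenchmarkWindow(element=el, **kwargs[wkey])
        kwargs.setdefault("root", root)
        return cls(**kwargs)


@dataclass
class _AssembledCampaign:
    """Duck-typed campaign assembled from files (see run_campaign)."""

    config: object
    candidates: list[Crystal]
    assignment: ShiftAssignment
    topologies: dict[str, Topology]
    static_tables: dict[str, ShieldingTable]
    trajectories: dict
    frame_tables: dict
    energies: dict
    manifest: dict


def _load_campaign(config: PipelineConfig) -> _AssembledCampaign:
    from .trajectory import read_extxyz

    root = Path(config.root)
    candidates = [
        to_p1(c) for c in read_cif((root / config.candidates_cif).read_text())
    ]
    for c in candidates:
        c.check_ordered()
    topologies = {c.name: perceive_bonds(c) for c in candidates}
    assignment = read_assignment_tsv((root / config.assignment_tsv).read_text())

    static_tables: dict[str, ShieldingTable] = {}
    for t in read_shieldings_tsv((root / config.static_tsv).read_text()):
        if t.structure_id in static_tables:
            raise ShiftDataError(
                f"duplicate static table for {t.structure_id}"
            )
        static_tables[t.structure_id] = t

    frame_tables: dict = {}
    for tag, path in config.md_tsv.items():
        for t in read_shieldings_tsv((root / path).read_text()):
            frame_tables.setdefault((tag, t.structure_id), []).append(t)

    trajectories: dict = {}
    for tag, dirname in config.trajectories_dir.items():
        for path in sorted((root / dirname).glob("*.xyz")):
            sid = path.stem
            if sid in topologies:
                labels = [s.label for s in next(
                    c for c in candidates if c.name == sid
                ).sites]
                trajectories[(tag, sid)] = read_extxyz(path.read_text(), labels=labels)

    energies: dict[str, list[EnergyRecord]] = {}
    for method, path in config.energies_tsv.items():
        df = pd.read_csv(root / path, sep="\t")
        energies[method] = [
            EnergyRecord(
                structure_id=str(r.structure_id),
                lattice_energy=float(r.lattice_energy),
                density=None if pd.isna(r.density) else float(r.density),
                method=method,
            )
            for r in df.itertuples()
        ]

    class _Cfg:
        md_approaches = tuple(config.md_tsv)

    manifest = {
        "root": str(root),
        "candidates": len(candidates),
        "approaches": ["static", *config.md_tsv],
        "window_c": asdict(config.window_c),
        "window_h": asdict(config.window_h),
    }
    return _AssembledCampaign(
        config=_Cfg(),
        candidates=candidates,
        assignment=assignment,
        topologies=topologies,
        static_tables=static_tables,
        trajectories=trajectories,
        frame_tables=frame_tables,
        energies=energies,
        manifest=manifest,
    )


def run_pipeline(config: PipelineConfig) -> Report:
    """Load inputs per the config, score, and optionally write the report bundle.

    The output bundle is report.json plus TSV tables (scores, consensus,
    sigma_refs, landscape). Thresholds and windows are echoed into the
    manifest verbatim so every run is auditable.
    """
    campaign = _load_campaign(config)
    report = run_campaign(campaign, window_c=config.window_c, window_h=config.window_h)
    if config.out_dir is not None:
        out = Path(config.root) / config.out_dir
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        rows = []
        for tag, scores in report.scores_by_approach.items():
            for s in scores:
                rows.append(asdict(s))
        pd.DataFrame(rows).to_csv(out / "scores.tsv", sep="\t", index=False)
        report.consensus.reset_index().to_csv(
            out / "consensus.tsv", sep="\t", index=False
        )
        ref_rows = [
            asdict(r)
            for refs in report.sigma_refs.values()
            for r in refs.values()
        ]
        pd.DataFrame(ref_rows).to_csv(out / "sigma_refs.tsv", sep="\t", index=False)
        if report.landscape is not None:
            report.landscape.to_csv(out / "landscape.tsv", sep="\t", index=False)
    return report


def compare_approaches(block_a: dict, block_b: dict) -> dict:
    """Delta table between two approach blocks (see Report.approach_block).

    Returns per-element σ_ref differences (a − b) and a per-candidate RMSD
    delta frame over the shared candidates. Errors if the candidate sets are
    disjoint.
    """
    d_sigma = {
        el: block_a["sigma_ref"][el] - block_b["sigma_ref"][el]
        for el in block_a["sigma_ref"]
        if el in block_b["sigma_ref"]
    }
    shared = sorted(set(block_a["rmsd"]) & set(block_b["rmsd"]))
    if not shared:
        raise NmrCspError("approaches share no candidates")
    rows = []
    for sid in shared:
        ra, rb = block_a["rmsd"][sid], block_b["rmsd"][sid]
        rows.append(
            {
                "structure_id": sid,
                "delta_rmsd_1h": _sub(ra.get("H"), rb.get("H")),
                "delta_rmsd_13c": _sub(ra.get("C"), rb.get("C")),
            }
        )
    return {
        "approaches": (block_a["approach"], block_b["approach"]),
        "sigma_ref_delta": d_sigma,
        "rmsd_delta": pd.DataFrame(rows),
    }


def _sub(a, b):
    if a is None or b is None:
        return np.nan
    return a - b
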