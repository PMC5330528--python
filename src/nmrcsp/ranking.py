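"""Candidate pre-filtering, benchmark-window shortlisting, consensus ranking,
and lattice-energy landscape statistics.

Benchmark windows are literature expectation values for shift-calculation
accuracy: a candidate is *shortlisted* when its RMSD lies within mean ± k·sd
(one standard deviation by default), and *pre-filtered* (excluded from the
expensive MD stage) when its static ¹³C RMSD exceeds mean + 3·sd. The default
windows are 1.9 ± 0.4 ppm for ¹³C and 0.33 ± 0.16 ppm for ¹H; because these
come from static-DFT benchmark sets they are explicitly configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ShiftDataError

__all__ = [
    "BenchmarkWindow",
    "CandidateScore",
    "EnergyRecord",
    "EnergyRmsd",
    "C13_WINDOW",
    "H1_WINDOW",
    "prefilter",
    "shortlist",
    "consensus_rank",
    "energy_landscape",
    "energy_gap",
    "energy_rmsd_vs_reference",
    "energy_rmsd_ratio",
]


@dataclass(frozen=True)
class BenchmarkWindow:
    """Expected RMSD window (ppm) for one element."""

    element: str
    mean: float
    sd: float
    k_select: float = 1.0
    k_prefilter: float = 3.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("window sd must be positive")

    @property
    def prefilter_threshold(self) -> float:
        return self.mean + self.k_prefilter * self.sd

    @property
    def select_bounds(self) -> tuple[float, float]:
        return (self.mean - self.k_select * self.sd, self.mean + self.k_select * self.sd)

    def selects(self, rmsd: float) -> bool:
        lo, hi = self.select_bounds
        return lo <= rmsd <= hi


#: literature expectation for ¹³C shift RMSDs; 3σ pre-filter at 3.1 ppm
C13_WINDOW = BenchmarkWindow(element="C", mean=1.9, sd=0.4)

#: literature expectation for ¹H shift RMSDs
H1_WINDOW = BenchmarkWindow(element="H", mean=0.33, sd=0.16)


@dataclass
class CandidateScore:
    """Per-candidate, per-approach shift-RMSD scores and selection flags."""

    structure_id: str
    approach: str
    rmsd_13c: float | None = None
    rmsd_1h: float | None = None
    prefiltered: bool = False
    shortlisted_13c: bool = False
    shortlisted_1h: bool = False
    phase_transition: bool = False

    def rmsd(self, element: str) -> float | None:
        return self.rmsd_1h if element == "H" else self.rmsd_13c


@dataclass(frozen=True)
class EnergyRecord:
    """Lattice energy of one candidate (kJ/mol per molecule)."""

    structure_id: str
    lattice_energy: float
    density: float | None = None
    method: str = ""


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def prefilter(
    static_scores: list[CandidateScore], window: BenchmarkWindow = C13_WINDOW
) -> tuple[list[CandidateScore], list[CandidateScore]]:
    """Split candidates on the 3σ static ¹³C criterion.

    A candidate is excluded iff its static ¹³C RMSD is strictly greater than
    mean + k_prefilter·sd (boundary equality keeps the candidate). Excluded
    candidates are not subjected to MD averaging. Idempotent.
    """
    threshold = window.prefilter_threshold
    kept, excluded = [], []
    for score in static_scores:
        if score.rmsd_13c is None:
            raise ShiftDataError(
                f"{score.structure_id}: pre-filter requires a static 13C RMSD"
            )
        if score.rmsd_13c > threshold:
            excluded.append(replace_score(score, prefiltered=True))
        else:
            kept.append(replace_score(score, prefiltered=False))
    return kept, excluded


def replace_score(score: CandidateScore, **kwargs) -> CandidateScore:
    out = CandidateScore(**{**score.__dict__, **kwargs})
    return out


def shortlist(
    scores: list[CandidateScore], window: BenchmarkWindow, element: str
) -> list[CandidateScore]:
    """Flag candidates whose RMSD lies within the benchmark window (mean ± k·sd)."""
    flag_attr = "shortlisted_1h" if element == "H" else "shortlisted_13c"
    out = []
    for score in scores:
        rmsd = score.rmsd(element)
        flagged = rmsd is not None and window.selects(rmsd)
        out.append(replace_score(score, **{flag_attr: flagged}))
    return out


def consensus_rank(scores_by_approach: dict[str, list[CandidateScore]]) -> pd.DataFrame:
    """Rank candidates by shortlist memberships across approaches and elements.

    Order: number of shortlist memberships (descending), then mean ¹H RMSD,
    then mean ¹³C RMSD (both ascending over the approaches where a score is
    present), then structure id. Deterministic under record shuffling.
    """
    if not scores_by_approach:
        raise ValueError("consensus_rank needs at least one approach")
    rows: dict[str, dict] = {}
    for approach, scores in scores_by_approach.items():
        for s in scores:
            row = rows.setdefault(
                s.structure_id,
                {"structure_id": s.structure_id, "memberships": 0, "h": [], "c": []},
            )
            row["memberships"] += int(s.shortlisted_1h) + int(s.shortlisted_13c)
            if s.rmsd_1h is not None:
                row["h"].append(s.rmsd_1h)
            if s.rmsd_13c is not None:
                row["c"].append(s.rmsd_13c)
    table = pd.DataFrame(
        [
            {
                "structure_id": r["structure_id"],
                "memberships": r["memberships"],
                "mean_rmsd_1h": float(np.mean(r["h"])) if r["h"] else np.inf,
                "mean_rmsd_13c": float(np.mean(r["c"])) if r["c"] else np.inf,
            }
            for r in rows.values()
        ]
    )
    table = table.sort_values(
        by=["memberships", "mean_rmsd_1h", "mean_rmsd_13c", "structure_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table.index = pd.RangeIndex(1, len(table) + 1, name="rank")
    return table


# ---------------------------------------------------------------------------
# Energy landscape
# ---------------------------------------------------------------------------


def energy_landscape(records: list[EnergyRecord]) -> pd.DataFrame:
    """Relative lattice energies (lowest calibrated to zero) and energy rank."""
    if not records:
        raise ValueError("energy_landscape needs at least one record")
    df = pd.DataFrame(
        {
            "structure_id": [r.structure_id for r in records],
            "lattice_energy": [r.lattice_energy for r in records],
            "density": [r.density for r in records],
        }
    )
    df["relative_energy"] = df["lattice_energy"] - df["lattice_energy"].min()
    df["rank"] = (
        df["lattice_energy"].rank(method="first", ascending=True).astype(int)
    )
    return df.sort_values("rank", kind="mergesort").reset_index(drop=True)


def energy_gap(landscape: pd.DataFrame, rank_a: int = 1, rank_b: int = 2) -> float:
    """Energy gap (kJ/mol) between two landscape ranks."""
    by_rank = landscape.set_index("rank")["lattice_energy"]
    return float(abs(by_rank.loc[rank_b] - by_rank.loc[rank_a]))


@dataclass(frozen=True)
class EnergyRmsd:
    """RMS deviation between two lattice-energy sets over shared candidates.

    ``centered`` removes the optimal constant offset (both sets mean-centred)
    since lattice-energy zeros differ between methods; ``raw`` keeps the
    offset and is reported for transparency.
    """

    centered: float
    raw: float
    n: int


def energy_rmsd_vs_reference(
    ff: list[EnergyRecord], ref: list[EnergyRecord]
) -> EnergyRmsd:
    """Energy RMSD of a force-field set against a reference method."""
    e_ff = {r.structure_id: r.lattice_energy for r in ff}
    e_ref = {r.structure_id: r.lattice_energy for r in ref}
    if set(e_ff) != set(e_ref):
        raise ShiftDataError(
            "energy sets cover different candidates: "
            f"{sorted(set(e_ff) ^ set(e_ref))}"
        )
    ids = sorted(e_ff)
    a = np.array([e_ff[i] for i in ids])
    b = np.array([e_ref[i] for i in ids])
    raw = float(np.sqrt(np.mean((a - b) ** 2)))
    ac = a - a.mean()
    bc = b - b.mean()
    centered = float(np.sqrt(np.mean((ac - bc) ** 2)))
    return EnergyRmsd(centered=centered, raw=raw, n=len(ids))


def energy_rmsd_ratio(x: EnergyRmsd, y: EnergyRmsd, centered: bool = True) -> float:
    """Ratio of two energy RMSDs (e.g. COMPASS / TMFF accuracy factor)."""
    num = x.centered if centered else x.raw
    den = y.centered if centered else y.raw
    return num / den
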