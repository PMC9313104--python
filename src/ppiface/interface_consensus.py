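"""Compare interfaces across receptor conformations and refinement stages.

The biological question is whether a receptor presents the *same* ligand
interface in its different catalytic conformations (for a P-type pump:
phosphoenzyme states and the ouabain-bound state), because only then can a
single inhibitor block the interaction in all states.  This module computes
the strict residue-set intersection of per-conformation interfaces and the
pairwise Jaccard indices, the narrowing of segments between the docking and
refined (post-MD) stages, peptide orientation statistics relative to the
cavity, and bookkeeping of regions deliberately excluded from the target
site (e.g. beta-subunit areas far from the cavity).

Consensus over conformations is a strict intersection; the union is also
reported since a universal inhibitor would have to cover every site.
Jaccard indices are reported, not thresholded: "practically identical" has
no canonical cut-off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .contacts import (
    InterfaceSegment,
    ResidueContactProfile,
    ResidueKey,
    merge_residues_to_segments,
)
from .core_model import ComplexModel, PPIfaceError
from .pose_filter import CavityDefinition


@dataclass
class ConformationInterface:
    """Interface of one receptor conformation at one pipeline stage."""

    conformation: str
    stage: Literal["docking", "refined"]
    segments: list[InterfaceSegment]
    profile: ResidueContactProfile | None = None

    def __post_init__(self):
        by_chain: dict[str, set[int]] = {}
        for seg in self.segments:
            seen = by_chain.setdefault(seg.chain, set())
            span = set(range(seg.start, seg.end + 1))
            if seen & span:
                raise ValueError(
                    f"overlapping segments on chain {seg.chain} in {self.conformation}"
                )
            seen |= span

    def residue_set(self) -> set[ResidueKey]:
        out: set[ResidueKey] = set()
        for seg in self.segments:
            out |= seg.residues()
        return out

    def chains(self) -> set[str]:
        return {s.chain for s in self.segments}


def jaccard(a: set, b: set) -> float:
    """Jaccard index of two residue sets; 1.0 when both are empty."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class ConsensusReport:
    per_conformation: dict[str, list[InterfaceSegment]]
    intersection_segments: list[InterfaceSegment]
    union_segments: list[InterfaceSegment]
    pairwise_jaccard: dict[tuple[str, str], float]
    excluded_regions: list[tuple[InterfaceSegment, str]] = field(default_factory=list)

    def intersection_residues(self) -> set[ResidueKey]:
        out: set[ResidueKey] = set()
        for seg in self.intersection_segments:
            out |= seg.residues()
        return out

    def min_jaccard(self) -> float:
        return min(self.pairwise_jaccard.values(), default=1.0)

    def to_dict(self) -> dict:
        seg = lambda s: {"chain": s.chain, "start": s.start, "end": s.end}
        return {
            "per_conformation": {
                conf: [seg(s) for s in segs]
                for conf, segs in self.per_conformation.items()
            },
            "intersection": [seg(s) for s in self.intersection_segments],
            "union": [seg(s) for s in self.union_segments],
            "pairwise_jaccard": {
                f"{a}|{b}": round(v, 4) for (a, b), v in self.pairwise_jaccard.items()
            },
            "excluded_regions": [
                {**seg(s), "reason": reason} for s, reason in self.excluded_regions
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def consensus(
    interfaces: Sequence[ConformationInterface],
    gap_tolerance: int = 0,
    min_length: int = 1,
) -> ConsensusReport:
    """Strict residue-set intersection across conformations, plus Jaccards.

    The intersection (and union) residue sets are re-segmented with the same
    merge rule used for interface calling; by default gaps are not bridged
    (pure set semantics) and single residues are kept.
    """
    if len(interfaces) < 2:
        raise ValueError("consensus needs at least two conformations")
    chains = interfaces[0].chains()
    for iface in interfaces[1:]:
        if iface.chains() != chains:
            raise PPIfaceError(
                "conformations cover different chains "
                f"({sorted(chains)} vs {sorted(iface.chains())}); "
                "check receptor numbering"
            )
    sets = {i.conformation: i.residue_set() for i in interfaces}
    inter = set.intersection(*sets.values())
    union = set.union(*sets.values())
    pairwise = {
        (a, b): jaccard(sets[a], sets[b]) for a, b in combinations(sorted(sets), 2)
    }
    return ConsensusReport(
        per_conformation={i.conformation: list(i.segments) for i in interfaces},
        intersection_segments=merge_residues_to_segments(inter, gap_tolerance, min_length),
        union_segments=merge_residues_to_segments(union, gap_tolerance, min_length),
        pairwise_jaccard=pairwise,
    )


@dataclass(frozen=True)
class SegmentChange:
    docking: InterfaceSegment
    refined: InterfaceSegment | None  # None when the area vanished on refinement
    width_before: int
    width_after: int


@dataclass
class NarrowingReport:
    ratio: float  # total refined residues / total docking residues
    changes: list[SegmentChange]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "docking": str(c.docking),
                "refined": str(c.refined) if c.refined else "-",
                "width_before": c.width_before,
                "width_after": c.width_after,
            }
            for c in self.changes
        ]
        return pd.DataFrame(rows, columns=["docking", "refined", "width_before", "width_after"])


def narrowing_metric(
    docking: ConformationInterface, refined: ConformationInterface
) -> NarrowingReport:
    """Quantify how refinement narrows the interface peaks.

    Refined segments are matched to docking segments by maximal residue
    overlap; the global ratio is (total refined residues)/(total docking
    residues), so identical stages give exactly 1.0.
    """
    if docking.stage != "docking" or refined.stage != "refined":
        raise ValueError("expected one 'docking' and one 'refined' interface")
    n_dock = len(docking.residue_set())
    n_ref = len(refined.residue_set())
    if n_dock == 0:
        raise ValueError("docking interface is empty")
    changes: list[SegmentChange] = []
    for dseg in docking.segments:
        dres = dseg.residues()
        best, best_overlap = None, 0
        for rseg in refined.segments:
            overlap = len(dres & rseg.residues())
            if overlap > best_overlap:
                best, best_overlap = rseg, overlap
        changes.append(
            SegmentChange(
                docking=dseg,
                refined=best,
                width_before=dseg.length,
                width_after=best.length if best else 0,
            )
        )
    return NarrowingReport(ratio=n_ref / n_dock, changes=changes)


# ---------------------------------------------------------------------------
# Peptide orientation relative to the cavity
# ---------------------------------------------------------------------------

Orientation = Literal["C_in", "N_in", "ambiguous"]


@dataclass(frozen=True, slots=True)
class OrientationStats:
    n_C_in: int
    n_N_in: int
    n_ambiguous: int

    @property
    def total(self) -> int:
        return self.n_C_in + self.n_N_in + self.n_ambiguous


def peptide_orientation(
    model: ComplexModel,
    cavity: CavityDefinition,
    window: int = 5,
    ambiguity_band: float = 2.0,
) -> Orientation:
    """Which peptide terminus points into the cavity.

    Compares the distance of the N-terminal-window heavy-atom centroid and
    the C-terminal-window centroid to the cavity centre; differences smaller
    than ``ambiguity_band`` (A) are called ambiguous.
    """
    if not model.ligand_is_peptide:
        raise PPIfaceError("orientation is defined for peptide ligands only")
    residues = model.ligand_residues()
    if len(residues) < 2 * window:
        raise ValueError(
            f"peptide has {len(residues)} residues; need >= {2 * window} for window {window}"
        )
    n_set = set(residues[:window])
    c_set = set(residues[-window:])
    n_pts = np.array([a.coords for a in model.ligand_atoms if a.residue_seq in n_set])
    c_pts = np.array([a.coords for a in model.ligand_atoms if a.residue_seq in c_set])
    d_n = float(np.linalg.norm(n_pts.mean(axis=0) - cavity.center_xyz))
    d_c = float(np.linalg.norm(c_pts.mean(axis=0) - cavity.center_xyz))
    if abs(d_n - d_c) < ambiguity_band:
        return "ambiguous"
    return "C_in" if d_c < d_n else "N_in"


def orientation_stats(
    models: Sequence[ComplexModel],
    cavity: CavityDefinition,
    window: int = 5,
    ambiguity_band: float = 2.0,
) -> OrientationStats:
    calls = [peptide_orientation(m, cavity, window, ambiguity_band) for m in models]
    return OrientationStats(
        n_C_in=calls.count("C_in"),
        n_N_in=calls.count("N_in"),
        n_ambiguous=calls.count("ambiguous"),
    )


# ---------------------------------------------------------------------------
# Excluded regions
# ---------------------------------------------------------------------------


def apply_exclusions(
    segments: Sequence[InterfaceSegment],
    exclusions: Sequence[tuple[InterfaceSegment, str]],
) -> tuple[list[InterfaceSegment], list[tuple[InterfaceSegment, str]]]:
    """Remove excluded residues from target segments, keeping a record.

    Returns (kept_segments, excluded_records).  Kept segments are the maximal
    runs of surviving residues; the excluded records carry the reason text so
    reports can show what was dropped and why.
    """
    excluded_res: set[ResidueKey] = set()
    for seg, _ in exclusions:
        excluded_res |= seg.residues()
    kept_res: set[ResidueKey] = set()
    for seg in segments:
        kept_res |= seg.residues() - excluded_res
    kept = merge_residues_to_segments(kept_res, gap_tolerance=0, min_length=1)
    return kept, list(exclusions)


def annotate_excluded(
    report: ConsensusReport,
    exclusions: Sequence[tuple[InterfaceSegment, str]],
) -> ConsensusReport:
    """Apply exclusions to a consensus report's intersection and union sets."""
    inter, records = apply_exclusions(report.intersection_segments, exclusions)
    union, _ = apply_exclusions(report.union_segments, exclusions)
    return ConsensusReport(
        per_conformation=report.per_conformation,
        intersection_segments=inter,
        union_segments=union,
        pairwise_jaccard=report.pairwise_jaccard,
        excluded_regions=list(records),
    )


def segments_to_bed(segments: Sequence[InterfaceSegment], path: str | Path) -> None:
    """BED-like export (chain, start-1, end): 0-based half-open in this export only."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chain}\t{seg.start - 1}\t{seg.end}\n")
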