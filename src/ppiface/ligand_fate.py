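"""Classify post-refinement compound poses and triage screened inhibitors.

During an MD refinement a docked small molecule can leave its intended
binding site.  Each final pose is assigned exactly one fate, checked in a
fixed precedence order (membrane > cavity > interface > displaced):

- ``membrane_embedded`` (red): at least half of the compound's heavy atoms
  are inside the membrane slab -- the compound partitioned into the bilayer.
- ``cavity_entered`` (yellow): the compound centroid lies within the cavity
  radius of the inter-subunit axis *and* below the interface C-alpha
  centroid (toward the membrane) -- it slid into the channel mouth and no
  longer blocks the surface interface.
- ``interface_bound`` (green): the compound still contacts at least three
  distinct interface residues at the contact cutoff.
- ``displaced``: none of the above; the compound drifted away.

Triage across receptor conformations eliminates any compound with a single
membrane or cavity event (such behaviour is a property of the compound's
chemistry, not of the conformation) and keeps compounds that remain
interface-bound in at least two conformations, ranked by the number of
conformations blocked and, on ties, by mean docking affinity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import DEFAULT_CUTOFF, ResidueKey, compute_contacts
from .core_model import ComplexModel, MembraneSlab, PPIfaceError
from .pose_filter import CavityDefinition, membrane_overlap


class FateLabel(str, Enum):
    INTERFACE_BOUND = "interface_bound"
    CAVITY_ENTERED = "cavity_entered"
    MEMBRANE_EMBEDDED = "membrane_embedded"
    DISPLACED = "displaced"

    @property
    def color(self) -> str:
        return {
            FateLabel.INTERFACE_BOUND: "green",
            FateLabel.CAVITY_ENTERED: "yellow",
            FateLabel.MEMBRANE_EMBEDDED: "red",
            FateLabel.DISPLACED: "grey",
        }[self]


@dataclass(frozen=True, slots=True)
class FateParams:
    membrane_fraction: float = 0.5  # atoms inside slab to call membrane_embedded
    min_interface_contacts: int = 3
    contact_cutoff: float = DEFAULT_CUTOFF


def classify_fate(
    model: ComplexModel,
    interface_residues: Iterable[ResidueKey],
    slab: MembraneSlab,
    cavity: CavityDefinition,
    params: FateParams = FateParams(),
) -> tuple[FateLabel, dict]:
    """Assign exactly one fate label to a compound pose (see module docstring).

    ``interface_residues`` is the flattened target-site residue set; its
    C-alpha centroid z defines "below the interface" for the cavity test.
    """
    if model.ligand_is_peptide:
        raise PPIfaceError(
            "classify_fate handles HETATM compounds; peptide poses go through pose_filter"
        )
    interface_residues = set(interface_residues)
    mem_fraction = membrane_overlap(model, slab)
    centroid = model.ligand_centroid()
    axis_dist = float(cavity.axis_distance(centroid)[0])
    iface_ca = model.ca_coords(interface_residues)
    if len(iface_ca) == 0:
        raise PPIfaceError("interface residues resolve to no C-alpha atoms")
    iface_z = float(iface_ca[:, 2].mean())
    contacts = compute_contacts(model, cutoff=params.contact_cutoff)
    touched = {p.receptor_key for p in contacts} & interface_residues

    metrics = {
        "membrane_fraction": mem_fraction,
        "axis_distance": axis_dist,
        "centroid_z": float(centroid[2]),
        "interface_z": iface_z,
        "n_interface_contacts": len(touched),
    }
    if mem_fraction >= params.membrane_fraction:
        return FateLabel.MEMBRANE_EMBEDDED, metrics
    if axis_dist <= cavity.radius and centroid[2] < iface_z:
        return FateLabel.CAVITY_ENTERED, metrics
    if len(touched) >= params.min_interface_contacts:
        return FateLabel.INTERFACE_BOUND, metrics
    return FateLabel.DISPLACED, metrics


@dataclass(frozen=True, slots=True)
class ConformationOutcome:
    docking_rank: int
    docking_affinity: float  # kcal/mol, input metadata from the screening stage
    fate: FateLabel


@dataclass
class CompoundRecord:
    compound_id: str
    outcomes: dict[str, ConformationOutcome]  # conformation tag -> outcome

    @property
    def n_interface_bound(self) -> int:
        return sum(
            1 for o in self.outcomes.values() if o.fate is FateLabel.INTERFACE_BOUND
        )

    @property
    def mean_affinity(self) -> float:
        return float(np.mean([o.docking_affinity for o in self.outcomes.values()]))

    def has_fate(self, fate: FateLabel) -> bool:
        return any(o.fate is fate for o in self.outcomes.values())


@dataclass
class TriageTable:
    conformations: list[str]
    survivors: list[CompoundRecord]  # ranked
    eliminated: list[tuple[CompoundRecord, str]]  # (record, reason)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, rec in enumerate(self.survivors, start=1):
            rows.append(self._row(rec, status="survivor", rank=rank, reason=""))
        for rec, reason in self.eliminated:
            rows.append(self._row(rec, status="eliminated", rank=None, reason=reason))
        return pd.DataFrame(rows)

    def _row(self, rec: CompoundRecord, status: str, rank, reason: str) -> dict:
        row = {
            "compound_id": rec.compound_id,
            "status": status,
            "rank": rank,
            "reason": reason,
            "n_interface_bound": rec.n_interface_bound,
            "mean_affinity": round(rec.mean_affinity, 3),
        }
        for conf in self.conformations:
            row[f"fate_{conf}"] = rec.outcomes[conf].fate.value
        return row

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "conformations": self.conformations,
            "survivors": [
                {
                    "compound_id": r.compound_id,
                    "n_interface_bound": r.n_interface_bound,
                    "mean_affinity": r.mean_affinity,
                    "fates": {c: o.fate.value for c, o in r.outcomes.items()},
                }
                for r in self.survivors
            ],
            "eliminated": [
                {
                    "compound_id": r.compound_id,
                    "reason": reason,
                    "fates": {c: o.fate.value for c, o in r.outcomes.items()},
                }
                for r, reason in self.eliminated
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


ELIMINATION_MEMBRANE = "membrane"
ELIMINATION_CAVITY = "cavity"
ELIMINATION_INTERFACE = "insufficient_interface"


def triage_compounds(
    records: Sequence[CompoundRecord],
    min_interface_bound: int = 2,
) -> TriageTable:
    """Eliminate and rank screened compounds by their fates across conformations.

    A single membrane or cavity event eliminates a compound outright (both
    behaviours reflect the compound's chemistry and predict failure in any
    conformation).  Survivors must be interface-bound in at least
    ``min_interface_bound`` conformations; they are ranked by that count
    (descending) with mean docking affinity (ascending, i.e. strongest
    first) breaking ties, then compound id.
    """
    if not records:
        return TriageTable(conformations=[], survivors=[], eliminated=[])
    conformations = sorted(records[0].outcomes)
    for rec in records:
        if sorted(rec.outcomes) != conformations:
            raise PPIfaceError(
                f"compound {rec.compound_id} covers conformations "
                f"{sorted(rec.outcomes)}, expected {conformations}"
            )
    survivors: list[CompoundRecord] = []
    eliminated: list[tuple[CompoundRecord, str]] = []
    for rec in sorted(records, key=lambda r: r.compound_id):
        if rec.has_fate(FateLabel.MEMBRANE_EMBEDDED):
            eliminated.append((rec, ELIMINATION_MEMBRANE))
        elif rec.has_fate(FateLabel.CAVITY_ENTERED):
            eliminated.append((rec, ELIMINATION_CAVITY))
        elif rec.n_interface_bound < min_interface_bound:
            eliminated.append((rec, ELIMINATION_INTERFACE))
        else:
            survivors.append(rec)
    survivors.sort(key=lambda r: (-r.n_interface_bound, r.mean_affinity, r.compound_id))
    return TriageTable(
        conformations=conformations, survivors=survivors, eliminated=eliminated
    )


def records_from_frame(
    frame: pd.DataFrame, fates: Mapping[tuple[str, str], FateLabel]
) -> list[CompoundRecord]:
    """Build compound records from a metadata table plus classified fates.

    ``frame`` columns: compound_id, conformation, docking_rank, affinity.
    ``fates`` maps (compound_id, conformation) to the classified FateLabel.
    """
    by_compound: dict[str, dict[str, ConformationOutcome]] = {}
    for _, row in frame.iterrows():
        key = (row["compound_id"], row["conformation"])
        if key not in fates:
            raise PPIfaceError(f"no classified fate for {key}")
        by_compound.setdefault(row["compound_id"], {})[row["conformation"]] = (
            ConformationOutcome(
                docking_rank=int(row["docking_rank"]),
                docking_affinity=float(row["affinity"]),
                fate=fates[key],
            )
        )
    return [CompoundRecord(cid, outs) for cid, outs in sorted(by_compound.items())]


def fate_report(table: TriageTable, html_path: str | Path | None = None) -> str:
    """Colour-coded HTML export of the triage table (plus TSV via to_tsv).

    Cells carry the fate colour (green/yellow/red/grey); an empty table
    renders a header-only document.
    """
    headers = ["compound", "status", "reason", *table.conformations]
    lines = [
        "<html><head><style>",
        "td.green{background:#b6e3b6} td.yellow{background:#f5f0a8}",
        "td.red{background:#f2b6b6} td.grey{background:#d9d9d9}",
        "table{border-collapse:collapse} td,th{border:1px solid #888;padding:3px 8px}",
        "</style></head><body><table>",
        "<tr>" + "".join(f"<th>{h}</th>" for h in headers) + "</tr>",
    ]
    def row_html(rec: CompoundRecord, status: str, reason: str) -> str:
        cells = [f"<td>{rec.compound_id}</td>", f"<td>{status}</td>", f"<td>{reason}</td>"]
        for conf in table.conformations:
            fate = rec.outcomes[conf].fate
            cells.append(f'<td class="{fate.color}">{fate.value}</td>')
        return "<tr>" + "".join(cells) + "</tr>"

    for rec in table.survivors:
        lines.append(row_html(rec, "survivor", ""))
    for rec, reason in table.eliminated:
        lines.append(row_html(rec, "eliminated", reason))
    lines.append("</table></body></html>")
    html = "\n".join(lines)
    if html_path is not None:
        Path(html_path).write_text(html)
    return html
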