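"""Accept/reject docked peptide poses against a membrane-embedded receptor.

Full-blind docking of a peptide to a membrane pump produces many poses that
are geometrically impossible in vivo (buried in the bilayer) or biologically
uninteresting (far from the inter-subunit cavity, or touching the receptor at
a single spot).  Three numeric criteria mirror the visual triage used in
ensemble docking studies of the Na,K-ATPase/amyloid system:

1. *cavity localisation* -- a sufficient fraction of ligand residues sits
   near the cavity between the alpha- and beta-subunits;
2. *membrane avoidance* -- no ligand heavy atom inside the membrane slab
   (strict: any membrane-touching pose is discarded);
3. *multipoint binding* -- contacts fall into several sequence-separated
   sites of the receptor rather than one local patch.

Thresholds quantifying "near the cavity" and "multiple points" have no
experimental definition, so they are explicit, configurable parameters
(defaults: >= 30% of ligand residues within 15 A of the cavity centre;
>= 3 contact clusters separated by >= 20 residues).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contacts import ContactPair, InterfaceSegment, compute_contacts, DEFAULT_CUTOFF
from .core_model import ComplexModel, MembraneSlab, PPIfaceError, coords_array


@dataclass(frozen=True, slots=True)
class CavityDefinition:
    """Inter-subunit cavity: a centre point with a vertical (z) axis and radius."""

    center: tuple[float, float, float]
    radius: float = 12.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("cavity radius must be positive")
        if not np.all(np.isfinite(self.center)):
            raise ValueError("cavity center must be finite")

    @property
    def center_xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def axis_distance(self, points: np.ndarray) -> np.ndarray:
        """Radial (xy) distance of points from the vertical axis through centre."""
        pts = np.atleast_2d(points)
        return np.linalg.norm(pts[:, :2] - self.center_xyz[:2], axis=1)


def cavity_center(
    model: ComplexModel,
    target_segments: Sequence[InterfaceSegment],
    radius: float = 12.0,
) -> CavityDefinition:
    """Cavity centre = unweighted C-alpha centroid of the target segments."""
    all_ca = []
    for seg in target_segments:
        ca = model.ca_coords(seg.residues())
        if len(ca) == 0:
            raise PPIfaceError(f"segment {seg} resolves to no C-alpha atoms")
        all_ca.append(ca)
    stacked = np.vstack(all_ca)
    if len(stacked) < 3:
        raise PPIfaceError(
            f"target segments resolve to only {len(stacked)} C-alpha atoms (need >= 3)"
        )
    return CavityDefinition(center=tuple(stacked.mean(axis=0)), radius=radius)


def membrane_overlap(model: ComplexModel, slab: MembraneSlab) -> float:
    """Fraction of ligand heavy atoms with z inside the membrane slab."""
    z = coords_array(model.ligand_atoms)[:, 2]
    return float(np.mean(slab.contains_z(z)))


def _ligand_unit_centroids(model: ComplexModel) -> np.ndarray:
    """Centroids of ligand residues (peptide) or of the whole compound."""
    if model.ligand_is_peptide:
        xyz = coords_array(model.ligand_atoms)
        res = np.array([a.residue_seq for a in model.ligand_atoms])
        return np.array([xyz[res == r].mean(axis=0) for r in np.unique(res)])
    return model.ligand_centroid()[None, :]


def cavity_proximity_test(
    model: ComplexModel,
    cavity: CavityDefinition,
    max_dist: float = 15.0,
    min_fraction: float = 0.3,
) -> tuple[bool, float]:
    """Criterion 1: ligand mainly positioned in or near the cavity.

    Passes iff the fraction of ligand residue centroids within ``max_dist``
    of the cavity centre is >= ``min_fraction`` (boundary inclusive).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    centroids = _ligand_unit_centroids(model)
    d = np.linalg.norm(centroids - cavity.center_xyz, axis=1)
    fraction = float(np.mean(d <= max_dist))
    return fraction >= min_fraction, fraction


def contact_clusters(
    contacts: Sequence[ContactPair], min_separation: int = 20
) -> list[list[tuple[str, int]]]:
    """Group contacted receptor residues into sequence-separated clusters.

    Residues on one chain split into a new cluster when the numbering gap to
    the previous contacted residue is >= ``min_separation``; clusters on
    different chains are always separate.
    """
    by_chain: dict[str, list[int]] = {}
    for pair in contacts:
        by_chain.setdefault(pair.receptor_chain, []).append(pair.receptor_residue)
    clusters: list[list[tuple[str, int]]] = []
    for chain in sorted(by_chain):
        nums = sorted(set(by_chain[chain]))
        current = [(chain, nums[0])]
        for n in nums[1:]:
            if n - current[-1][1] >= min_separation:
                clusters.append(current)
                current = []
            current.append((chain, n))
        clusters.append(current)
    return clusters


def multipoint_contact_test(
    contacts: Sequence[ContactPair],
    min_sites: int = 3,
    min_separation: int = 20,
) -> tuple[bool, int]:
    """Criterion 3: contacts at multiple sequence-separated receptor sites."""
    if min_sites < 2 or min_separation < 1:
        raise ValueError("min_sites >= 2 and min_separation >= 1 required")
    n = len(contact_clusters(contacts, min_separation=min_separation))
    return n >= min_sites, n


@dataclass(frozen=True, slots=True)
class FilterParams:
    """Thresholds for the three pose-acceptance criteria, all configurable."""

    contact_cutoff: float = DEFAULT_CUTOFF
    cavity_max_dist: float = 15.0
    cavity_min_fraction: float = 0.3
    min_sites: int = 3
    min_separation: int = 20
    # individual criteria can be switched off for ablation runs
    use_cavity: bool = True
    use_membrane: bool = True
    use_multipoint: bool = True


@dataclass(frozen=True)
class FilterVerdict:
    model_id: str
    passed: bool
    cavity_localized: bool
    no_membrane_overlap: bool
    multipoint: bool
    metrics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "passed": self.passed,
            "cavity_localized": self.cavity_localized,
            "no_membrane_overlap": self.no_membrane_overlap,
            "multipoint": self.multipoint,
            **{f"metric_{k}": v for k, v in self.metrics.items()},
        }


def evaluate_pose(
    model: ComplexModel,
    slab: MembraneSlab,
    cavity: CavityDefinition,
    params: FilterParams = FilterParams(),
) -> FilterVerdict:
    """Apply the three criteria to one pose and record the backing metrics."""
    contacts = compute_contacts(model, cutoff=params.contact_cutoff)
    cav_ok, cav_fraction = cavity_proximity_test(
        model, cavity, params.cavity_max_dist, params.cavity_min_fraction
    )
    mem_fraction = membrane_overlap(model, slab)
    mem_ok = mem_fraction == 0.0
    multi_ok, n_clusters = multipoint_contact_test(
        contacts, params.min_sites, params.min_separation
    )
    checks = []
    if params.use_cavity:
        checks.append(cav_ok)
    if params.use_membrane:
        checks.append(mem_ok)
    if params.use_multipoint:
        checks.append(multi_ok)
    return FilterVerdict(
        model_id=model.model_id,
        passed=all(checks),
        cavity_localized=cav_ok,
        no_membrane_overlap=mem_ok,
        multipoint=multi_ok,
        metrics={
            "cavity_fraction": cav_fraction,
            "membrane_fraction": mem_fraction,
            "n_contact_clusters": n_clusters,
            "n_contacts": len(contacts),
        },
    )


def filter_ensemble(
    models: Sequence[ComplexModel],
    slab: MembraneSlab,
    cavity: CavityDefinition,
    params: FilterParams = FilterParams(),
) -> tuple[list[FilterVerdict], list[ComplexModel]]:
    """Verdicts for every input pose plus the surviving poses, order preserved."""
    verdicts = [evaluate_pose(m, slab, cavity, params) for m in models]
    survivors = [m for m, v in zip(models, verdicts) if v.passed]
    return verdicts, survivors
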