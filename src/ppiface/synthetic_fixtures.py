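"""Deterministic toy structures exercising every analysis module offline.

The generator emulates the geometry that matters for contact analysis, pose
filtering, orientation calls and fate classification, and nothing else:

- a two-chain receptor (alpha = chain A, beta = chain B) built as two
  parallel residue "walls" at x = +/-8 A with a 16 A gap (the inter-subunit
  cavity) between them, sitting on the +z side of a membrane slab;
- each residue carries a C-alpha and one side-chain pseudo-atom pointing
  into the gap -- enough for minimum-distance contacts without rotamers;
- planted interface segments whose ground truth (residue ranges, cavity
  centre, slab bounds) is recorded next to the structures;
- peptide poses planted in prescribed classes (good, membrane violator,
  far, single-point) and compound poses planted in the four fate classes.

Everything is driven by one numpy PRNG seeded from the spec, so equal specs
give byte-identical files.  The pseudo-structures are not physical
conformers: they reproduce the *distance relationships* the classifiers
test, not protein geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .contacts import InterfaceSegment
from .core_model import ALPHA, BETA, AtomSite, ComplexModel, MembraneSlab, write_complex_pdb
from .ligand_fate import FateLabel

PoseClass = Literal["good", "membrane_violator", "far", "single_point"]
POSE_CLASSES: tuple[PoseClass, ...] = ("good", "membrane_violator", "far", "single_point")

# receptor wall geometry (Angstrom)
_WALL_X = 8.0  # chain planes at x = -8 (A) and +8 (B)
_SC_INSET = 1.5  # side-chain pseudo-atom offset toward the gap
_GRID_STEP = 7.0  # residue spacing along y and between rows (z)
_ROW_LEN = 10  # residues per extracellular row
_ANCHOR_INSET = 2.0  # peptide anchor offset from a side-chain atom, toward the gap


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic ensemble.

    Defaults mirror the modelled system: 15 complex models per receptor
    conformation across three conformations, ~20% decoy poses, a 42-residue
    peptide ligand, 12-atom compounds, and four planted interface segments
    (three on the alpha-subunit, one on the beta-subunit) whose sequence
    separations exceed the multipoint clustering distance.
    """

    seed: int = 0
    n_models: int = 15
    conformations: tuple[str, ...] = ("E1P", "E2P", "OBN")
    isoforms: tuple[str, ...] = ("Ab42", "isoD7", "pS8")
    n_res_alpha: int = 100
    n_res_beta: int = 60
    n_tm: int = 20  # transmembrane residues per chain
    slab: tuple[float, float] = (-34.0, -4.0)
    planted_segments: tuple[tuple[str, int, int], ...] = (
        ("A", 30, 35),
        ("A", 55, 60),
        ("A", 80, 86),
        ("B", 35, 39),
    )
    noise_sigma: float = 0.3  # ligand placement jitter
    decoy_fraction: float = 0.2
    peptide_length: int = 42
    compound_atoms: int = 12

    def __post_init__(self):
        if self.n_res_alpha < 30 or self.n_res_beta < 30:
            raise ValueError("each chain needs at least 30 residues")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")


def _residue_xyz(spec: FixtureSpec, chain: str, resseq: int) -> tuple[np.ndarray, np.ndarray]:
    """CA and side-chain positions of one receptor residue on its wall."""
    sign = -1.0 if chain == "A" else 1.0
    x_ca = sign * _WALL_X
    x_sc = sign * (_WALL_X - _SC_INSET)
    z_lo, z_hi = -30.0, -6.0
    if resseq <= spec.n_tm:  # transmembrane stretch, single column inside the slab
        frac = (resseq - 1) / max(spec.n_tm - 1, 1)
        pos = np.array([x_ca, 0.0, z_lo + frac * (z_hi - z_lo)])
        sc = pos.copy()
        sc[0] = x_sc
        return pos, sc
    j = resseq - spec.n_tm - 1
    y = -31.5 + _GRID_STEP * (j % _ROW_LEN)
    z = 4.0 + _GRID_STEP * (j // _ROW_LEN)
    pos = np.array([x_ca, y, z])
    sc = np.array([x_sc, y, z])
    return pos, sc


@dataclass
class ReceptorScaffold:
    """Receptor + membrane atoms plus the generator's recorded ground truth."""

    spec: FixtureSpec
    receptor_atoms: list[AtomSite]
    membrane_atoms: list[AtomSite]
    receptor_chains: dict[str, str]
    slab: MembraneSlab
    planted_segments: list[InterfaceSegment]
    cavity_center: np.ndarray  # CA centroid of the planted segments
    interface_z: float  # CA centroid z of the planted segments

    def planted_residues(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for seg in self.planted_segments:
            out |= seg.residues()
        return out

    def with_ligand(
        self,
        ligand_atoms: list[AtomSite],
        *,
        model_id: str,
        ligand_chain: str | None,
        conformation: str = "E1P",
        isoform: str = "Ab42",
    ) -> ComplexModel:
        return ComplexModel(
            model_id=model_id,
            receptor_chains=dict(self.receptor_chains),
            receptor_atoms=list(self.receptor_atoms),
            ligand_atoms=ligand_atoms,
            ligand_chain=ligand_chain,
            membrane_atoms=list(self.membrane_atoms),
            conformation=conformation,
            isoform=isoform,
        )

    def ground_truth(self) -> dict:
        return {
            "slab": [self.slab.z_min, self.slab.z_max],
            "cavity_center": [round(float(v), 3) for v in self.cavity_center],
            "interface_z": round(self.interface_z, 3),
            "planted_segments": [
                {"chain": s.chain, "start": s.start, "end": s.end}
                for s in self.planted_segments
            ],
        }


def make_receptor(spec: FixtureSpec) -> ReceptorScaffold:
    """Two pseudo-walls flanking a cavity on the +z side of a membrane slab.

    The receptor itself is rigid and deterministic (no jitter): every model
    of an ensemble shares it, as MD end-frames of one receptor would share a
    topology.  Membrane pseudo-atoms (resname MEM, atom P) tile the two slab
    boundary planes so the slab can be re-inferred from the file alone.
    """
    atoms: list[AtomSite] = []
    serial = 0
    for chain, n_res in (("A", spec.n_res_alpha), ("B", spec.n_res_beta)):
        for resseq in range(1, n_res + 1):
            ca, sc = _residue_xyz(spec, chain, resseq)
            for name, pos in (("CA", ca), ("CB", sc)):
                serial += 1
                atoms.append(
                    AtomSite(
                        serial=serial,
                        name=name,
                        element="C",
                        residue_seq=resseq,
                        residue_name="ALA",
                        chain_id=chain,
                        coords=(float(pos[0]), float(pos[1]), float(pos[2])),
                    )
                )
    slab = MembraneSlab(*spec.slab)
    membrane: list[AtomSite] = []
    mem_res = 0
    for z_plane in (slab.z_min, slab.z_max):
        for xi in range(-3, 4):
            for yi in range(-3, 4):
                mem_res += 1
                serial += 1
                membrane.append(
                    AtomSite(
                        serial=serial,
                        name="P",
                        element="P",
                        residue_seq=mem_res,
                        residue_name="MEM",
                        chain_id="M",
                        coords=(10.0 * xi, 10.0 * yi, z_plane),
                        is_hetero=True,
                    )
                )
    segments = [InterfaceSegment(c, s, e) for c, s, e in spec.planted_segments]
    ca_pts = []
    for seg in segments:
        for res in range(seg.start, seg.end + 1):
            ca_pts.append(_residue_xyz(spec, seg.chain, res)[0])
    ca_pts = np.array(ca_pts)
    center = ca_pts.mean(axis=0)
    return ReceptorScaffold(
        spec=spec,
        receptor_atoms=atoms,
        membrane_atoms=membrane,
        receptor_chains={"A": ALPHA, "B": BETA},
        slab=slab,
        planted_segments=segments,
        cavity_center=center,
        interface_z=float(ca_pts[:, 2].mean()),
    )


# ---------------------------------------------------------------------------
# Peptide poses
# ---------------------------------------------------------------------------


def _anchor_points(
    spec: FixtureSpec, segments: Sequence[InterfaceSegment]
) -> list[np.ndarray]:
    """Anchor positions covering every residue of the given segments.

    Adjacent same-row residues share one anchor placed between their
    side-chain atoms (still within the contact cutoff of both); residues at
    row boundaries get their own anchor.
    """
    anchors: list[np.ndarray] = []
    for seg in segments:
        res = list(range(seg.start, seg.end + 1))
        i = 0
        while i < len(res):
            _, sc1 = _residue_xyz(spec, seg.chain, res[i])
            pair = None
            if i + 1 < len(res):
                _, sc2 = _residue_xyz(spec, seg.chain, res[i + 1])
                same_row = abs(sc1[2] - sc2[2]) < 1e-9 and abs(abs(sc1[1] - sc2[1]) - _GRID_STEP) < 1e-9
                if same_row:
                    pair = sc2
            inward = np.array([_ANCHOR_INSET if seg.chain == "A" else -_ANCHOR_INSET, 0.0, 0.0])
            if pair is not None:
                anchors.append((sc1 + pair) / 2 + inward)
                i += 2
            else:
                anchors.append(sc1 + inward)
                i += 1
    return anchors


def _peptide_atoms(
    positions: dict[int, np.ndarray], rng: np.random.Generator, sigma: float
) -> list[AtomSite]:
    """Two heavy atoms (CA + side-chain pseudo-atom) per peptide residue."""
    atoms: list[AtomSite] = []
    serial = 9000
    for resseq in sorted(positions):
        base = positions[resseq] + rng.normal(0.0, sigma, size=3)
        cb = base + np.array([0.0, 0.0, 0.7])
        for name, pos in (("CA", base), ("CB", cb)):
            serial += 1
            atoms.append(
                AtomSite(
                    serial=serial,
                    name=name,
                    element="C",
                    residue_seq=resseq,
                    residue_name="ALA",
                    chain_id="P",
                    coords=(float(pos[0]), float(pos[1]), float(pos[2])),
                )
            )
    return atoms


def _ring(center: np.ndarray, n: int, radius: float, phase: float = 0.0) -> list[np.ndarray]:
    """n points on a y-z-plane ring around ``center`` (x fixed)."""
    out = []
    for k in range(n):
        theta = phase + 2 * np.pi * k / max(n, 1)
        out.append(center + np.array([0.0, radius * np.cos(theta), radius * np.sin(theta)]))
    return out


def plant_peptide_pose(
    scaffold: ReceptorScaffold,
    pose_class: PoseClass = "good",
    orientation: Literal["C_in", "N_in"] = "C_in",
    seed: int = 0,
    *,
    model_id: str | None = None,
    conformation: str = "E1P",
    isoform: str = "Ab42",
    noise_sigma: float | None = None,
) -> ComplexModel:
    """One peptide pose of a prescribed class.

    ``good`` poses contact every planted segment, stay clear of the slab and
    keep well over the required fraction of residues near the cavity centre.
    ``membrane_violator`` dips part of the chain into the slab and violates
    nothing else; ``single_point`` contacts only the first planted segment;
    ``far`` floats 60 A away from the receptor.
    """
    spec = scaffold.spec
    sigma = spec.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(seed)
    n = spec.peptide_length
    window = 5
    segments = scaffold.planted_segments
    if pose_class == "single_point":
        segments = segments[:1]
    anchors = _anchor_points(spec, segments) if pose_class != "far" else []
    if len(anchors) > n - 2 * window:
        raise ValueError("peptide too short to cover the planted segments")

    # the "mouth" point sits on the cavity axis mid-gap, safely off both walls
    mouth = np.array([0.0, scaffold.cavity_center[1], scaffold.cavity_center[2]])
    away = mouth + np.array([0.0, 0.0, 28.0])

    n_idx = list(range(1, window + 1))
    c_idx = list(range(n - window + 1, n + 1))
    inner_idx = [i for i in range(window + 1, n - window + 1)]
    anchor_idx = inner_idx[: len(anchors)]
    cluster_idx = inner_idx[len(anchors):]

    positions: dict[int, np.ndarray] = {}
    near_idx, far_idx = (c_idx, n_idx) if orientation == "C_in" else (n_idx, c_idx)
    for i, p in zip(near_idx, _ring(mouth, len(near_idx), 2.0)):
        positions[i] = p
    for i, p in zip(far_idx, _ring(away, len(far_idx), 2.0, phase=0.5)):
        positions[i] = p
    for i, p in zip(anchor_idx, anchors):
        positions[i] = p
    for i, p in zip(cluster_idx, _ring(mouth, len(cluster_idx), 3.0, phase=1.0)):
        positions[i] = p

    if pose_class == "membrane_violator":
        # dip six mid-chain cluster residues into the slab; everything else intact
        dip = cluster_idx[:6]
        z_mid = 0.5 * (scaffold.slab.z_min + scaffold.slab.z_max)
        for k, i in enumerate(dip):
            positions[i] = np.array([0.0, scaffold.cavity_center[1] + 2.0 * k, z_mid])
    elif pose_class == "far":
        shift = np.array([60.0, 0.0, 0.0])
        positions = {i: p + shift for i, p in positions.items()}

    atoms = _peptide_atoms(positions, rng, sigma)
    return scaffold.with_ligand(
        atoms,
        model_id=model_id or f"{conformation}_{pose_class}_{seed}",
        ligand_chain="P",
        conformation=conformation,
        isoform=isoform,
    )


# ---------------------------------------------------------------------------
# Compound poses
# ---------------------------------------------------------------------------


def plant_compound_pose(
    scaffold: ReceptorScaffold,
    fate_class: FateLabel,
    seed: int = 0,
    *,
    model_id: str | None = None,
    conformation: str = "E1P",
) -> ComplexModel:
    """One 12-atom HETATM compound pose engineered for a prescribed fate."""
    spec = scaffold.spec
    rng = np.random.default_rng(seed)
    n = spec.compound_atoms
    center = scaffold.cavity_center

    if fate_class is FateLabel.INTERFACE_BOUND:
        # hug three residues of the topmost planted segment (well above the
        # interface-centroid z, so the cavity test cannot fire first)
        top = max(scaffold.planted_segments, key=lambda s: _residue_xyz(spec, s.chain, s.start)[0][2])
        res = list(range(top.start, top.end + 1))[:3]
        base_pts = []
        for r in res:
            _, sc = _residue_xyz(spec, top.chain, r)
            inward = np.array([_ANCHOR_INSET if top.chain == "A" else -_ANCHOR_INSET, 0, 0])
            base_pts.append(sc + inward)
        pts = [base_pts[k % 3] + rng.normal(0, 0.4, 3) * (k >= 3) for k in range(n)]
    elif fate_class is FateLabel.CAVITY_ENTERED:
        axis_pt = np.array([center[0], center[1], scaffold.interface_z - 10.0])
        pts = _ring(axis_pt, n, 2.0)
    elif fate_class is FateLabel.MEMBRANE_EMBEDDED:
        z_mid = 0.5 * (scaffold.slab.z_min + scaffold.slab.z_max)
        pts = _ring(np.array([0.0, 0.0, z_mid]), n, 2.0)
    elif fate_class is FateLabel.DISPLACED:
        pts = _ring(center + np.array([50.0, 0.0, 10.0]), n, 2.0)
    else:  # pragma: no cover - exhaustive over FateLabel
        raise ValueError(f"unknown fate class {fate_class}")

    atoms = []
    for k, p in enumerate(pts):
        p = np.asarray(p, dtype=float) + rng.normal(0.0, 0.1, size=3)
        atoms.append(
            AtomSite(
                serial=9500 + k,
                name=f"C{k + 1}",
                element="C",
                residue_seq=901,
                residue_name="LIG",
                chain_id="X",
                coords=(float(p[0]), float(p[1]), float(p[2])),
                is_hetero=True,
            )
        )
    return scaffold.with_ligand(
        atoms,
        model_id=model_id or f"{conformation}_{fate_class.value}_{seed}",
        ligand_chain=None,
        conformation=conformation,
    )


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


def ensemble_plan(spec: FixtureSpec) -> list[dict]:
    """Deterministic per-model plan (conformation, isoform, class, orientation).

    Decoys (one of each violator class, round-robin) fill the trailing
    ``decoy_fraction`` of each conformation's models; good poses alternate
    C-in / N-in orientations.
    """
    n_decoys = int(round(spec.decoy_fraction * spec.n_models))
    plan = []
    for ci, conf in enumerate(spec.conformations):
        for m in range(spec.n_models):
            if m < spec.n_models - n_decoys:
                cls: PoseClass = "good"
                orientation = "C_in" if m % 2 == 0 else "N_in"
            else:
                cls = POSE_CLASSES[1 + (m - (spec.n_models - n_decoys)) % 3]
                orientation = "C_in"
            plan.append(
                {
                    "model_id": f"{conf}_{m:02d}",
                    "conformation": conf,
                    "isoform": spec.isoforms[m % len(spec.isoforms)],
                    "pose_class": cls,
                    "orientation": orientation,
                    "seed": spec.seed * 100003 + ci * 1009 + m,
                }
            )
    return plan


def build_ensemble(spec: FixtureSpec) -> tuple[ReceptorScaffold, list[ComplexModel], list[dict]]:
    """In-memory ensemble following :func:`ensemble_plan`."""
    scaffold = make_receptor(spec)
    plan = ensemble_plan(spec)
    models = [
        plant_peptide_pose(
            scaffold,
            pose_class=entry["pose_class"],
            orientation=entry["orientation"],
            seed=entry["seed"],
            model_id=entry["model_id"],
            conformation=entry["conformation"],
            isoform=entry["isoform"],
        )
        for entry in plan
    ]
    return scaffold, models, plan


def make_ensemble(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write a fixture directory: pose PDBs, metadata TSV, ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scaffold, models, plan = build_ensemble(spec)
    for entry, model in zip(plan, models):
        write_complex_pdb(model, outdir / f"{entry['model_id']}.pdb")
    meta = pd.DataFrame(plan)
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    truth = {"spec_seed": spec.seed, **scaffold.ground_truth(), "models": plan}
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth


def plant_orientation_series(
    scaffold: ReceptorScaffold, n_c_in: int = 17, n_n_in: int = 13, seed: int = 0
) -> list[ComplexModel]:
    """Good poses with a prescribed C-in / N-in orientation split."""
    models = []
    flags = ["C_in"] * n_c_in + ["N_in"] * n_n_in
    for k, orient in enumerate(flags):
        models.append(
            plant_peptide_pose(
                scaffold,
                pose_class="good",
                orientation=orient,  # type: ignore[arg-type]
                seed=seed * 4099 + k,
                model_id=f"orient_{k:02d}",
            )
        )
    return models


def make_screening_set(
    scaffold: ReceptorScaffold, outcome_frame: pd.DataFrame, seed: int = 0
) -> dict[tuple[str, str], ComplexModel]:
    """Compound poses realising a planned fate per (compound, conformation).

    ``outcome_frame`` needs columns compound_id, conformation, fate (a
    FateLabel value string), as produced by ``datasets.screening_table``.
    """
    out: dict[tuple[str, str], ComplexModel] = {}
    for k, row in enumerate(outcome_frame.itertuples(index=False)):
        fate = FateLabel(row.fate)
        out[(row.compound_id, row.conformation)] = plant_compound_pose(
            scaffold,
            fate,
            seed=seed * 65537 + k,
            model_id=f"{row.compound_id}_{row.conformation}",
            conformation=row.conformation,
        )
    return out
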