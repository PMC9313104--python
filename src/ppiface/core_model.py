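"""Structure data model and PDB I/O with explicit chain roles and membrane geometry.

A :class:`ComplexModel` bundles one receptor--ligand structure: the receptor
chains with their subunit roles (catalytic alpha, auxiliary beta), a ligand
that is either a peptide chain or a set of HETATM sites for a small-molecule
compound, and optionally explicit membrane atoms.  The membrane is abstracted
as a z-slab (:class:`MembraneSlab`): the bilayer normal is taken along z, so a
single [z_min, z_max] interval is enough for all geometry tests downstream.

Hydrogens are ignored everywhere (heavy atoms only): docking and MD outputs
vary in protonation, and every distance criterion in this package is defined
on heavy atoms.  Residue numbering is author (PDB) numbering, 1-based, with
inclusive segment ranges.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml

# Subunit roles a receptor chain may declare.
ALPHA = "alpha_subunit"
BETA = "beta_subunit"
CHAIN_ROLES = (ALPHA, BETA)

#: Conformation tags with a declared meaning; arbitrary user tags are allowed.
KNOWN_CONFORMATIONS = ("E1", "E2", "E1P", "E2P", "OBN", "E1/E2")
#: Amyloid-beta isoform tags with a declared meaning.
KNOWN_ISOFORMS = ("Ab42", "isoD7", "pS8")

#: Residue names treated as membrane pseudo-atoms / lipids by default.
DEFAULT_MEMBRANE_RESNAMES = ("MEM", "DUM", "DPP", "DPPC", "POPC", "DDPC")
_WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})


class PPIfaceError(Exception):
    """Base class for structured errors raised by this package."""


class MissingChainError(PPIfaceError):
    def __init__(self, chain_id: str, path: str | None = None):
        self.chain_id = chain_id
        where = f" in {path}" if path else ""
        super().__init__(f"declared chain {chain_id!r} not found{where}")


class LigandError(PPIfaceError):
    pass


class InsertionCodeError(PPIfaceError):
    pass


class EmptySelectionError(PPIfaceError):
    pass


@dataclass(frozen=True, slots=True)
class AtomSite:
    """One heavy atom with author numbering preserved exactly."""

    serial: int
    name: str
    element: str
    residue_seq: int
    residue_name: str
    chain_id: str
    coords: tuple[float, float, float]
    is_hetero: bool = False

    def __post_init__(self):
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


def coords_array(atoms: Sequence[AtomSite]) -> np.ndarray:
    """(N, 3) coordinate array for a list of atoms (empty -> shape (0, 3))."""
    if not atoms:
        return np.zeros((0, 3))
    return np.array([a.coords for a in atoms], dtype=float)


@dataclass(frozen=True, slots=True)
class MembraneSlab:
    """Membrane bilayer as a slab normal to the z axis, bounds in Angstrom."""

    z_min: float
    z_max: float

    def __post_init__(self):
        if not self.z_min < self.z_max:
            raise ValueError(f"slab requires z_min < z_max, got ({self.z_min}, {self.z_max})")

    def contains_z(self, z) -> np.ndarray | bool:
        return (np.asarray(z) >= self.z_min) & (np.asarray(z) <= self.z_max)


@dataclass
class ComplexModel:
    """One receptor(+membrane)+ligand structure with chain roles and tags."""

    model_id: str
    receptor_chains: dict[str, str]
    receptor_atoms: list[AtomSite]
    ligand_atoms: list[AtomSite]
    ligand_chain: str | None = None  # set for peptide ligands, None for compounds
    membrane_atoms: list[AtomSite] = field(default_factory=list)
    conformation: str = "unspecified"
    isoform: str = "unspecified"

    def __post_init__(self):
        if not self.receptor_chains:
            raise ValueError("at least one receptor chain is required")
        for cid, role in self.receptor_chains.items():
            if role not in CHAIN_ROLES:
                raise ValueError(f"unknown chain role {role!r} for chain {cid!r}")
        if not self.ligand_atoms:
            raise LigandError(f"model {self.model_id!r} has zero ligand atoms")
        if self.ligand_chain is not None and self.ligand_chain in self.receptor_chains:
            raise ValueError(
                f"ligand chain {self.ligand_chain!r} collides with a receptor chain"
            )
        if not self.conformation or not self.isoform:
            raise ValueError("conformation and isoform tags must be non-empty")

    # -- receptor helpers -------------------------------------------------

    @property
    def ligand_is_peptide(self) -> bool:
        return self.ligand_chain is not None

    def receptor_residues(self, chain_id: str | None = None) -> list[tuple[str, int]]:
        """Sorted (chain, residue_seq) keys present in the receptor."""
        keys = {
            (a.chain_id, a.residue_seq)
            for a in self.receptor_atoms
            if chain_id is None or a.chain_id == chain_id
        }
        return sorted(keys)

    def ligand_residues(self) -> list[int]:
        return sorted({a.residue_seq for a in self.ligand_atoms})

    def ca_coords(self, keys: Iterable[tuple[str, int]]) -> np.ndarray:
        """C-alpha coordinates for the requested (chain, residue) keys.

        Residues without a CA atom are silently skipped (HETATM groups have
        none); callers that need completeness check the returned length.
        """
        want = set(keys)
        pts = [
            a.coords
            for a in self.receptor_atoms
            if a.name == "CA" and (a.chain_id, a.residue_seq) in want
        ]
        return np.array(pts, dtype=float) if pts else np.zeros((0, 3))

    def ligand_centroid(self) -> np.ndarray:
        return coords_array(self.ligand_atoms).mean(axis=0)


# ---------------------------------------------------------------------------
# PDB reading / writing (gemmi backend)
# ---------------------------------------------------------------------------


def _select_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy wins, tie -> first seen."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of the winning atoms
    chosen = set(id(a) for a in best.values())
    return [a for a in residue if id(a) in chosen]


def read_complex_pdb(
    path: str | Path,
    receptor_roles: Mapping[str, str],
    *,
    ligand_chain: str | None = None,
    ligand_resnames: Sequence[str] | None = None,
    membrane_resnames: Sequence[str] = DEFAULT_MEMBRANE_RESNAMES,
    conformation: str = "unspecified",
    isoform: str = "unspecified",
    model_id: str | None = None,
) -> ComplexModel | list[ComplexModel]:
    """Read a (possibly multi-MODEL) PDB file into ComplexModel objects.

    The ligand is either a declared peptide chain (``ligand_chain``) or the
    HETATM residues whose name is in ``ligand_resnames``.  Hydrogens and
    waters are dropped; alternate locations resolve to highest occupancy;
    author residue numbering is preserved exactly.  Returns a single model
    for single-MODEL files, otherwise a list.
    """
    if ligand_chain is None and not ligand_resnames:
        raise LigandError("declare either ligand_chain or ligand_resnames")
    path = Path(path)
    structure = gemmi.read_pdb(str(path))
    membrane_set = {r.upper() for r in membrane_resnames}
    ligand_set = {r.upper() for r in ligand_resnames} if ligand_resnames else set()

    out: list[ComplexModel] = []
    for imodel, model in enumerate(structure, start=1):
        rec: list[AtomSite] = []
        lig: list[AtomSite] = []
        mem: list[AtomSite] = []
        seen_chains: set[str] = set()
        for chain in model:
            seen_chains.add(chain.name)
            for residue in chain:
                if residue.seqid.icode not in (" ", "", "\x00"):
                    raise InsertionCodeError(
                        f"insertion code {residue.seqid.icode!r} at "
                        f"{chain.name}:{residue.seqid.num} is not supported"
                    )
                resname = residue.name.upper()
                if resname in _WATER_RESNAMES:
                    continue
                for atom in _select_altlocs(residue):
                    if atom.element.is_hydrogen:
                        continue
                    site = AtomSite(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name,
                        residue_seq=residue.seqid.num,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        is_hetero=residue.het_flag == "H",
                    )
                    if chain.name in receptor_roles and resname not in membrane_set:
                        rec.append(site)
                    elif chain.name == ligand_chain:
                        lig.append(site)
                    elif resname in ligand_set:
                        lig.append(site)
                    elif resname in membrane_set:
                        mem.append(site)
        for cid in receptor_roles:
            if cid not in seen_chains:
                raise MissingChainError(cid, str(path))
        if ligand_chain is not None and ligand_chain not in seen_chains:
            raise MissingChainError(ligand_chain, str(path))
        if not lig:
            raise LigandError(f"zero ligand atoms in {path} (model {imodel})")
        mid = model_id or path.stem
        if len(structure) > 1:
            mid = f"{mid}#{imodel}"
        out.append(
            ComplexModel(
                model_id=mid,
                receptor_chains=dict(receptor_roles),
                receptor_atoms=rec,
                ligand_atoms=lig,
                ligand_chain=ligand_chain,
                membrane_atoms=mem,
                conformation=conformation,
                isoform=isoform,
            )
        )
    return out[0] if len(out) == 1 else out


def write_complex_pdb(model: ComplexModel, path: str | Path) -> None:
    """Write a ComplexModel back to a single-MODEL PDB file."""
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    by_chain: dict[str, list[list[AtomSite]]] = {}
    for site in [*model.receptor_atoms, *model.ligand_atoms, *model.membrane_atoms]:
        groups = by_chain.setdefault(site.chain_id, [])
        if groups and (
            groups[-1][0].residue_seq == site.residue_seq
            and groups[-1][0].residue_name == site.residue_name
        ):
            groups[-1].append(site)
        else:
            groups.append([site])
    # gemmi add_* calls copy their argument, so each object is built fully
    # before being attached
    for cid, groups in by_chain.items():
        chain = gemmi.Chain(cid)
        for sites in groups:
            residue = gemmi.Residue()
            residue.name = sites[0].residue_name
            residue.seqid = gemmi.SeqId(sites[0].residue_seq, " ")
            residue.het_flag = "H" if sites[0].is_hetero else "A"
            for site in sites:
                atom = gemmi.Atom()
                atom.name = site.name
                atom.element = gemmi.Element(site.element)
                atom.serial = site.serial
                atom.pos = gemmi.Position(*site.coords)
                atom.occ = 1.0
                residue.add_atom(atom)
            chain.add_residue(residue)
        gm.add_chain(chain)
    st.add_model(gm)
    Path(path).write_text(st.make_pdb_string())


def infer_membrane_slab(model: ComplexModel, selector: str = "*") -> MembraneSlab:
    """Slab bounds from explicit membrane atoms matching an atom-name pattern.

    ``selector`` is an fnmatch-style pattern on atom names (e.g. ``"P*"``).
    z_min/z_max are the min/max z of the selected atoms; order-invariant.
    """
    zs = [a.coords[2] for a in model.membrane_atoms if fnmatch.fnmatch(a.name, selector)]
    if not zs:
        raise EmptySelectionError(
            f"membrane selector {selector!r} matched no atoms in model {model.model_id!r}"
        )
    return MembraneSlab(z_min=min(zs), z_max=max(zs))


# ---------------------------------------------------------------------------
# Receptor topology config
# ---------------------------------------------------------------------------

_REQUIRED_CONFIG_KEYS = ("receptor_chains",)


def load_receptor_config(path: str | Path) -> dict:
    """Load a YAML receptor topology config.

    Expected keys: ``receptor_chains`` (chain id -> role), and optionally
    ``ligand_chain`` or ``ligand_resnames``, ``slab`` ([z_min, z_max]),
    ``conformation``, ``isoform``, threshold overrides.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for key in _REQUIRED_CONFIG_KEYS:
        if key not in cfg:
            raise KeyError(key)
    for cid, role in cfg["receptor_chains"].items():
        if role not in CHAIN_ROLES:
            raise ValueError(f"config chain {cid!r} has unknown role {role!r}")
    if "slab" in cfg and cfg["slab"] is not None:
        z_min, z_max = cfg["slab"]
        cfg["slab"] = MembraneSlab(float(z_min), float(z_max))
    return cfg
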