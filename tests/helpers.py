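"""Shared test utilities: brute-force oracles and tiny model builders."""

from __future__ import annotations

import numpy as np

from ppiface.core_model import ALPHA, AtomSite, ComplexModel


def brute_force_contacts(model: ComplexModel, cutoff: float = 5.0) -> dict:
    """All-pairs O(N^2) contact oracle, independent of the k-d tree path.

    Returns {(chain, rec_res, lig_unit): min_distance} for pairs within
    cutoff, with the ligand grouped by residue.
    """
    best: dict = {}
    for ra in model.receptor_atoms:
        for la in model.ligand_atoms:
            d = float(np.linalg.norm(np.array(ra.coords) - np.array(la.coords)))
            if d <= cutoff:
                key = (ra.chain_id, ra.residue_seq, la.residue_seq)
                if d < best.get(key, np.inf):
                    best[key] = d
    return best


def mini_model(
    receptor: list[tuple[str, int, tuple[float, float, float]]],
    ligand: list[tuple[int, tuple[float, float, float]]],
    ligand_chain: str | None = "P",
    model_id: str = "mini",
) -> ComplexModel:
    """Hand-built model: receptor entries are (chain, resseq, xyz); ligand
    entries are (resseq, xyz).  One CA atom per receptor residue position."""
    rec = [
        AtomSite(i + 1, "CA", "C", res, "ALA", chain, xyz)
        for i, (chain, res, xyz) in enumerate(receptor)
    ]
    lig = [
        AtomSite(1000 + i, "CA", "C", res, "ALA" if ligand_chain else "LIG",
                 ligand_chain or "X", xyz, is_hetero=ligand_chain is None)
        for i, (res, xyz) in enumerate(ligand)
    ]
    chains = sorted({chain for chain, _, _ in receptor}) or ["A"]
    return ComplexModel(
        model_id=model_id,
        receptor_chains={c: ALPHA for c in chains},
        receptor_atoms=rec,
        ligand_atoms=lig,
        ligand_chain=ligand_chain,
    )


def random_contact_model(rng: np.random.Generator) -> ComplexModel:
    """Random small receptor + peptide ligand for oracle comparisons."""
    n_rec = int(rng.integers(20, 80))
    n_lig = int(rng.integers(5, 30))
    receptor = []
    for i in range(n_rec):
        chain = "A" if i < n_rec // 2 else "B"
        res = int(rng.integers(1, 40))
        xyz = tuple(rng.uniform(-15, 15, size=3))
        receptor.append((chain, res, xyz))
    ligand = [
        (int(rng.integers(1, 15)), tuple(rng.uniform(-15, 15, size=3)))
        for _ in range(n_lig)
    ]
    return mini_model(receptor, ligand, model_id=f"rand{rng.integers(1e6)}")
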