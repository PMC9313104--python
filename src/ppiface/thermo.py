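"""ITC-derived binding thermodynamics and conformational-state comparison.

Isothermal titration calorimetry yields, per receptor state, an association
constant Ka (M^-1) and a binding enthalpy dH (kcal/mol).  Everything else
follows from two identities:

    dG = -R T ln(Ka)          (standard Gibbs energy of association)
    dG = dH - T dS            (hence T dS = dH - dG)

with R = 1.9872e-3 kcal mol^-1 K^-1 and T = 298.15 K (25 C) by default.
Kd = 1/Ka is reported in micromolar.  Derivations are exact; rounding
happens only at the presentation layer (Kd to 2 significant figures,
energies to 2 decimals, the convention of published ITC tables).

``reconcile_row`` checks a published table row for internal consistency:
printed Ka values are themselves rounded, so a recomputed dG can differ from
the printed dG by a few hundredths of kcal/mol.  Rows outside a stated
reconciliation tolerance (default 0.02 kcal/mol) are flagged, not "fixed" --
the printed numbers stay authoritative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

R_KCAL = 1.9872e-3  # kcal mol^-1 K^-1
T_STANDARD = 298.15  # K, 25 C


@dataclass(frozen=True, slots=True)
class ThermoState:
    """One receptor state as measured by ITC."""

    label: str
    Ka: float  # M^-1
    dH: float  # kcal/mol
    T: float = T_STANDARD  # K
    n: float = 1.0  # binding stoichiometry
    dG_reported: float | None = None  # printed dG, if reconciling a table

    def __post_init__(self):
        if self.Ka <= 0:
            raise ValueError(f"Ka must be positive, got {self.Ka} for {self.label!r}")
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")


def state_from_kd(
    label: str, kd_uM: float, dH: float, T: float = T_STANDARD
) -> ThermoState:
    """Build a state from a dissociation constant in micromolar."""
    if kd_uM <= 0:
        raise ValueError("Kd must be positive")
    return ThermoState(label=label, Ka=1e6 / kd_uM, dH=dH, T=T)


@dataclass(frozen=True, slots=True)
class ThermoDerived:
    label: str
    Ka: float
    dH: float
    T: float
    Kd_uM: float
    dG: float
    TdS: float


def derive_thermo(state: ThermoState) -> ThermoDerived:
    """Exact Kd/dG/TdS from one (Ka, dH, T) triple; no rounding."""
    dG = -R_KCAL * state.T * math.log(state.Ka)
    return ThermoDerived(
        label=state.label,
        Ka=state.Ka,
        dH=state.dH,
        T=state.T,
        Kd_uM=1e6 / state.Ka,
        dG=dG,
        TdS=state.dH - dG,
    )


def tds_from_printed(dH: float, dG: float) -> float:
    """Entropy term as published ITC tables derive it: TdS = dH - dG(printed)."""
    return dH - dG


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def format_derived(d: ThermoDerived) -> dict:
    """Presentation-layer rounding: Kd 2 sig figs, energies 2 decimals."""
    return {
        "label": d.label,
        "Kd_uM": round_sig(d.Kd_uM, 2),
        "dG": round(d.dG, 2),
        "TdS": round(d.TdS, 2),
        "dH": round(d.dH, 2),
    }


# ---------------------------------------------------------------------------
# Table reconciliation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReconciledRow:
    """Comparison of derived quantities against one printed table row."""

    label: str
    Kd_uM_derived: float
    Kd_uM_printed: float
    Kd_consistent: bool
    dG_derived: float  # unrounded -RT ln Ka
    dG_printed: float
    dG_deviation: float  # |rounded derived - printed|
    dG_consistent: bool
    TdS_derived: float  # dH - dG_printed, the table's own derivation
    TdS_printed: float
    TdS_consistent: bool

    @property
    def consistent(self) -> bool:
        return self.Kd_consistent and self.dG_consistent and self.TdS_consistent


def reconcile_row(
    state: ThermoState,
    printed_Kd_uM: float,
    printed_TdS: float,
    printed_dG: float,
    dG_tolerance: float = 0.02,
) -> ReconciledRow:
    """Check one printed (Ka, dH, Kd, TdS, dG) row for internal consistency.

    Kd is compared after rounding to 2 significant figures; TdS is derived
    as dH - dG(printed) and compared at 2 decimals; dG is recomputed from Ka
    and compared to the printed value within ``dG_tolerance`` (printed Ka
    values are rounded, so small deviations are expected; larger ones flag
    the row as internally inconsistent).
    """
    d = derive_thermo(state)
    kd_rounded = round_sig(d.Kd_uM, 2)
    tds = tds_from_printed(state.dH, printed_dG)
    dg_dev = abs(round(d.dG, 2) - printed_dG)
    return ReconciledRow(
        label=state.label,
        Kd_uM_derived=kd_rounded,
        Kd_uM_printed=printed_Kd_uM,
        Kd_consistent=kd_rounded == printed_Kd_uM,
        dG_derived=d.dG,
        dG_printed=printed_dG,
        dG_deviation=round(dg_dev, 2),
        dG_consistent=dg_dev <= dG_tolerance + 1e-12,
        TdS_derived=round(tds, 2),
        TdS_printed=printed_TdS,
        TdS_consistent=round(tds, 2) == printed_TdS,
    )


# ---------------------------------------------------------------------------
# State similarity and competition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityReport:
    max_abs_ddG: float
    max_abs_ddH: float
    verdict: str  # "similar" | "not_similar"
    pairwise_ddG: dict[tuple[str, str], float] = field(default_factory=dict)


def compare_states(
    states: Sequence[ThermoState],
    tolerance_dG: float = 0.6,
    use_reported_dG: bool = True,
) -> SimilarityReport:
    """Maximum pairwise |ddG| and |ddH| across receptor states.

    The default tolerance of 0.6 kcal/mol corresponds to the ~20% relative
    uncertainty typical of ITC association constants (RT ln 1.2 x 2 ~ 0.2;
    0.6 leaves headroom for the enthalpy split).  When every state carries a
    printed dG and ``use_reported_dG`` is set, the comparison uses those
    values; otherwise dG is derived from Ka.
    """
    if len(states) < 2:
        raise ValueError("need at least two states to compare")
    if use_reported_dG and all(s.dG_reported is not None for s in states):
        dgs = {s.label: s.dG_reported for s in states}
    else:
        dgs = {s.label: derive_thermo(s).dG for s in states}
    dhs = {s.label: s.dH for s in states}
    pairwise = {
        (a, b): abs(dgs[a] - dgs[b]) for a, b in combinations(sorted(dgs), 2)
    }
    max_ddg = max(pairwise.values())
    max_ddh = max(abs(dhs[a] - dhs[b]) for a, b in combinations(sorted(dhs), 2))
    return SimilarityReport(
        max_abs_ddG=max_ddg,
        max_abs_ddH=max_ddh,
        verdict="similar" if max_ddg <= tolerance_dG else "not_similar",
        pairwise_ddG={k: round(v, 4) for k, v in pairwise.items()},
    )


def competition_check(
    free: ThermoState, in_complex: ThermoState, tolerance_dG: float = 0.6
) -> tuple[bool, float]:
    """Does a co-ligand leave binding unchanged?

    Compares derived dG of the receptor alone vs the receptor pre-bound with
    the co-ligand; returns (unchanged, |ddG|).
    """
    ddg = abs(derive_thermo(free).dG - derive_thermo(in_complex).dG)
    return ddg <= tolerance_dG, ddg


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_states_tsv(path: str | Path) -> list[ThermoState]:
    """Read states from TSV with columns: label, Ka, dH [, T, dG_reported]."""
    frame = pd.read_csv(path, sep="\t")
    states = []
    for _, row in frame.iterrows():
        states.append(
            ThermoState(
                label=str(row["label"]),
                Ka=float(row["Ka"]),
                dH=float(row["dH"]),
                T=float(row["T"]) if "T" in frame.columns and not pd.isna(row.get("T")) else T_STANDARD,
                dG_reported=(
                    float(row["dG_reported"])
                    if "dG_reported" in frame.columns and not pd.isna(row.get("dG_reported"))
                    else None
                ),
            )
        )
    return states


def derived_table(states: Sequence[ThermoState]) -> pd.DataFrame:
    """Derived thermodynamics for many states, raw and presentation columns."""
    rows = []
    for s in states:
        d = derive_thermo(s)
        pres = format_derived(d)
        rows.append(
            {
                "label": s.label,
                "Ka": s.Ka,
                "dH": s.dH,
                "T": s.T,
                "Kd_uM_raw": d.Kd_uM,
                "dG_raw": d.dG,
                "TdS_raw": d.TdS,
                "Kd_uM": pres["Kd_uM"],
                "dG": pres["dG"],
                "TdS": pres["TdS"],
            }
        )
    return pd.DataFrame(rows)


def write_derived(
    states: Sequence[ThermoState], tsv_path: str | Path, json_path: str | Path | None = None
) -> pd.DataFrame:
    frame = derived_table(states)
    frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    return frame
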