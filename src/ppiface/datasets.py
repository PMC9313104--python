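"""Reference data for the Na,K-ATPase / amyloid-beta system.

Small, published-table-sized inputs typed in as code so that analyses and
tests run without any download: ITC thermodynamics of Ab42 binding to
Na,K-ATPase in five states, the ouabain competition measurements, the
reported interface segments per receptor conformation and pipeline stage,
and the screening outcome table for the ten top-rated candidate inhibitors
across three conformations.
"""

from __future__ import annotations

import pandas as pd

from .contacts import InterfaceSegment
from .ligand_fate import FateLabel
from .thermo import ThermoState, state_from_kd

# ---------------------------------------------------------------------------
# ITC thermodynamics: Ab42 binding to Na,K-ATPase in five states at 25 C.
# Columns beyond (Ka, dH) are the printed derived cells used for
# reconciliation: Kd in uM, TdS and dG in kcal/mol.
# ---------------------------------------------------------------------------

_ITC_ROWS = [
    # state,   Ka (M^-1), dH,    Kd_uM, TdS,  dG
    ("E1/E2", 7.7e5, -2.54, 1.3, 5.48, -8.02),
    ("E1", 3.7e5, -1.54, 2.7, 6.02, -7.56),
    ("E2", 4.9e5, -2.21, 2.0, 5.55, -7.76),
    ("E2P", 5.1e5, -1.59, 2.0, 6.19, -7.78),
    ("OBN", 8.3e5, -1.21, 1.2, 6.87, -8.08),
]


def itc_table() -> pd.DataFrame:
    """ITC parameters for Ab42 binding to the pump in five states."""
    return pd.DataFrame(
        _ITC_ROWS, columns=["state", "Ka", "dH", "Kd_uM", "TdS", "dG"]
    )


def itc_states() -> list[ThermoState]:
    """The five measured states with printed dG attached for reconciliation."""
    return [
        ThermoState(label=state, Ka=Ka, dH=dH, dG_reported=dG)
        for state, Ka, dH, _, _, dG in _ITC_ROWS
    ]


def ouabain_competition_states() -> tuple[ThermoState, ThermoState]:
    """Ouabain binding to the free pump (E2P) vs the pump pre-bound with Ab42.

    Measured: free enzyme Kd = 0.10 uM, dH = -13.7 kcal/mol (printed
    TdS = -4.2); with Ab42 bound Kd = 0.12 uM, dH = -20.2 (printed
    TdS = -10.8).
    """
    free = state_from_kd("OBN_free", kd_uM=0.10, dH=-13.7)
    in_complex = state_from_kd("OBN_with_Ab42", kd_uM=0.12, dH=-20.2)
    return free, in_complex


OUABAIN_PRINTED_TDS = {"OBN_free": -4.2, "OBN_with_Ab42": -10.8}


# ---------------------------------------------------------------------------
# Reported interface segments per conformation and stage (alpha chain "A",
# beta chain "B"); author numbering, inclusive ranges, as printed.
# ---------------------------------------------------------------------------

_INTERFACE_SITES: dict[str, dict[str, dict[str, list[tuple[int, int]]]]] = {
    "E1P": {
        "docking": {
            "A": [(121, 124), (312, 317), (887, 893)],
            "B": [(84, 87), (216, 222), (270, 273), (287, 290)],
        },
        "refined": {
            "A": [(117, 126), (311, 318), (794, 794), (884, 894)],
            "B": [(82, 87), (91, 111), (196, 196), (217, 217), (266, 273), (287, 298)],
        },
    },
    "E2P": {
        "docking": {
            "A": [(113, 128), (309, 316), (883, 900), (970, 979)],
            "B": [(82, 107), (197, 197), (216, 226), (267, 273), (285, 290), (294, 303)],
        },
        "refined": {
            "A": [(117, 124), (310, 316), (879, 879), (883, 883), (886, 893), (970, 979)],
            "B": [(83, 85), (91, 107), (217, 218), (268, 273), (287, 290)],
        },
    },
    "OBN": {
        "docking": {
            "A": [(117, 125), (309, 317), (886, 893), (969, 979)],
            "B": [(82, 87), (96, 107), (216, 221), (271, 273), (287, 290)],
        },
        "refined": {
            "A": [(115, 125), (306, 317), (792, 795), (879, 879), (883, 883), (886, 893), (974, 974)],
            # first beta range reproduced as printed (2-87)
            "B": [(2, 87), (91, 91), (100, 100), (103, 107), (216, 218), (273, 273), (287, 290), (294, 294)],
        },
    },
}


def reported_interface_segments(
    conformation: str, stage: str
) -> list[InterfaceSegment]:
    """Reported interface segments for one conformation at one stage."""
    ranges = _INTERFACE_SITES[conformation][stage]
    return [
        InterfaceSegment(chain, start, end)
        for chain in sorted(ranges)
        for start, end in ranges[chain]
    ]


#: Target-site definition used for inhibitor screening: the four consensus
#: regions (three on the alpha-subunit, one on the beta-subunit).
TARGET_SITE_SEGMENTS = [
    InterfaceSegment("A", 119, 124),
    InterfaceSegment("A", 311, 315),
    InterfaceSegment("A", 887, 897),
    InterfaceSegment("B", 84, 88),
]

#: Beta-subunit regions far from the inter-subunit cavity, excluded from the
#: target-site definition (assumed not to contribute to pump inhibition).
BETA_EXCLUSION_SEGMENTS = [
    (InterfaceSegment("B", 216, 226), "far from the inter-subunit cavity"),
    (InterfaceSegment("B", 267, 273), "far from the inter-subunit cavity"),
    (InterfaceSegment("B", 285, 290), "far from the inter-subunit cavity"),
]


# ---------------------------------------------------------------------------
# Inhibitor screening outcomes: ten top-rated compounds docked to three
# conformations; per conformation the docking rank, Vina affinity (kcal/mol)
# and the post-MD fate.  Fates encode the reported outcome pattern: six
# membrane events among the 30 complexes, two cavity-entering compounds
# (plus one compound with both a membrane and a cavity event), one compound
# interface-bound in all three conformations and two in two conformations.
# ---------------------------------------------------------------------------

_G = FateLabel.INTERFACE_BOUND
_Y = FateLabel.CAVITY_ENTERED
_R = FateLabel.MEMBRANE_EMBEDDED
_D = FateLabel.DISPLACED

_SCREENING_ROWS = [
    # compound,  (rank, affinity, fate) for E1P, E2P, OBN
    ("NCI39918", (1, -9.4, _G), (4, -8.0, _D), (3, -8.6, _D)),
    ("NCI610512", (2, -9.3, _R), (7, -7.4, _D), (5, -7.6, _Y)),
    ("NCI686480", (3, -9.1, _R), (3, -8.2, _R), (4, -8.1, _R)),
    ("NCI39921", (4, -8.9, _G), (1, -8.7, _D), (2, -8.7, _G)),
    ("NCI617551", (5, -8.9, _G), (2, -8.3, _G), (7, -7.4, _G)),
    ("NCI84171", (6, -8.7, _G), (5, -7.9, _D), (1, -8.9, _Y)),
    ("NCI298806", (7, -8.7, _D), (10, -5.6, _D), (9, -6.7, _Y)),
    ("NCI23128", (8, -8.7, _D), (8, -7.3, _G), (6, -7.6, _D)),
    ("NCI688806", (9, -8.7, _R), (6, -7.6, _R), (8, -7.4, _D)),
    ("NCI58783", (10, -8.6, _G), (9, -6.5, _G), (10, -6.4, _D)),
]

SCREENING_CONFORMATIONS = ("E1P", "E2P", "OBN")


def screening_table() -> pd.DataFrame:
    """Long-format screening outcomes: one row per compound x conformation."""
    rows = []
    for compound, *per_conf in _SCREENING_ROWS:
        for conf, (rank, affinity, fate) in zip(SCREENING_CONFORMATIONS, per_conf):
            rows.append(
                {
                    "compound_id": compound,
                    "conformation": conf,
                    "docking_rank": rank,
                    "affinity": affinity,
                    "fate": fate.value,
                }
            )
    return pd.DataFrame(rows)
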