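"""Compound fate classification precedence and screening triage rules."""

import pytest

from ppiface import datasets
from ppiface.core_model import PPIfaceError
from ppiface.ligand_fate import (
    CompoundRecord,
    ConformationOutcome,
    FateLabel,
    FateParams,
    classify_fate,
    fate_report,
    records_from_frame,
    triage_compounds,
)
from ppiface.synthetic_fixtures import plant_compound_pose, plant_peptide_pose


class TestClassifyFate:
    @pytest.mark.parametrize("fate", list(FateLabel))
    def test_planted_fates_recovered(self, scaffold, cavity, fate):
        model = plant_compound_pose(scaffold, fate, seed=21)
        got, metrics = classify_fate(model, scaffold.planted_residues(), scaffold.slab, cavity)
        assert got is fate
        if fate is FateLabel.MEMBRANE_EMBEDDED:
            assert metrics["membrane_fraction"] >= 0.5
        if fate is FateLabel.INTERFACE_BOUND:
            assert metrics["n_interface_contacts"] >= 3

    def test_exactly_one_label_per_pose(self, scaffold, cavity):
        labels = {
            classify_fate(
                plant_compound_pose(scaffold, fate, seed=3),
                scaffold.planted_residues(),
                scaffold.slab,
                cavity,
            )[0]
            for fate in FateLabel
        }
        assert labels == set(FateLabel)

    def test_membrane_takes_precedence(self, scaffold, cavity):
        """A pose half-buried in the slab is red even if near the axis."""
        model = plant_compound_pose(scaffold, FateLabel.MEMBRANE_EMBEDDED, seed=4)
        got, _ = classify_fate(
            model, scaffold.planted_residues(), scaffold.slab, cavity,
            FateParams(membrane_fraction=0.5),
        )
        assert got is FateLabel.MEMBRANE_EMBEDDED

    def test_peptide_ligand_rejected(self, scaffold, cavity):
        model = plant_peptide_pose(scaffold, "good", seed=1)
        with pytest.raises(PPIfaceError):
            classify_fate(model, scaffold.planted_residues(), scaffold.slab, cavity)


def _record(cid, fates, affinity=-8.0):
    outcomes = {
        conf: ConformationOutcome(docking_rank=i + 1, docking_affinity=affinity, fate=f)
        for i, (conf, f) in enumerate(fates.items())
    }
    return CompoundRecord(cid, outcomes)


G, Y, R, D = (
    FateLabel.INTERFACE_BOUND,
    FateLabel.CAVITY_ENTERED,
    FateLabel.MEMBRANE_EMBEDDED,
    FateLabel.DISPLACED,
)


class TestTriage:
    def test_full_blocker_ranks_first(self):
        records = [
            _record("CPD_A", {"E1P": G, "E2P": G, "OBN": G}),
            _record("CPD_B", {"E1P": G, "E2P": G, "OBN": D}),
        ]
        table = triage_compounds(records)
        assert [r.compound_id for r in table.survivors] == ["CPD_A", "CPD_B"]
        assert table.survivors[0].n_interface_bound == 3

    def test_single_membrane_event_eliminates(self):
        rec = _record("CPD_M", {"E1P": R, "E2P": R, "OBN": G})
        table = triage_compounds([rec])
        assert table.survivors == []
        assert table.eliminated[0][1] == "membrane"

    def test_membrane_plus_cavity_eliminated(self):
        rec = _record("CPD_MC", {"E1P": R, "E2P": D, "OBN": Y})
        table = triage_compounds([rec])
        assert table.eliminated[0][1] == "membrane"

    def test_insufficient_interface_eliminated(self):
        rec = _record("CPD_1", {"E1P": G, "E2P": D, "OBN": D})
        table = triage_compounds([rec])
        assert table.eliminated[0][1] == "insufficient_interface"

    def test_survivors_never_carry_red_or_yellow(self):
        records = [
            _record("A1", {"E1P": G, "E2P": G, "OBN": G}),
            _record("A2", {"E1P": G, "E2P": G, "OBN": Y}),
            _record("A3", {"E1P": G, "E2P": G, "OBN": R}),
        ]
        table = triage_compounds(records)
        for rec in table.survivors:
            assert not rec.has_fate(R) and not rec.has_fate(Y)

    def test_order_invariance(self):
        records = [
            _record("B1", {"E1P": G, "E2P": G, "OBN": D}, affinity=-9.0),
            _record("B2", {"E1P": G, "E2P": G, "OBN": G}, affinity=-7.0),
            _record("B3", {"E1P": R, "E2P": D, "OBN": D}),
        ]
        fwd = triage_compounds(records)
        rev = triage_compounds(list(reversed(records)))
        assert [r.compound_id for r in fwd.survivors] == [r.compound_id for r in rev.survivors]
        assert {r.compound_id for r, _ in fwd.eliminated} == {r.compound_id for r, _ in rev.eliminated}

    def test_affinity_breaks_count_ties(self):
        records = [
            _record("C_weak", {"E1P": G, "E2P": G, "OBN": D}, affinity=-7.0),
            _record("C_strong", {"E1P": G, "E2P": G, "OBN": D}, affinity=-9.0),
        ]
        table = triage_compounds(records)
        assert [r.compound_id for r in table.survivors] == ["C_strong", "C_weak"]

    def test_inconsistent_conformations_raise(self):
        records = [
            _record("D1", {"E1P": G, "E2P": G}),
            _record("D2", {"E1P": G, "OBN": G}),
        ]
        with pytest.raises(PPIfaceError):
            triage_compounds(records)


class TestScreeningTable:
    def test_narrative_outcome(self):
        """Ten compounds x three conformations triage to exactly three
        survivors with the all-conformation blocker first."""
        frame = datasets.screening_table()
        fates = {
            (r.compound_id, r.conformation): FateLabel(r.fate)
            for r in frame.itertuples(index=False)
        }
        records = records_from_frame(frame, fates)
        table = triage_compounds(records)
        assert [r.compound_id for r in table.survivors] == ["NCI617551", "NCI39921", "NCI58783"]
        assert table.survivors[0].n_interface_bound == 3
        reasons = dict((r.compound_id, reason) for r, reason in table.eliminated)
        assert reasons["NCI686480"] == "membrane"
        assert reasons["NCI688806"] == "membrane"
        assert reasons["NCI610512"] == "membrane"
        assert reasons["NCI84171"] == "cavity"
        assert reasons["NCI298806"] == "cavity"
        assert reasons["NCI39918"] == "insufficient_interface"
        assert reasons["NCI23128"] == "insufficient_interface"

    def test_six_membrane_events_among_thirty(self):
        frame = datasets.screening_table()
        assert len(frame) == 30
        assert (frame["fate"] == FateLabel.MEMBRANE_EMBEDDED.value).sum() == 6


class TestFateReport:
    def test_empty_table_renders_header_only(self):
        table = triage_compounds([])
        html = fate_report(table)
        assert "<table>" in html and html.count("<tr>") == 1

    def test_thirty_cells_with_six_red(self):
        frame = datasets.screening_table()
        fates = {
            (r.compound_id, r.conformation): FateLabel(r.fate)
            for r in frame.itertuples(index=False)
        }
        table = triage_compounds(records_from_frame(frame, fates))
        html = fate_report(table)
        n_fate_cells = sum(html.count(f'class="{c}"') for c in ("green", "yellow", "red", "grey"))
        assert n_fate_cells == 30
        assert html.count('class="red"') == 6

    def test_tsv_round_trip(self, tmp_path):
        import pandas as pd

        frame = datasets.screening_table()
        fates = {
            (r.compound_id, r.conformation): FateLabel(r.fate)
            for r in frame.itertuples(index=False)
        }
        table = triage_compounds(records_from_frame(frame, fates))
        path = tmp_path / "triage.tsv"
        table.to_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert len(back) == 10
        assert (back["status"] == "survivor").sum() == 3
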