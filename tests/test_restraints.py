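"""Docking restraint construction, export, dropout, and model validation."""

import numpy as np
import pytest

from lretfit.errors import EmptyResultError
from lretfit.restraints import (
    DistanceRestraint,
    ModelCoordinates,
    RestraintSet,
    bounds_for_target,
    build_restraints,
    cluster_consistency,
    dropout_subset,
    export_restraint_table,
    parse_restraint_table,
    validate_model,
)
from lretfit.states import ProbePair, assign_states


def _conformer(res_a, res_b, closed=None, po=None, open_=None):
    bod = [d for d in (closed, po) if d is not None]
    cy3 = [d for d in (po, open_) if d is not None]
    return assign_states(bod, cy3, ProbePair(res_a, res_b), "ATP")


@pytest.fixture
def atp_conformers():
    return [
        _conformer(51, 51, closed=37.7, po=45.4, open_=78.0),
        _conformer(13, 13, closed=35.4, po=51.0, open_=77.8),
        _conformer(13, 51, closed=36.7, po=51.5, open_=79.7),
        _conformer(774, 51, closed=30.9, po=51.5, open_=80.8),
    ]


class TestBoundsRule:
    @pytest.mark.parametrize(
        "target, expected",
        [(37.7, (5.0, 5.0)), (75.0, (5.0, 5.0)), (75.0001, (7.0, 7.0)),
         (79.7, (7.0, 7.0))],
    )
    def test_width_switch_at_75(self, target, expected):
        # "greater than 75" widens; the boundary itself keeps +/-5
        assert bounds_for_target(target) == expected


class TestBuildRestraints:
    def test_identity_pair_single_restraint_with_narrow_bounds(self, atp_conformers):
        rset = build_restraints(atp_conformers[:1], "closed")
        assert len(rset) == 1
        r = rset.restraints[0]
        assert (r.target, r.minus, r.plus) == (37.7, 5.0, 5.0)
        assert (r.target - r.minus, r.target + r.plus) == (32.7, 42.7)

    def test_mixed_pair_mirrored_with_wide_bounds(self, atp_conformers):
        rset = build_restraints([atp_conformers[2]], "open")
        assert len(rset) == 2
        targets = {(r.residue_a, r.residue_b) for r in rset}
        assert targets == {(13, 51), (51, 13)}
        for r in rset:
            assert (r.minus, r.plus) == (7.0, 7.0)
            assert (round(r.target - r.minus, 3), round(r.target + r.plus, 3)) == (
                72.7, 86.7,
            )

    def test_mirror_symmetry_and_bounds_width_invariants(self, atp_conformers):
        for state in ("closed", "partially_open", "open"):
            rset = build_restraints(atp_conformers, state)
            assert rset.is_mirror_symmetric()
            for r in rset:
                width = r.minus + r.plus
                assert width == (10.0 if r.target <= 75.0 else 14.0)

    def test_partially_open_mean_vs_both_channels(self):
        rec = assign_states([37.7, 45.4], [47.0, 78.0], ProbePair(51, 51), "ATP")
        mean_set = build_restraints([rec], "partially_open")
        both_set = build_restraints([rec], "partially_open",
                                    partially_open_mode="both")
        assert len(mean_set) == 1 and len(both_set) == 2
        assert mean_set.restraints[0].target == pytest.approx((45.4 + 47.0) / 2)
        assert sorted(r.target for r in both_set) == [45.4, 47.0]

    def test_missing_state_skipped_with_warning_or_strict_error(self):
        rec = assign_states([], [50.0, 80.0], ProbePair(66, 66), "ATP")  # generic labels
        with pytest.warns(UserWarning, match="absent"):
            rset = build_restraints([rec], "closed")
        assert len(rset) == 0
        with pytest.raises(EmptyResultError):
            build_restraints([rec], "closed", strict=True)

    def test_restraint_validation(self):
        with pytest.raises(ValueError):
            DistanceRestraint("A", 51, "B", 51, target=40.0, minus=0.0, plus=5.0)


class TestExportParse:
    def test_round_trip_identity(self, atp_conformers):
        rset = build_restraints(atp_conformers, "open")
        text = export_restraint_table(rset)
        assert len(text.strip().splitlines()) == len(rset)
        back = parse_restraint_table(text, state="open")
        original = {(r.selection_key, r.target, r.minus, r.plus) for r in rset}
        parsed = {(r.selection_key, r.target, r.minus, r.plus) for r in back}
        assert parsed == original

    def test_line_count_matches_set_size(self, atp_conformers):
        rset = build_restraints(atp_conformers, "closed")
        # 2 identity pairs + 2 mixed pairs (mirrored) = 6 statements
        assert len(export_restraint_table(rset).strip().splitlines()) == 6

    def test_empty_set_rejected(self):
        with pytest.raises(EmptyResultError):
            export_restraint_table(RestraintSet(restraints=[]))

    def test_unknown_dialect_rejected(self, atp_conformers):
        rset = build_restraints(atp_conformers[:1], "closed")
        with pytest.raises(ValueError, match="dialect"):
            export_restraint_table(rset, dialect="xplor-nih")

    def test_missing_chain_id_rejected(self, atp_conformers):
        with pytest.raises(ValueError, match="chain"):
            build_restraints(atp_conformers[:1], "closed",
                             chain_map={"A": "", "B": "B"})

    def test_air_passthrough_appended_verbatim(self, atp_conformers, tmp_path):
        airs = tmp_path / "airs.tbl"
        airs.write_text("! ambiguous interface restraints\n")
        rset = build_restraints(atp_conformers[:1], "closed")
        text = export_restraint_table(rset, air_passthrough=airs)
        assert text.endswith("! ambiguous interface restraints\n")


class TestDropout:
    def test_dropping_probe_removes_all_its_restraints(self, atp_conformers):
        rset = build_restraints(atp_conformers, "closed")  # pairs 51-51,13-13,13-51,774-51
        reduced = dropout_subset(rset, 51)
        remaining = {(r.residue_a, r.residue_b) for r in reduced}
        assert remaining == {(13, 13)}

    def test_absent_residue_leaves_set_unchanged(self, atp_conformers):
        rset = build_restraints(atp_conformers, "closed")
        with pytest.warns(UserWarning, match="no restraint"):
            same = dropout_subset(rset, 999)
        assert len(same) == len(rset)

    def test_dropping_every_probe_empties_the_set(self, atp_conformers):
        rset = build_restraints(atp_conformers, "closed")
        for residue in (51, 13, 774):
            rset = dropout_subset(rset, residue)
        assert len(rset) == 0


def _model_from_targets(rset):
    """Place each restrained residue pair along x at its exact target."""
    coords = {}
    for i, r in enumerate(rset.sorted()):
        # offset pairs far apart in y so they do not interact
        coords[(r.segment_a, r.residue_a)] = np.array([0.0, 100.0 * i, 0.0])
        coords[(r.segment_b, r.residue_b)] = np.array([r.target, 100.0 * i, 0.0])
    return ModelCoordinates(coords=coords, model_id="true")


class TestValidateModel:
    def test_true_model_fully_satisfied(self, toy_conformers):
        # geometry built from the restraint targets satisfies them all
        from lretfit.restraints import DistanceRestraint

        _, coords = toy_conformers["closed"]
        targets = {(51, 51): 37.7, (13, 13): 35.4, (13, 51): 36.7}
        rset = RestraintSet(restraints=[
            DistanceRestraint("A", a, "B", b, target=t, minus=5, plus=5)
            for (a, b), t in targets.items()
        ])
        report = validate_model(coords, rset, threshold=0.01)
        assert report.n_satisfied == report.n_total == 3
        assert report.max_abs_deviation < 1e-6

    def test_displaced_residue_detected(self):
        rset = RestraintSet(restraints=[
            DistanceRestraint("A", 51, "B", 51, target=40.0, minus=5, plus=5),
            DistanceRestraint("A", 13, "B", 13, target=36.0, minus=5, plus=5),
        ])
        model = _model_from_targets(rset)
        # displace one partner by +8 Å along the pair axis
        model.coords[("B", 13)] = model.coords[("B", 13)] + np.array([8.0, 0, 0])
        report = validate_model(model, rset, threshold=5.0)
        assert report.n_satisfied == 1
        bad = report.table[~report.table["satisfied"]]
        assert bad.iloc[0]["resid_a"] == 13
        assert bad.iloc[0]["deviation"] == pytest.approx(8.0)

    def test_missing_residue_named_in_error(self):
        rset = RestraintSet(restraints=[
            DistanceRestraint("A", 51, "B", 51, target=40.0, minus=5, plus=5),
        ])
        model = ModelCoordinates(coords={("A", 51): np.zeros(3)})
        with pytest.raises(KeyError, match="residue 51"):
            validate_model(model, rset)


class TestClusterConsistency:
    def test_identical_models_have_zero_spread(self):
        coords = {("A", 51): np.zeros(3), ("B", 51): np.array([40.0, 0, 0])}
        models = [ModelCoordinates(coords=dict(coords), model_id=f"c{i}")
                  for i in range(3)]
        table, avg = cluster_consistency(models, [("A", 51, "B", 51)])
        assert avg == 0.0

    def test_known_spread(self):
        models = []
        for i, d in enumerate((40.0, 41.0, 42.0)):
            models.append(ModelCoordinates(
                coords={("A", 51): np.zeros(3), ("B", 51): np.array([d, 0, 0])},
                model_id=f"c{i}",
            ))
        table, avg = cluster_consistency(models, [("A", 51, "B", 51)])
        assert table.iloc[0]["sd"] == pytest.approx(1.0)
        assert avg == pytest.approx(1.0)

    def test_single_cluster_rejected(self):
        m = ModelCoordinates(coords={("A", 51): np.zeros(3)})
        with pytest.raises(ValueError, match="two"):
            cluster_consistency([m], [])


class TestPdbIO:
    def test_pdb_round_trip_preserves_distances(self, toy_conformers, tmp_path):
        from lretfit.synthetic import write_conformer_pdb

        _, coords = toy_conformers["open"]
        path = tmp_path / "open.pdb"
        write_conformer_pdb(coords, path)
        back = ModelCoordinates.from_pdb(path)
        for (chain, res) in coords.coords:
            np.testing.assert_allclose(
                back.position(chain, res), coords.position(chain, res), atol=2e-3
            )
        assert back.distance("A", 51, "B", 51) == pytest.approx(78.0, abs=0.01)
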