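"""The synthetic-data generator: decays, studies, conformers, mixtures."""

import numpy as np
import pytest

from lretfit.decay import channel_distances, fit_decay, read_trace
from lretfit.errors import FeasibilityError
from lretfit.photophysics import DYE_PAIRS
from lretfit.restraints import DistanceRestraint, RestraintSet, validate_model
from lretfit.synthetic import (
    build_toy_conformers,
    load_reference_distances,
    reference_ground_truth,
    simulate_decay,
    simulate_saxs_mixture,
    simulate_study,
    simulate_titration,
)


class TestReferenceTable:
    def test_bundled_table_is_complete_and_ordered(self):
        table = load_reference_distances()
        assert {"NBD", "FL"} == set(table["construct"])
        # closed < partially open < open in every row
        assert (table["closed_mean"] < table["po_bodipy_mean"]).all()
        assert (table["closed_mean"] < table["po_cy3_mean"]).all()
        assert (table[["po_bodipy_mean", "po_cy3_mean"]].max(axis=1)
                < table["open_mean"]).all()

    def test_worked_example_row(self):
        table = load_reference_distances()
        row = table[(table["pair_a"] == 51) & (table["pair_b"] == 51)
                    & (table["construct"] == "NBD")
                    & (table["condition"] == "ATP")].iloc[0]
        assert (row["closed_mean"], row["open_mean"]) == (37.7, 78.0)
        assert (row["po_bodipy_mean"], row["po_cy3_mean"]) == (45.4, 47.0)


class TestSimulateDecay:
    def test_cy3_channel_carries_partially_open_and_open(self, atp_truth):
        # fitted, stripped lifetimes map back to the partially open and
        # open distances; the closed separation is invisible to the
        # long-R0 acceptor (its sensitized lifetime merges with the
        # instrument response)
        trace = simulate_decay(atp_truth, "51-51", "ATP", "cy3")
        fit = fit_decay(trace)
        dists = channel_distances(fit, 2.0, DYE_PAIRS["cy3"])
        assert dists == pytest.approx([47.0, 78.0], abs=1e-3)

    def test_bodipy_channel_carries_closed_and_partially_open(self, atp_truth):
        trace = simulate_decay(atp_truth, "51-51", "ATP", "bodipy")
        fit = fit_decay(trace)
        dists = channel_distances(fit, 2.0, DYE_PAIRS["bodipy"])
        assert dists == pytest.approx([37.7, 45.4], abs=1e-3)

    def test_donor_channel_two_exponential(self, atp_truth):
        trace = simulate_decay(atp_truth, "51-51", "ATP", "donor")
        from lretfit.decay import fit_donor_lifetime

        tau_d, fraction = fit_donor_lifetime(trace)
        assert tau_d == pytest.approx(2.0, rel=1e-6)
        assert fraction == pytest.approx(0.9, rel=1e-4)

    def test_unknown_pair_rejected(self, atp_truth):
        with pytest.raises(KeyError, match="ground truth"):
            simulate_decay(atp_truth, "99-99", "ATP", "cy3")

    def test_zero_duration_rejected(self):
        truth = reference_ground_truth("NBD", ("ATP",), duration=0.1)
        with pytest.raises(ValueError, match="duration"):
            simulate_decay(truth, "51-51", "ATP", "cy3")


class TestSimulateStudy:
    def test_file_counts_and_manifest_consistency(self, tmp_path):
        truth = reference_ground_truth("NBD", ("ATP", "apo"))
        manifest = simulate_study(truth, tmp_path / "study", replicates=3)
        # 5 pairs x 2 conditions x 2 channels x 3 replicates acceptor traces
        acceptor = manifest[manifest["channel"] != "donor"]
        assert len(acceptor) == 5 * 2 * 2 * 3
        # plus donor-only traces per probe residue (3 residues) x replicates
        donor = manifest[manifest["channel"] == "donor"]
        assert len(donor) == 3 * 3
        for fname in manifest["file"]:
            assert (tmp_path / "study" / fname).exists()

    def test_seeded_rerun_is_byte_identical(self, tmp_path):
        truth = reference_ground_truth(
            "NBD", ("ATP",), noise_model="gaussian", seed=42,
        )
        truth.records = truth.records[:1]
        simulate_study(truth, tmp_path / "a", replicates=2)
        simulate_study(truth, tmp_path / "b", replicates=2)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_zero_replicates_rejected(self, tmp_path, atp_truth):
        with pytest.raises(ValueError, match="replicate"):
            simulate_study(atp_truth, tmp_path, replicates=0)

    def test_noisy_traces_round_trip_within_two_sd(self, tmp_path):
        # noisy decays: recovered per-state distances agree with truth
        # within 2 SD of the replicate spread
        from lretfit.pipeline import fit_study

        truth = reference_ground_truth(
            "NBD", ("ATP",), noise_model="gaussian", noise_scale=0.005, seed=3,
        )
        truth.records = [r for r in truth.records if r.pair.label == "51-51"]
        manifest = simulate_study(truth, tmp_path / "noisy", replicates=3)
        table, _ = fit_study(tmp_path / "noisy", manifest)
        row = table.iloc[0]
        rec = truth.records[0]
        for col, true_val in (
            ("closed", rec.closed), ("partially_open_bodipy", rec.partially_open_bodipy),
            ("partially_open_cy3", rec.partially_open_cy3), ("open", rec.open_),
        ):
            sd = max(row[f"{col}_sd"], 0.05)
            assert abs(row[f"{col}_mean"] - true_val) <= 2.0 * sd + 0.1


class TestToyConformers:
    def test_probe_distances_match_targets(self, toy_conformers, toy_state_targets):
        for state, targets in toy_state_targets.items():
            _, coords = toy_conformers[state]
            for (ra, rb), target in targets.items():
                assert coords.distance("A", ra, "B", rb) == pytest.approx(
                    target, abs=1e-6
                )

    def test_true_model_satisfies_own_restraints(self, toy_conformers,
                                                 toy_state_targets):
        for state, targets in toy_state_targets.items():
            _, coords = toy_conformers[state]
            rset = RestraintSet(restraints=[
                DistanceRestraint("A", a, "B", b, target=t, minus=5, plus=5)
                for (a, b), t in targets.items()
            ])
            report = validate_model(coords, rset, threshold=0.001)
            assert report.fraction_satisfied == 1.0

    def test_contrasting_state_violates_restraints(self, toy_conformers,
                                                   toy_state_targets):
        # the open model against closed-state restraints: every Cβ–Cβ
        # separation is ~40 Å too long
        _, open_coords = toy_conformers["open"]
        closed_targets = toy_state_targets["closed"]
        rset = RestraintSet(restraints=[
            DistanceRestraint("A", a, "B", b, target=t, minus=5, plus=5)
            for (a, b), t in closed_targets.items()
        ])
        report = validate_model(open_coords, rset, threshold=5.0)
        assert report.fraction_satisfied == 0.0

    def test_c2_symmetry_of_mirrored_pairs(self, toy_conformers):
        _, coords = toy_conformers["closed"]
        assert coords.distance("A", 13, "B", 51) == pytest.approx(
            coords.distance("A", 51, "B", 13), abs=1e-9
        )

    def test_infeasible_targets_raise_feasibility_error(self):
        # under C2 symmetry a cross distance d(1,2) can never be shorter
        # than half the gap between the identity distances:
        # d(1,2) >= |d(1,1) - d(2,2)| / 2, so (100, 10, 20) is impossible
        bad = {"s": {(1, 1): 100.0, (2, 2): 10.0, (1, 2): 20.0}}
        with pytest.raises(FeasibilityError, match="triangle"):
            build_toy_conformers(bad)


class TestSaxsMixtures:
    def test_pure_state_equals_single_profile(self, toy_conformers):
        from lretfit.saxs import debye_profile

        models = [bm for bm, _ in toy_conformers.values()]
        mix = simulate_saxs_mixture(models, [1.0, 0.0, 0.0])
        single = debye_profile(models[0], mix.q)
        np.testing.assert_allclose(mix.intensity, single.intensity, rtol=1e-12)

    def test_off_simplex_weights_rejected(self, toy_conformers):
        models = [bm for bm, _ in toy_conformers.values()]
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_saxs_mixture(models, [0.5, 0.2, 0.2])
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_saxs_mixture(models, [-0.1, 0.6, 0.5])

    def test_noise_is_seeded(self, toy_conformers):
        models = [bm for bm, _ in toy_conformers.values()]
        a = simulate_saxs_mixture(models, [0.5, 0.3, 0.2], noise_level=0.02, seed=5)
        b = simulate_saxs_mixture(models, [0.5, 0.3, 0.2], noise_level=0.02, seed=5)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestSimulateTitration:
    def test_half_max_at_km(self):
        concs = np.array([5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 300.0])
        series = simulate_titration(100.0, 50.0, 1.0, concs)
        assert series.rates[concs == 50.0][0] == pytest.approx(50.0, rel=1e-12)

    def test_noiseless_refit_recovers_exactly(self):
        from lretfit.enzymology import fit_hill_kinetics

        series = simulate_titration(100.0, 50.0, 2.0, np.linspace(5, 300, 8))
        fit = fit_hill_kinetics(series)
        assert (fit.vmax, fit.km, fit.n) == pytest.approx(
            (100.0, 50.0, 2.0), rel=1e-4
        )

    def test_empty_concentrations_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_titration(100.0, 50.0, 1.0, [])


class TestFullCircle:
    def test_noiseless_study_reproduces_truth(self, tmp_path):
        # generate -> fit -> assign -> tabulate over two pairs and two
        # conditions; every populated state within 0.5 Å of the ground truth
        from lretfit.pipeline import fit_study

        truth = reference_ground_truth("NBD", ("ATP", "apo"))
        keep = {"51-51", "13-51"}
        truth.records = [r for r in truth.records if r.pair.label in keep]
        manifest = simulate_study(truth, tmp_path / "fc", replicates=1)
        table, _ = fit_study(tmp_path / "fc", manifest)
        for rec in truth.records:
            row = table[(table["pair"] == rec.pair.label)
                        & (table["condition"] == rec.condition)].iloc[0]
            assert row["closed_mean"] == pytest.approx(rec.closed, abs=0.5)
            assert row["partially_open_bodipy_mean"] == pytest.approx(
                rec.partially_open_bodipy, abs=0.5)
            assert row["partially_open_cy3_mean"] == pytest.approx(
                rec.partially_open_cy3, abs=0.5)
            assert row["open_mean"] == pytest.approx(rec.open_, abs=0.5)
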