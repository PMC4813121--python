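import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from weevilmove import (
    ReconstructionError,
    StudyDesign,
    build_occupancy,
    dedup_events,
    infer_crossings,
    read_events,
    simulate_experiment,
    write_events,
)
from weevilmove.trajectory_reconstruction import sort_events

from conftest import make_events, make_roster


class TestIO:
    def test_write_read_round_trip(self, tmp_path, small_sim):
        write_events(small_sim.events, tmp_path / "detections.csv")
        small_sim.roster.to_csv(tmp_path / "individuals.csv", index=False)
        ev, ros = read_events(tmp_path / "detections.csv",
                              tmp_path / "individuals.csv")
        assert ev.equals(sort_events(small_sim.events))
        assert len(ros) == len(small_sim.roster)

    def test_empty_event_file_is_valid(self, tmp_path):
        make_events([]).to_csv(tmp_path / "d.csv", index=False)
        make_roster([("w1", "F", 1)]).to_csv(tmp_path / "i.csv", index=False)
        ev, _ = read_events(tmp_path / "d.csv", tmp_path / "i.csv")
        assert ev.empty

    def test_unknown_tag_is_named(self, tmp_path):
        make_events([("ghost", "A1", 5)]).to_csv(tmp_path / "d.csv",
                                                 index=False)
        make_roster([("w1", "F", 1)]).to_csv(tmp_path / "i.csv", index=False)
        with pytest.raises(ValueError, match="ghost"):
            read_events(tmp_path / "d.csv", tmp_path / "i.csv")

    def test_malformed_row_reports_line(self, tmp_path):
        df = make_events([("w1", "A1", 5), ("w1", "A9", 6)])
        df.to_csv(tmp_path / "d.csv", index=False)
        make_roster([("w1", "F", 1)]).to_csv(tmp_path / "i.csv", index=False)
        with pytest.raises(ValueError, match="line 3"):
            read_events(tmp_path / "d.csv", tmp_path / "i.csv")

    def test_unsorted_input_sorted_content_identical(self, tmp_path):
        rows = [("w1", "A1", 500), ("w2", "A2", 10), ("w1", "A2", 700)]
        make_events(rows).to_csv(tmp_path / "d.csv", index=False)
        make_roster([("w1", "F", 1), ("w2", "M", 1)]).to_csv(
            tmp_path / "i.csv", index=False)
        ev, _ = read_events(tmp_path / "d.csv", tmp_path / "i.csv")
        assert list(ev["timestamp_s"]) == [10, 500, 700]
        assert set(map(tuple, ev.values)) == set(
            ("r0", t, a, s) for t, a, s in rows)


class TestDedup:
    @pytest.mark.parametrize("rows,kept", [
        ([("w1", "A1", 100), ("w1", "A1", 130)], [100]),
        ([("w1", "A1", 100), ("w1", "A2", 130)], [100, 130]),
        ([("w1", "A1", 0), ("w1", "A1", 59), ("w1", "A1", 118)], [0, 118]),
    ])
    def test_dead_time_examples(self, rows, kept):
        out = dedup_events(sort_events(make_events(rows)))
        assert list(out["timestamp_s"]) == kept

    @given(times=st.lists(st.integers(0, 2000), min_size=0, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_dedup_idempotent_and_spaced(self, times):
        ev = sort_events(make_events([("w1", "A1", t) for t in sorted(times)]))
        once = dedup_events(ev)
        assert once.equals(dedup_events(once))
        gaps = np.diff(once["timestamp_s"].to_numpy())
        assert (gaps >= 60).all()
        # linear-scan oracle
        kept, last = [], None
        for t in sorted(times):
            if last is None or t - last >= 60:
                kept.append(t)
                last = t
        assert list(once["timestamp_s"]) == kept


class TestCrossings:
    ROSTER = [("w1", "F", 1)]

    def test_simple_crossing(self):
        cr = infer_crossings(make_events([("w1", "A1", 100), ("w1", "A2", 420)]),
                             make_roster(self.ROSTER))
        assert len(cr) == 1
        row = cr.iloc[0]
        assert row.direction == "1->2" and row.duration_s == 320

    def test_same_antenna_pair_is_aborted_entry(self):
        cr = infer_crossings(make_events([("w1", "A1", 100), ("w1", "A1", 500)]),
                             make_roster(self.ROSTER))
        assert cr.empty

    def test_trailing_unpaired_read_is_not_a_crossing(self):
        cr = infer_crossings(
            make_events([("w1", "A1", 100), ("w1", "A2", 420),
                         ("w1", "A2", 900)]),
            make_roster(self.ROSTER))
        assert len(cr) == 1

    def test_inconsistent_read_strict_raises(self):
        ev = make_events([("w1", "A2", 100), ("w1", "A1", 300)])
        with pytest.raises(ReconstructionError, match="w1"):
            infer_crossings(ev, make_roster(self.ROSTER), strict=True)

    def test_inconsistent_read_lenient_resyncs(self, caplog):
        ev = make_events([("w1", "A2", 100), ("w1", "A1", 300)])
        cr = infer_crossings(ev, make_roster(self.ROSTER), strict=False)
        assert len(cr) == 1 and cr.iloc[0].direction == "2->1"

    def test_round_trip_matches_truth(self, small_chain):
        got = small_chain["crossings"].sort_values(
            ["replicate_id", "start_s", "tag_id"]).reset_index(drop=True)
        want = small_chain["sim"].truth.sort_values(
            ["replicate_id", "start_s", "tag_id"]).reset_index(drop=True)
        assert got.equals(want[got.columns.tolist()])

    def test_round_trip_tolerates_aborted_entries(self, coeffs):
        sim = simulate_experiment(StudyDesign(treatments=((10, 3),)), coeffs,
                                  seed=13, abort_rate=0.3)
        cr = infer_crossings(dedup_events(sim.events), sim.roster)
        got = cr.sort_values(["replicate_id", "start_s"]).reset_index(drop=True)
        want = sim.truth.sort_values(
            ["replicate_id", "start_s"]).reset_index(drop=True)
        assert got.equals(want[got.columns.tolist()])


class TestOccupancy:
    def test_no_crossings_static_occupancy(self):
        roster = make_roster([("w1", "M", 1), ("w2", "M", 1), ("w3", "F", 1)])
        empty = pd.DataFrame(columns=["replicate_id", "tag_id", "direction",
                                      "start_s", "end_s", "duration_s"])
        occ = build_occupancy(empty, roster)["r0"]
        for t in (0, 1000, 43199):
            assert occ.density[1](t) == 3 and occ.density[2](t) == 0
        assert occ.sex_ratio[1](0) == pytest.approx(2 / 3)
        assert occ.sex_ratio[2](0) == 0.5  # empty-patch convention

    def test_single_crossing_switches_counts_at_completion(self):
        roster = make_roster([("w1", "M", 1), ("w2", "F", 1)])
        cr = pd.DataFrame(
            [("r0", "w1", "1->2", 100, 400, 300)],
            columns=["replicate_id", "tag_id", "direction", "start_s",
                     "end_s", "duration_s"])
        occ = build_occupancy(cr, roster)["r0"]
        assert occ.density[1](399) == 2 and occ.density[2](399) == 0
        assert occ.density[1](400) == 1 and occ.density[2](400) == 1
        assert occ.sex_ratio[2](400) == 1.0  # all-male patch
        assert occ.sex_ratio[1](400) == 0.0  # all-female patch
        assert occ.agent_patch("w1", 399) == 1
        assert occ.agent_patch("w1", 400) == 2

    def test_conservation_at_all_times(self, small_chain):
        rng = np.random.default_rng(0)
        for occ in small_chain["occupancy"].values():
            t = rng.integers(0, occ.night_s, 50)
            total = occ.density[1](t) + occ.density[2](t) + occ.corridor(t)
            assert (total == occ.n_agents).all()

    def test_overlapping_crossings_rejected(self):
        roster = make_roster([("w1", "M", 1)])
        cr = pd.DataFrame(
            [("r0", "w1", "1->2", 100, 400, 300),
             ("r0", "w1", "2->1", 200, 600, 400)],
            columns=["replicate_id", "tag_id", "direction", "start_s",
                     "end_s", "duration_s"])
        with pytest.raises(ReconstructionError, match="mid-corridor"):
            build_occupancy(cr, roster)

    def test_inconsistent_direction_rejected(self):
        roster = make_roster([("w1", "M", 1)])
        cr = pd.DataFrame(
            [("r0", "w1", "2->1", 100, 400, 300)],
            columns=["replicate_id", "tag_id", "direction", "start_s",
                     "end_s", "duration_s"])
        with pytest.raises(ReconstructionError, match="inconsistent"):
            build_occupancy(cr, roster)

    def test_step_function_mean_matches_fine_grid(self, small_chain):
        occ = next(iter(small_chain["occupancy"].values()))
        sf = occ.density[1]
        grid = np.arange(0, occ.night_s, 10.0)
        for a, b in [(0.0, 1800.0), (3600.0, 7200.0), (100.0, 43000.0)]:
            sel = (grid >= a) & (grid < b)
            assert sf.mean(a, b) == pytest.approx(sf(grid[sel]).mean(),
                                                  rel=1e-3)
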