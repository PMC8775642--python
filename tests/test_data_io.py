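"""Domain types, CSV round trips, and dataset partitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fatiguekit import (
    Condition,
    FatigueTrial,
    RecoverySeries,
    assign_rw_group,
    read_recovery,
    read_trials,
    split_ab,
    write_recovery,
    write_trials,
)
from fatiguekit.data import DEFAULT_RW_BINS
from fatiguekit.errors import DomainError, PartitionError, RecordError, SchemaError
from fatiguekit.simulate import GeneratorParams, generate_dataset

from conftest import exact_recovery_series, make_trial


class TestDomainTypes:
    def test_condition_default_tool_weights(self):
        assert Condition(20.0, "small").tool_weight == 1.5
        assert Condition(40.0, "large").tool_weight == 5.6

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(ms0=120.0, mvc=100.0),  # stronger after exhaustion than baseline
            dict(push_force=150.0, mvc=100.0),  # f_MVC > 1
            dict(met=-1.0),
            dict(cr10_0=11.0),
        ],
    )
    def test_trial_invariants_rejected(self, kwargs):
        with pytest.raises(RecordError):
            make_trial(**kwargs)

    def test_recovery_series_must_anchor_at_ms0(self):
        trial = make_trial(ms0=58.0)
        with pytest.raises(RecordError, match="ms0"):
            RecoverySeries(trial, times=[0, 1], ms=[60.0, 70.0], cr10=[8, 7])

    def test_recovery_series_times_start_at_zero_and_increase(self):
        trial = make_trial(ms0=58.0)
        with pytest.raises(RecordError):
            RecoverySeries(trial, times=[1, 2], ms=[58.0, 70.0], cr10=[8, 7])
        with pytest.raises(RecordError):
            RecoverySeries(trial, times=[0, 2, 1], ms=[58.0, 70, 65], cr10=[8, 7, 6])


class TestSplitAB:
    def test_four_combinations_split_two_and_two(self, four_condition_trials):
        group_a, group_b = split_ab(four_condition_trials)
        assert {(t.condition.push_force, t.condition.tool_label) for t in group_a} == {
            (20.0, "small"),
            (40.0, "large"),
        }
        assert {(t.condition.push_force, t.condition.tool_label) for t in group_b} == {
            (20.0, "large"),
            (40.0, "small"),
        }

    def test_single_condition_leaves_other_group_empty(self):
        trials = [make_trial() for _ in range(5)]
        group_a, group_b = split_ab(trials)
        assert len(group_a) == 5 and group_b == []

    def test_unknown_condition_raises(self):
        with pytest.raises(PartitionError):
            split_ab([make_trial(push_force=30.0)])

    def test_override_map(self):
        trials = [make_trial(push_force=30.0)]
        a, b = split_ab(trials, membership={(30.0, "small"): "B"})
        assert a == [] and len(b) == 1

    def test_split_is_a_partition_on_synthetic_data(self, default_dataset):
        a, b = split_ab(default_dataset.trials)
        assert len(a) + len(b) == len(default_dataset.trials)
        assert {id(t) for t in a}.isdisjoint({id(t) for t in b})


class TestRwGroups:
    @pytest.mark.parametrize(
        "tool_weight,body_mass,label",
        [(5.6, 68.17, "H"), (1.5, 68.17, "L"), (4.0, 68.17, "N")],
    )
    def test_bin_assignment(self, tool_weight, body_mass, label):
        group = assign_rw_group(tool_weight, body_mass)
        assert group.label == label
        assert not group.in_gap
        assert group.rw == pytest.approx(100 * tool_weight / body_mass)

    def test_gap_value_maps_to_nearest_bin_with_flag(self):
        # the 4.7-4.8 gap between the rounded L and N bins: values map to the
        # nearest bin, with the exact midpoint tie going to the lower bin
        midpoint = assign_rw_group(4.75, 100.0)
        assert midpoint.in_gap and midpoint.label == "L"
        group = assign_rw_group(4.76, 100.0)
        assert group.in_gap and group.label == "N"

    def test_below_all_bins_flags_and_uses_nearest(self):
        group = assign_rw_group(1.0, 100.0)
        assert group.in_gap and group.label == "L"

    def test_nonpositive_mass_raises(self):
        with pytest.raises(DomainError):
            assign_rw_group(5.6, 0.0)
        with pytest.raises(DomainError):
            assign_rw_group(-1.0, 70.0)

    @given(
        w1=st.floats(0.5, 12.0),
        w2=st.floats(0.5, 12.0),
        mass=st.floats(45.0, 120.0),
    )
    def test_heavier_tool_never_moves_to_lighter_group(self, w1, w2, mass):
        order = {"L": 0, "N": 1, "H": 2}
        lo, hi = sorted((w1, w2))
        g_lo = assign_rw_group(lo, mass)
        g_hi = assign_rw_group(hi, mass)
        assert order[g_lo.label] <= order[g_hi.label]


trial_strategy = st.builds(
    lambda pid, force, tool, mvc_extra, met, ms0f, cr10: make_trial(
        participant_id=pid,
        push_force=force,
        tool=tool,
        mvc=force + mvc_extra,
        met=met,
        ms0=(force + mvc_extra) * ms0f,
        cr10_0=cr10,
    ),
    pid=st.sampled_from(["P01", "P02", "P03"]),
    force=st.sampled_from([20.0, 40.0]),
    tool=st.sampled_from(["small", "large"]),
    mvc_extra=st.floats(1.0, 150.0, allow_nan=False),
    met=st.floats(0.1, 60.0, allow_nan=False),
    ms0f=st.floats(0.2, 0.95),
    cr10=st.floats(0.0, 10.0),
)


class TestCsvRoundTrip:
    @given(trials=st.lists(trial_strategy, min_size=0, max_size=6))
    def test_trials_write_read_identity(self, trials, tmp_path_factory):
        path = tmp_path_factory.mktemp("csv") / "trials.csv"
        write_trials(trials, path)
        back = read_trials(path)
        assert len(back) == len(trials)
        for orig, rt in zip(trials, back):
            assert rt.participant_id == orig.participant_id
            assert rt.condition == orig.condition
            assert rt.mvc == orig.mvc  # exact: shortest-repr float round trip
            assert rt.met == orig.met
            assert rt.ms0 == orig.ms0
            assert rt.cr10_0 == orig.cr10_0

    def test_empty_trial_list_writes_header_only(self, tmp_path):
        path = tmp_path / "trials.csv"
        write_trials([], path)
        assert path.read_text().strip() == (
            "participant_id,push_force_N,tool,tool_weight_kg,mvc_N,met_min,ms0_N,cr10_0"
        )
        assert read_trials(path) == []

    def test_full_study_recovery_row_count(self, tmp_path):
        # 17 participants x 4 conditions x 7 time points -> 476 long rows
        dataset = generate_dataset(GeneratorParams(n_participants=17, seed=3))
        path = tmp_path / "recovery.csv"
        write_recovery(dataset.recovery, path)
        assert len(pd.read_csv(path)) == 17 * 4 * 7 == 476

    def test_recovery_write_read_identity(self, tmp_path):
        trial = make_trial()
        series = [exact_recovery_series(trial, rr=0.132)]
        rec_path = tmp_path / "recovery.csv"
        write_recovery(series, rec_path)
        back = read_recovery(rec_path, [trial])
        assert len(back) == 1
        np.testing.assert_array_equal(back[0].times, series[0].times)
        np.testing.assert_array_equal(back[0].ms, series[0].ms)
        np.testing.assert_array_equal(back[0].cr10, series[0].cr10)


class TestReadErrors:
    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant_id,push_force_N\nP01,20\n")
        with pytest.raises(SchemaError, match="mvc_N"):
            read_trials(path)

    def test_invariant_violation_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_trials([make_trial()], path)
        df = pd.read_csv(path)
        df.loc[0, "ms0_N"] = 120.0  # exceeds mvc 100
        df.to_csv(path, index=False)
        with pytest.raises(RecordError, match="row 0"):
            read_trials(path)

    def test_non_numeric_cell_is_a_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_trials([make_trial()], path)
        text = path.read_text().replace("100.0", "not-a-number", 1)
        path.write_text(text)
        with pytest.raises(SchemaError, match="not-a-number"):
            read_trials(path)
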