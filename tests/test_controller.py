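"""Switching controller: patience, ranking, pruning, and full runs
against an independent hand-simulation oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afcs.controller import (
    AFCSConfig,
    ControllerState,
    RankingError,
    patience_step,
    prune_worst,
    rank_activations,
    run_afcs,
)
from afcs.runtime import extra_epochs
from afcs.synthetic import ScriptedLossTable, scripted_trainer

from oracle import hand_simulate


def fresh_state(**kwargs) -> ControllerState:
    defaults = dict(active_af="A", remaining_afs=["A", "B", "C"])
    defaults.update(kwargs)
    return ControllerState(**defaults)


def feed(state, losses, p, mode="consecutive_increases"):
    """Feed a loss stream; return the 1-based index of the trigger, or None."""
    for i, loss in enumerate(losses, start=1):
        state.epoch = i
        if patience_step(state, loss, p, mode=mode):
            return i
    return None


class TestPatienceStep:
    def test_three_consecutive_increases_trigger(self):
        assert feed(fresh_state(), [1.0, 0.9, 0.95, 0.97, 0.99], p=3) == 5

    def test_counter_resets_on_decrease(self):
        # two increases, a reset, then three more: trigger on the 7th value
        assert feed(fresh_state(), [1.0, 1.1, 1.2, 0.8, 0.9, 1.0, 1.1], p=3) == 7

    def test_strictly_decreasing_never_triggers(self):
        assert feed(fresh_state(), np.linspace(5, 1, 50), p=2) is None

    def test_plateau_is_not_an_increase_in_default_mode(self):
        assert feed(fresh_state(), [1.0, 1.0, 1.0, 1.0], p=2) is None

    def test_plateau_triggers_in_no_best_improvement_mode(self):
        assert feed(fresh_state(), [1.0, 1.0, 1.0], p=2, mode="no_best_improvement") == 3

    def test_nan_counts_as_degradation_and_never_best(self):
        state = fresh_state()
        nan = float("nan")
        assert feed(state, [1.0, nan, nan], p=2) == 3
        assert state.best_loss == 1.0

    def test_best_checkpoint_tracks_minimum(self):
        state = fresh_state()
        for epoch, (loss, token) in enumerate(
            [(1.0, "t1"), (0.7, "t2"), (0.9, "t3")], start=1
        ):
            state.epoch = epoch
            patience_step(state, loss, p=5, checkpoint=token)
        assert (state.best_loss, state.best_checkpoint, state.best_epoch) == (0.7, "t2", 2)


class TestRankActivations:
    def test_ascending_by_probe_loss(self):
        trainer = scripted_trainer({"ReLU": [0.5], "ELU": [0.7], "SELU": [0.9]})
        ranking = rank_activations(trainer, ["ReLU", "ELU", "SELU"])
        assert ranking.order == ("ReLU", "ELU", "SELU")
        assert ranking.best == "ReLU" and ranking.worst == "SELU"

    def test_ties_broken_by_candidate_order(self):
        trainer = scripted_trainer({"Mish": [0.8], "ELU": [0.7], "SELU": [0.7]})
        ranking = rank_activations(trainer, ["Mish", "ELU", "SELU"])
        assert ranking.order == ("ELU", "SELU", "Mish")

    def test_reference_state_restored_after_probing(self):
        trainer = scripted_trainer({"A": [0.5, 0.4], "B": [0.6]}, hold_last=True)
        epoch_before = trainer.current_epoch
        rank_activations(trainer, ["A", "B"])
        assert trainer.current_epoch == epoch_before
        # next training epoch consumes position 0 again
        trainer.set_activation("A")
        assert trainer.train_one_epoch() == 0.5

    def test_non_finite_probe_ranks_last_and_is_flagged(self):
        trainer = scripted_trainer({"A": [float("nan")], "B": [0.6], "C": [0.5]})
        ranking = rank_activations(trainer, ["A", "B", "C"])
        assert ranking.order == ("C", "B", "A")
        assert ranking.flagged == ("A",)

    def test_all_non_finite_raises(self):
        trainer = scripted_trainer({"A": [float("nan")], "B": [float("inf")]})
        with pytest.raises(RankingError):
            rank_activations(trainer, ["A", "B"])


class TestPruneWorst:
    def test_removes_above_floor(self):
        assert prune_worst(["ReLU", "ELU", "SELU", "Mish"], "ELU", 3) == [
            "ReLU", "SELU", "Mish",
        ]

    def test_blocked_at_floor_in_loop_phase(self):
        remaining = ["ReLU", "SELU", "Mish"]
        assert prune_worst(remaining, "Mish", 3, phase="loop") == remaining

    def test_initial_phase_removal_is_unconditional(self):
        names = ["Tanh", "ReLU", "ELU", "SELU", "Mish", "SiLU", "GELU"]
        survivors = prune_worst(names, "Tanh", 6, phase="initial")
        assert survivors == ["ReLU", "ELU", "SELU", "Mish", "SiLU", "GELU"]

    def test_missing_worst_is_a_contract_error(self):
        with pytest.raises(ValueError):
            prune_worst(["A", "B"], "C", 2)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        cfg = AFCSConfig()
        assert cfg.p0 == 3 and cfg.p1 == 2 and cfg.afcs_loop == 5
        assert cfg.min_af_count == 3 and len(cfg.list_af) == 6

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(list_af=("A", "B")),
            dict(afcs_loop=1),
            dict(min_af_count=1),
            dict(min_af_count=6),  # > len(list_af) - 1
            dict(p0=0),
            dict(patience_mode="psychic"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AFCSConfig(**kwargs)

    def test_patience_below_two_warns_but_is_accepted(self):
        with pytest.warns(UserWarning):
            cfg = AFCSConfig(p1=1)
        assert cfg.p1 == 1

    def test_round_trip_through_dict_with_field_aliases(self):
        cfg = AFCSConfig(p0=4, afcs_loop=3)
        again = AFCSConfig.from_dict(cfg.as_dict())
        assert again == cfg


def immediate_worsening_table(n_afs=6):
    """Each column: one good first epoch, then strictly increasing losses."""
    names = [chr(ord("A") + i) for i in range(n_afs)]
    cols = {
        af: [0.5 + 0.01 * i] + [1.0 + 0.1 * k + 0.01 * i for k in range(30)]
        for i, af in enumerate(names)
    }
    return names, ScriptedLossTable(columns=cols, hold_last=True)


GOLDEN_TABLES = {
    "immediate_worsening": (
        immediate_worsening_table()[1],
        dict(
            list_af=("A", "B", "C", "D", "E", "F"),
            p0=3, p1=2, afcs_loop=5, min_af_count=3,
        ),
    ),
    "recovery_and_reset": (
        ScriptedLossTable(
            columns={
                "A": [0.9, 0.8, 0.85, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95],
                "B": [0.95, 0.6, 0.65, 0.7, 0.5, 0.6, 0.7, 0.8],
                "C": [1.1, 1.0, 0.9, 0.95, 1.0, 1.05],
                "D": [1.2, 1.1, 1.15, 1.2, 1.25],
            },
            hold_last=True,
        ),
        dict(list_af=("A", "B", "C", "D"), p0=3, p1=2, afcs_loop=3, min_af_count=2),
    ),
    "floor_blocks_pruning": (
        ScriptedLossTable(
            columns={
                "A": [0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2],
                "B": [0.55, 0.55, 0.6, 0.7, 0.8, 0.9],
                "C": [0.6, 0.52, 0.61, 0.7, 0.8, 0.9],
                "D": [0.7, 0.8, 0.9, 1.0],
            },
            hold_last=True,
        ),
        dict(list_af=("A", "B", "C", "D"), p0=2, p1=2, afcs_loop=4, min_af_count=3),
    ),
    "late_improvement": (
        ScriptedLossTable(
            columns={
                "A": [1.0, 0.9, 0.8, 0.82, 0.84, 0.86, 0.5, 0.6, 0.7, 0.8],
                "B": [0.95, 0.85, 0.9, 0.95, 1.0, 1.05],
                "C": [1.05, 0.75, 0.8, 0.85, 0.9],
                "D": [1.3, 1.2, 1.25, 1.3, 1.35],
                "E": [1.4, 1.3, 1.35, 1.4, 1.45],
            },
            hold_last=True,
        ),
        dict(list_af=("A", "B", "C", "D", "E"), p0=3, p1=2, afcs_loop=4, min_af_count=2),
    ),
    "uniform_patience": (
        immediate_worsening_table(5)[1],
        dict(
            list_af=("A", "B", "C", "D", "E"), p0=2, p1=2, afcs_loop=6, min_af_count=2
        ),
    ),
}


@pytest.mark.parametrize("name", sorted(GOLDEN_TABLES))
def test_run_matches_hand_simulation(name):
    """Schedule, loss trace and switch epochs equal an independent
    step-by-step simulation of the procedure on the same table."""
    table, cfg_kwargs = GOLDEN_TABLES[name]
    cfg = AFCSConfig(seed=0, **cfg_kwargs)
    result = run_afcs(scripted_trainer(table), cfg, epoch_cap=500)
    expected_schedule, expected_trace = hand_simulate(
        {af: table.columns[af] for af in cfg.list_af},
        cfg.p0, cfg.p1, cfg.afcs_loop, cfg.min_af_count,
    )
    assert not result.truncated
    assert [(r.step, r.epoch, r.af) for r in result.schedule] == expected_schedule
    assert [(r.epoch, r.af, r.val_loss) for r in result.trace] == expected_trace


def test_hand_frozen_immediate_worsening_run():
    """Fully hand-worked expectation for the immediate-worsening table:
    A wins the probe (0.50), F is dropped; each later cycle rolls back to
    A's epoch-1 best, B wins every re-probe (0.51 beats A's exhausted
    column), and A then E are pruned until the floor holds at {B, C, D}."""
    table, cfg_kwargs = GOLDEN_TABLES["immediate_worsening"]
    result = run_afcs(scripted_trainer(table), AFCSConfig(seed=0, **cfg_kwargs), 500)
    assert [(r.step, r.epoch, r.af) for r in result.schedule] == [
        (1, 1, "A"), (2, 1, "B"), (3, 1, "B"), (4, 1, "B"), (5, 1, "B"),
    ]
    assert result.final_state.remaining_afs == ["B", "C", "D"]
    assert result.post_best_epochs == extra_epochs(3, 2, 5) == 11


def test_dominant_candidate_is_always_reselected():
    """With one activation scripted far below the rest, every re-probe
    switches back to it (plateau mode so the patience can trigger)."""
    cols = {"A": [0.1] * 40, "B": [0.5] * 40, "C": [0.6] * 40}
    cfg = AFCSConfig(
        list_af=("A", "B", "C"), p0=2, p1=2, afcs_loop=4, min_af_count=2,
        patience_mode="no_best_improvement", seed=0,
    )
    result = run_afcs(scripted_trainer(ScriptedLossTable(columns=cols)), cfg, 500)
    assert [r.af for r in result.schedule] == ["A", "A", "A", "A"]
    assert not result.truncated


def test_min_af_count_at_len_minus_one_means_single_removal():
    names, table = immediate_worsening_table(4)
    cfg = AFCSConfig(
        list_af=tuple(names), p0=2, p1=2, afcs_loop=3, min_af_count=len(names) - 1,
        seed=0,
    )
    result = run_afcs(scripted_trainer(table), cfg, 500)
    assert len(result.final_state.remaining_afs) == len(names) - 1


def test_epoch_cap_truncates_with_flag():
    cols = {af: np.linspace(2.0, 0.1, 50).tolist() for af in ("A", "B", "C")}
    cfg = AFCSConfig(list_af=("A", "B", "C"), p0=3, p1=2, afcs_loop=3,
                     min_af_count=2, seed=0)
    result = run_afcs(
        scripted_trainer(ScriptedLossTable(columns=cols, hold_last=True)), cfg, epoch_cap=20
    )
    assert result.truncated
    assert not result.schedule.complete
    assert len(result.trace) == 20


def random_table(rng, n_afs, length=25):
    names = [chr(ord("A") + i) for i in range(n_afs)]
    return {
        af: np.round(rng.uniform(0.3, 2.0, size=length), 3).tolist() for af in names
    }


@pytest.mark.parametrize("seed", range(12))
def test_randomized_tables_match_oracle_and_invariants(seed):
    rng = np.random.default_rng(seed)
    n_afs = int(rng.integers(3, 7))
    cols = random_table(rng, n_afs)
    loop = int(rng.integers(2, 5))
    min_count = int(rng.integers(2, n_afs))
    cfg = AFCSConfig(
        list_af=tuple(cols), p0=2, p1=2, afcs_loop=loop, min_af_count=min_count,
        seed=seed,
    )
    table = ScriptedLossTable(columns=cols, hold_last=True)
    result = run_afcs(scripted_trainer(table), cfg, epoch_cap=400)
    expected_schedule, expected_trace = hand_simulate(
        table.columns, 2, 2, loop, min_count, epoch_cap=400
    )
    assert [(r.step, r.epoch, r.af) for r in result.schedule] == expected_schedule[: len(result.schedule)]
    assert [(r.epoch, r.af, r.val_loss) for r in result.trace] == expected_trace
    if not result.truncated:
        # completed-run invariants
        assert len(result.schedule) == loop
        assert result.schedule[0].epoch == 1
        epochs = [r.epoch for r in result.schedule]
        assert epochs == sorted(epochs)
    assert len(result.final_state.remaining_afs) >= min_count
    for record in result.schedule:
        assert record.af in cfg.list_af


def test_rerun_is_bit_reproducible():
    table, cfg_kwargs = GOLDEN_TABLES["recovery_and_reset"]
    cfg = AFCSConfig(seed=4, **cfg_kwargs)
    a = run_afcs(scripted_trainer(table), cfg, 500)
    b = run_afcs(scripted_trainer(table), cfg, 500)
    assert a.schedule == b.schedule
    assert a.trace == b.trace
    assert a.events == b.events


@given(
    st.lists(st.floats(0.1, 5.0, allow_nan=False), min_size=1, max_size=30),
    st.integers(1, 4),
)
@settings(max_examples=80, deadline=None)
def test_patience_counter_matches_naive_oracle(losses, p):
    """Property: the trigger index equals a direct scan counting strict
    increases with reset on any non-increase."""
    state = fresh_state()
    got = feed(state, losses, p)
    count = 0
    expected = None
    for i in range(1, len(losses)):
        count = count + 1 if losses[i] > losses[i - 1] else 0
        if count >= p:
            expected = i + 1
            break
    assert got == expected
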