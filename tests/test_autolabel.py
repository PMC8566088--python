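import dataclasses

import numpy as np
import pytest

from gaitmark.autolabel import (
    AutoLabelResult,
    autolabel_cycle,
    autolabel_cycles,
    postprocess,
    select_training_data,
    tune_k,
)
from gaitmark.evaluation import success_rate
from gaitmark.experiments import split_half
from gaitmark.preprocess import extract_cycles, sliding_windows
from gaitmark.synthgait import GeneratorConfig, generate_day, generate_transition_day
from gaitmark.templates import build_template_library


@pytest.fixture(scope="module")
def clean_library(clean_day):
    rec, _ = clean_day
    return build_template_library([rec])


class TestAutolabelCycle:
    def test_noise_free_cycle_matches_its_own_pattern(self, clean_day,
                                                      clean_library):
        rec, _ = clean_day
        cycles = extract_cycles(rec)
        for c in cycles[::4]:
            r = autolabel_cycle(c, clean_library, k=0.05)
            assert r.assigned_pattern == c.label
            assert r.best_cost < 0.05
            assert r.selected

    def test_result_invariants(self, clean_day, clean_library):
        rec, _ = clean_day
        c = extract_cycles(rec)[0]
        r = autolabel_cycle(c, clean_library, k=1e9)
        assert r.best_cost == pytest.approx(min(r.all_costs))
        assert r.assigned_pattern == int(np.argmin(r.all_costs)) + 1
        assert r.selected  # k = +inf limit selects everything

    def test_k_must_be_positive_and_library_nonempty(self, clean_day,
                                                     clean_library):
        rec, _ = clean_day
        c = extract_cycles(rec)[0]
        with pytest.raises(ValueError):
            autolabel_cycle(c, clean_library, k=0.0)
        with pytest.raises(ValueError):
            autolabel_cycle(c, [], k=0.5)

    def test_label_invariant_to_library_order(self, clean_day,
                                              clean_library):
        rec, _ = clean_day
        c = extract_cycles(rec)[3]
        a = autolabel_cycle(c, clean_library, k=0.5)
        b = autolabel_cycle(c, clean_library[::-1], k=0.5)
        assert a.assigned_pattern == b.assigned_pattern
        assert np.allclose(a.all_costs, b.all_costs)

    def test_noisy_label_accuracy_above_95_percent(self):
        cfg = GeneratorConfig(noise_sd=0.3, seed=42)
        rec, _ = generate_day(cfg, n_cycles_per_pattern=20, seed=42)
        cycles = extract_cycles(rec)
        lib = build_template_library([rec])
        results = autolabel_cycles(cycles, lib, k=5.0)
        acc = np.mean([r.assigned_pattern == c.label
                       for r, c in zip(results, cycles)])
        assert acc > 0.95


def _result(pattern, cost=0.1, cid=0):
    return AutoLabelResult(cycle_ref=cid, assigned_pattern=pattern,
                           best_cost=cost, all_costs=np.array([cost]),
                           selected=True)


class TestPostprocess:
    def test_constant_labels_suppress_nothing(self, clean_day):
        rec, _ = clean_day
        cycles = extract_cycles(rec)[:4]
        results = [_result(1, cid=i) for i in range(4)]
        out = postprocess(results, cycles)
        assert not any(r.suppressed for r in out)

    def test_single_transition_suppresses_the_pair(self, clean_day):
        rec, _ = clean_day
        cycles = extract_cycles(rec)[:4]
        results = [_result(p, cid=i) for i, p in enumerate([1, 1, 2, 2])]
        out = postprocess(results, cycles)
        assert [r.suppressed for r in out] == [False, True, True, False]

    def test_transition_day_suppresses_exactly_the_boundary_pair(self,
                                                                 clean_cfg):
        rec, truth, transitions = generate_transition_day(
            clean_cfg, segments=[(1, 5), (2, 5)])
        assert transitions == [5]
        lib_day, _ = generate_day(clean_cfg, n_cycles_per_pattern=3)
        lib = build_template_library([lib_day])
        cycles = extract_cycles(rec)
        out = postprocess(autolabel_cycles(cycles, lib, k=0.5), cycles)
        assert [r.suppressed for r in out] == [False] * 4 + [True] * 2 + [False] * 4

    def test_segment_count_gives_one_fewer_transitions(self, clean_cfg):
        _, _, transitions = generate_transition_day(
            clean_cfg, segments=[(1, 2), (3, 2), (2, 2), (5, 2)])
        assert len(transitions) == 3


class TestSelection:
    def test_all_below_threshold_gives_dr_one(self, clean_day):
        rec, _ = clean_day
        cycles = extract_cycles(rec)
        windows = sliding_windows(rec, cycles=cycles)
        results = [_result(1, cost=0.01, cid=i) for i in range(len(cycles))]
        selected, dr = select_training_data(results, cycles, windows, k=1.0)
        assert dr == 1.0
        assert all(w.label == 1 for w in selected)

    def test_dr_arithmetic(self, clean_day):
        rec, _ = clean_day
        cycles = extract_cycles(rec)[:2]
        results = [_result(1, cost=0.1), _result(1, cost=0.3)]
        _, dr = select_training_data(results, cycles, [], k=0.2)
        assert dr == 0.5

    def test_dr_monotone_in_k(self, noisy_day):
        rec, _ = noisy_day
        cycles = extract_cycles(rec)
        lib = build_template_library([rec])
        results = autolabel_cycles(cycles, lib, k=1.0)
        drs = [select_training_data(results, cycles, [], k)[1]
               for k in np.linspace(0.01, 5.0, 12)]
        assert all(a <= b for a, b in zip(drs, drs[1:]))

    def test_suppressed_cycles_keep_stance_lose_swing(self, clean_day):
        rec, _ = clean_day
        cycles = extract_cycles(rec)
        windows = [w for w in sliding_windows(rec, cycles=cycles)
                   if w.cycle_index == 1]
        results = [_result(1, cid=i) for i in range(len(cycles))]
        results[1].suppressed = True
        selected, _ = select_training_data(results, cycles, windows, k=1.0)
        assert {w.phase for w in selected} == {"stance"}
        assert len(selected) < len(windows)

    def test_selection_is_subset_of_input_windows(self, noisy_day):
        rec, _ = noisy_day
        cycles = extract_cycles(rec)
        windows = sliding_windows(rec, cycles=cycles)
        lib = build_template_library([rec])
        results = postprocess(autolabel_cycles(cycles, lib, 1.0), cycles)
        selected, _ = select_training_data(results, cycles, windows, k=1.0)
        starts = {w.start for w in windows}
        assert len(selected) <= len(windows)
        assert all(w.start in starts for w in selected)


class TestTuneK:
    def test_grid_of_one_returns_that_value(self, noisy_day):
        rec, _ = noisy_day
        am, pm = split_half(rec)
        k_star, table = tune_k(am, pm, grid=[3.0])
        assert k_star == 3.0
        assert len(table) == 1

    def test_chosen_k_meets_dr_floor_and_maximizes_sr(self, noisy_day):
        rec, _ = noisy_day
        am, pm = split_half(rec)
        k_star, table = tune_k(am, pm, dr_min=0.9)
        feasible = table[table.dr >= 0.9]
        assert len(feasible) > 0
        row = table[table.k == k_star].iloc[0]
        assert row.dr >= 0.9
        # exhaustive check: no feasible grid value has higher SR
        assert row.sr >= feasible.sr.max() - 1e-12

    def test_sr_is_computed_on_selected_cycles(self, noisy_day):
        rec, _ = noisy_day
        am, pm = split_half(rec)
        lib = build_template_library([am])
        cycles = extract_cycles(pm)
        results = autolabel_cycles(cycles, lib, k=2.0)
        sr = success_rate(results, [c.label for c in cycles])
        correct_sel = [r.assigned_pattern == c.label
                       for r, c in zip(results, cycles) if r.selected]
        assert sr == pytest.approx(np.mean(correct_sel))

    def test_noise_free_sr_is_one_for_any_k_above_floor(self, clean_day,
                                                        clean_library):
        rec, _ = clean_day
        cycles = extract_cycles(rec)
        results = autolabel_cycles(cycles, clean_library, k=0.05)
        assert all(r.selected for r in results)
        assert success_rate(results, [c.label for c in cycles]) == 1.0


def test_replace_preserves_dataclass_fields():
    r = _result(2, cost=0.4)
    r2 = dataclasses.replace(r, selected=False)
    assert r2.assigned_pattern == 2 and not r2.selected and r.selected
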