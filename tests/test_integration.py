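"""Insertion plans, the staged reference host, tracing and map export."""

import numpy as np
import pytest
from PIL import Image

from attnkit.accounting import count_params
from attnkit.integration import (
    InsertionPlan,
    StagedCNN,
    attach_to_neck,
    attach_to_stages,
    export_attention_maps,
    forward_with_trace,
)
from attnkit.modules import make_variant
from attnkit.specs import ModuleSpec


class TestInsertionPlan:
    def test_one_module_per_width(self):
        plan = attach_to_stages([8, 16], ModuleSpec("gcli-b", 8, {"fraction": 0.5}))
        assert [m.channels for m in plan.modules] == [8, 16]
        assert plan.module_at(1) is plan.modules[1]
        assert plan.module_at(5) is None

    def test_added_params_is_sum_of_per_position_counts(self):
        spec = ModuleSpec("gcli-a", 8)
        plan = attach_to_stages([8, 16, 32], spec)
        expected = sum(count_params(spec.with_channels(w)) for w in (8, 16, 32))
        assert plan.added_params() == expected

    def test_neck_plan_matches_stage_plan_shape(self):
        spec = ModuleSpec("eca", 8)
        plan = attach_to_neck([8, 8, 8], spec)
        assert plan.positions == [(0, 8), (1, 8), (2, 8)]

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            InsertionPlan([(0, 16)], [make_variant("GCLI-A", 8)])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            InsertionPlan([(0, 8), (1, 8)], [make_variant("ECA", 8)])

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            attach_to_stages([8, 0], ModuleSpec("eca", 8))


class TestStagedCNN:
    def test_output_shape(self, rng):
        host = StagedCNN(stage_widths=(4, 8), n_classes=3, seed=1)
        x = rng.standard_normal((5, 8, 8, 1))
        assert host(x).shape == (5, 3)

    def test_seed_determinism(self, rng):
        x = rng.standard_normal((2, 8, 8, 1))
        a = StagedCNN(seed=7)(x)
        b = StagedCNN(seed=7)(x)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, StagedCNN(seed=8)(x))

    def test_odd_extent_rejected(self, rng):
        host = StagedCNN(stage_widths=(4,), seed=0)
        with pytest.raises(ValueError):
            host(rng.standard_normal((1, 7, 7, 1)))

    def test_zero_weight_gc_plan_is_bit_identical_to_plain_host(self, rng):
        host = StagedCNN(stage_widths=(4, 8), seed=2)
        plan = attach_to_stages([4, 8], ModuleSpec("gc", 4, {"ratio": 2}))
        for mod in plan.modules:
            mod.set_all_zero()
        x = rng.standard_normal((3, 8, 8, 1))
        assert np.array_equal(host(x, plan), host(x))

    def test_attached_gcli_changes_the_output(self, rng):
        host = StagedCNN(stage_widths=(4, 8), seed=2)
        plan = attach_to_stages([4, 8], ModuleSpec("gcli-a", 4), rng)
        x = rng.standard_normal((3, 8, 8, 1))
        assert not np.array_equal(host(x, plan), host(x))


class TestTracing:
    def test_trace_has_one_record_per_attached_module(self, rng):
        host = StagedCNN(stage_widths=(4, 8), seed=0)
        plan = attach_to_stages([4, 8], ModuleSpec("gcli-a", 4), rng)
        x = rng.standard_normal((2, 8, 8, 1))
        out, trace = forward_with_trace(host, plan, x)
        assert out.shape == (2, host.n_classes)
        assert [rec["position"] for rec in trace] == [0, 1]
        # stage i halves the extent i+1 times: 8 -> 4 -> 2
        assert trace[0]["alpha"].shape == (2, 4, 4)
        assert trace[1]["alpha"].shape == (2, 2, 2)
        np.testing.assert_allclose(trace[0]["alpha"].sum(axis=(1, 2)), 1.0)
        assert trace[0]["gate"].shape == (2, 4)
        assert np.all((trace[0]["gate"] > 0) & (trace[0]["gate"] < 1))

    def test_trace_without_plan_is_empty(self, rng):
        host = StagedCNN(stage_widths=(4,), seed=0)
        out, trace = forward_with_trace(host, None, rng.standard_normal((1, 4, 4, 1)))
        assert trace == []

    def test_plan_host_mismatch_rejected(self, rng):
        host = StagedCNN(stage_widths=(4, 8), seed=0)
        plan = attach_to_stages([4, 16], ModuleSpec("eca", 4))
        with pytest.raises(ValueError):
            forward_with_trace(host, plan, rng.standard_normal((1, 8, 8, 1)))


class TestExport:
    def _trace(self):
        one_hot = np.zeros((1, 2, 2))
        one_hot[0, 1, 0] = 1.0
        return [
            {"position": 0, "channels": 4,
             "alpha": np.full((1, 2, 2), 0.25), "gate": np.full((1, 4), 0.5)},
            {"position": 1, "channels": 8, "alpha": one_hot,
             "gate": np.linspace(0.1, 0.8, 8).reshape(1, 8)},
        ]

    def test_uniform_alpha_renders_mid_gray(self, tmp_path):
        export_attention_maps(self._trace(), tmp_path)
        img = np.asarray(Image.open(tmp_path / "alpha_pos0.png"))
        assert img.shape == (2, 2)
        assert np.all(img == 128)

    def test_one_hot_alpha_renders_single_white_pixel(self, tmp_path):
        export_attention_maps(self._trace(), tmp_path)
        img = np.asarray(Image.open(tmp_path / "alpha_pos1.png"))
        assert img[1, 0] == 255
        assert img.sum() == 255

    def test_gates_csv_rows(self, tmp_path):
        export_attention_maps(self._trace(), tmp_path)
        lines = (tmp_path / "gates.csv").read_text().strip().splitlines()
        assert lines[0] == "position,channels,gate_values"
        assert lines[1].startswith("0,4,0.5;0.5;0.5;0.5")
        assert len(lines) == 3

    def test_records_without_alpha_still_land_in_csv(self, tmp_path):
        trace = [{"position": 0, "channels": 4, "gate": np.full((1, 4), 0.5)}]
        written = export_attention_maps(trace, tmp_path)
        assert written == [tmp_path / "gates.csv"]

    def test_empty_trace_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_attention_maps([], tmp_path)

    def test_end_to_end_export_from_live_trace(self, tmp_path, rng):
        host = StagedCNN(stage_widths=(4,), seed=0)
        plan = attach_to_stages([4], ModuleSpec("gcli-a", 4), rng)
        _, trace = forward_with_trace(host, plan, rng.standard_normal((1, 4, 4, 1)))
        written = export_attention_maps(trace, tmp_path)
        assert (tmp_path / "alpha_pos0.png") in written
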