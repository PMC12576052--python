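"""Label transform, boosted regression fit/predict, strand averaging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qvmeth.errors import AlignmentMismatchError, InsufficientDataError
from qvmeth.model import (
    DEFAULT_HYPERPARAMS,
    MethylationLevelModel,
    TrainedModel,
    TransformConfig,
    average_strands,
    inverse_transform,
    logit_transform,
    predict_loci,
    train_model,
)
from qvmeth.records import MethylationRecord


class TestTransform:
    def test_midpoint_maps_to_zero_in_both_modes(self):
        for mode in ("clip", "literal"):
            assert logit_transform(0.5, TransformConfig(mode=mode)) == 0.0

    def test_literal_endpoint_constants(self):
        cfg = TransformConfig(alpha=1e-3, mode="literal")
        assert logit_transform(0.0, cfg) == -1e-3
        assert logit_transform(1.0, cfg) == 1e-3

    def test_interior_closed_form(self):
        assert logit_transform(0.9) == pytest.approx(math.log(9.0), abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            logit_transform(1.5)
        with pytest.raises(ValueError):
            logit_transform(-0.1)

    def test_sigmoid_inverse_values(self):
        assert inverse_transform(0.0) == 0.5
        assert inverse_transform(math.log(9.0)) == pytest.approx(0.9)
        assert inverse_transform(-50.0) == pytest.approx(0.0, abs=1e-20)

    @given(st.floats(min_value=1e-3, max_value=1.0 - 1e-3))
    @settings(derandomize=True, max_examples=50)
    def test_clip_round_trip_exact_inside_band(self, y):
        cfg = TransformConfig(alpha=1e-3, mode="clip")
        assert inverse_transform(logit_transform(y, cfg)) == pytest.approx(
            y, abs=1e-12
        )

    def test_clip_round_trip_saturates_outside_band(self):
        cfg = TransformConfig(alpha=1e-3, mode="clip")
        assert inverse_transform(logit_transform(0.0, cfg)) == pytest.approx(
            0.001
        )
        assert inverse_transform(logit_transform(1.0, cfg)) == pytest.approx(
            0.999
        )

    def test_clip_mode_is_monotone(self):
        cfg = TransformConfig(alpha=1e-3, mode="clip")
        grid = np.linspace(0, 1, 501)
        vals = logit_transform(grid, cfg)
        assert np.all(np.diff(vals) >= 0)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TransformConfig(alpha=0.7)
        with pytest.raises(ValueError):
            TransformConfig(mode="weird")


def _linear_dataset(n=60, n_feat=6, seed=2):
    """Levels that are an exact sigmoid-linear function of one feature."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_feat))
    levels = 1.0 / (1.0 + np.exp(-2.0 * X[:, 0]))
    return X, levels


class TestFitPredict:
    def test_self_fit_on_noiseless_linear_signal(self):
        X, levels = _linear_dataset()
        model = MethylationLevelModel(X, levels)
        res = model.fit(num_round=50, seed=0)
        pcc = np.corrcoef(levels, res.fittedvalues)[0, 1]
        assert pcc > 0.99

    def test_constant_labels_predict_constant(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        model = MethylationLevelModel(X, np.full(20, 0.7))
        res = model.fit(num_round=10, seed=0)
        assert np.allclose(res.predict(rng.normal(size=(5, 4))), 0.7,
                           atol=1e-6)

    def test_same_seed_is_deterministic(self):
        X, levels = _linear_dataset()
        preds = []
        for _ in range(2):
            res = MethylationLevelModel(X, levels).fit(num_round=30, seed=5)
            preds.append(res.predict(X[:10]))
        assert np.array_equal(preds[0], preds[1])

    def test_alignment_and_minimum_size_errors(self):
        X, levels = _linear_dataset()
        with pytest.raises(AlignmentMismatchError):
            MethylationLevelModel(X, levels[:-3])
        with pytest.raises(InsufficientDataError):
            MethylationLevelModel(X[:4], levels[:4])

    def test_default_hyperparams_echoed_in_metadata(self):
        X, levels = _linear_dataset(n=15)
        trained = train_model(X, levels, hyperparams={"num_round": 5})
        assert trained.hyperparams["eta"] == 0.1
        assert trained.hyperparams["max_depth"] == 8
        assert DEFAULT_HYPERPARAMS["num_round"] == 1500

    def test_save_load_round_trip(self, tmp_path):
        X, levels = _linear_dataset()
        res = MethylationLevelModel(X, levels, provenance="unit").fit(
            num_round=20, seed=1
        )
        res.save(tmp_path / "model")
        loaded = TrainedModel.load(tmp_path / "model")
        assert loaded.provenance == "unit"
        assert loaded.transform == TransformConfig()
        assert np.allclose(loaded.predict_levels(X), res.predict(X))

    def test_summary_mentions_fit_settings(self):
        X, levels = _linear_dataset(n=25)
        res = MethylationLevelModel(X, levels).fit(num_round=12, seed=0)
        text = res.summary()
        assert "num_round:       12" in text
        assert "No. loci:        25" in text

    def test_predict_loci_carries_identity_and_depth(self):
        X, levels = _linear_dataset(n=30)
        trained = train_model(X, levels, hyperparams={"num_round": 20})
        loci = [
            MethylationRecord("chr1", 10 * i, "+", 0.0, depth=12)
            for i in range(5)
        ]
        out = predict_loci(trained, X[:5], loci)
        assert [(r.chrom, r.start, r.depth) for r in out] == [
            ("chr1", 10 * i, 12) for i in range(5)
        ]
        assert all(0.0 <= r.level <= 1.0 for r in out)

    def test_predict_loci_empty_input(self):
        X, levels = _linear_dataset(n=12)
        trained = train_model(X, levels, hyperparams={"num_round": 5})
        assert predict_loci(trained, np.empty((0, X.shape[1])), []) == []


class TestStrandAveraging:
    def test_cpg_pair_is_averaged_at_forward_c(self):
        recs = [
            MethylationRecord("chr1", 100, "+", 0.8, depth=10),
            MethylationRecord("chr1", 101, "-", 0.6, depth=14),
        ]
        out = average_strands(recs)
        assert len(out) == 1
        assert out[0].start == 100
        assert out[0].level == pytest.approx(0.7)
        assert out[0].depth == 24

    def test_unpaired_record_passes_through(self):
        rec = MethylationRecord("chr1", 200, "+", 0.4, depth=9)
        assert average_strands([rec]) == [rec]

    def test_idempotent_on_equal_levels(self):
        recs = [
            MethylationRecord("chr1", 100, "+", 1.0),
            MethylationRecord("chr1", 101, "-", 1.0),
        ]
        out = average_strands(recs)
        assert out[0].level == 1.0

    def test_non_cpg_geometry_stays_unpaired(self):
        recs = [
            MethylationRecord("chr1", 100, "+", 0.8),
            MethylationRecord("chr1", 105, "-", 0.6),
        ]
        assert len(average_strands(recs)) == 2
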