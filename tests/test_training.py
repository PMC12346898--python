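import numpy as np
import pytest

from lungsound.audio_io import AudioSignal, MultiChannelRecording
from lungsound.model import ModelConfig
from lungsound.training import (
    SplitSpec,
    TrainConfig,
    TrainHistory,
    prepare_inputs,
    split,
    train_ensemble,
    train_session,
)
from lungsound.evaluation import aggregate_reports

TINY_MODEL = ModelConfig(stage_widths=(4, 8, 8, 16))


def _dataset(n_per_class, rng, n_samples=4000):
    out = []
    i = 0
    for label, n in n_per_class.items():
        for _ in range(n):
            x = rng.standard_normal(n_samples) * 0.1
            out.append(
                MultiChannelRecording(
                    channels={"BRUL": AudioSignal(x, 4000, "BRUL")},
                    label=label,
                    subject_id=f"S{i:03d}",
                )
            )
            i += 1
    return out


class TestSplit:
    def test_balanced_100_gives_70_15_15(self, rng):
        data = _dataset({"normal": 40, "wheeze": 40, "fine_crackle": 20}, rng, 200)
        tr, va, te = split(data, SplitSpec(seed=1))
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_disjoint_and_exhaustive(self, rng):
        data = _dataset({"normal": 11, "wheeze": 7, "fine_crackle": 5}, rng, 200)
        tr, va, te = split(data, SplitSpec(seed=2))
        ids = lambda part: {r.subject_id for r in part}
        assert ids(tr) | ids(va) | ids(te) == ids(data)
        assert not (ids(tr) & ids(va)) and not (ids(tr) & ids(te)) and not (ids(va) & ids(te))

    def test_stratification_per_class(self, rng):
        data = _dataset({"normal": 20, "wheeze": 10, "fine_crackle": 10}, rng, 200)
        tr, va, te = split(data, SplitSpec(seed=3))
        count = lambda part, lab: sum(r.label == lab for r in part)
        assert count(tr, "normal") == 14  # largest remainder of 20*(.7,.15,.15)
        assert count(tr, "wheeze") == 7
        assert count(va, "normal") == 3

    def test_seed_determinism(self, rng):
        data = _dataset({"normal": 9, "wheeze": 6, "fine_crackle": 6}, rng, 200)
        a = split(data, SplitSpec(seed=9))
        b = split(data, SplitSpec(seed=9))
        for pa, pb in zip(a, b):
            assert [r.subject_id for r in pa] == [r.subject_id for r in pb]

    def test_class_too_small_to_stratify(self, rng):
        data = _dataset({"normal": 5, "wheeze": 2, "fine_crackle": 5}, rng, 200)
        with pytest.raises(ValueError, match="stratify"):
            split(data, SplitSpec(seed=0))

    def test_augmented_variants_follow_their_subject(self, rng):
        data = _dataset({"normal": 4, "wheeze": 4, "fine_crackle": 4}, rng, 200)
        variants = []
        for rec in data[:4]:
            variants.append(
                MultiChannelRecording(
                    channels=rec.channels,
                    label=rec.label,
                    subject_id=f"{rec.subject_id}-aug0",
                    augmented=True,
                )
            )
        tr, va, te = split(data + variants, SplitSpec(seed=4))
        base = lambda r: r.subject_id.split("-aug")[0]
        for part in (tr, va, te):
            bases = {base(r) for r in part}
            for other in (tr, va, te):
                if other is part:
                    continue
                assert not bases & {base(r) for r in other}

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.3, 0.3))


class TestTrainConfig:
    def test_linear_lr_decay_endpoints(self):
        cfg = TrainConfig(epochs=50)
        assert cfg.lr_at_epoch(0) == pytest.approx(1e-4)
        assert cfg.lr_at_epoch(49) == pytest.approx(5e-5)
        mid = cfg.lr_at_epoch(25)
        assert 5e-5 < mid < 1e-4

    def test_single_epoch_uses_lr_start(self):
        assert TrainConfig(epochs=1).lr_at_epoch(0) == 1e-4

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(lr_start=1e-5, lr_end=1e-4)


def _toy_arrays(rng, n=12):
    x = rng.standard_normal((n, 1, 128, 350)).astype(np.float32)
    y = rng.integers(0, 3, n)
    # plant a separable cue so training has something to learn
    for i in range(n):
        x[i, 0, :, y[i] * 100 : y[i] * 100 + 80] += 1.5
    return x, np.asarray(y)


class TestTrainSession:
    def test_one_epoch_history(self, rng):
        x, y = _toy_arrays(rng)
        cfg = TrainConfig(epochs=1, batch_size=6, n_sessions=1)
        model, hist = train_session(TINY_MODEL, (x, y), (x[:4], y[:4]), cfg, 0)
        assert len(hist.train_loss) == 1
        assert np.isfinite(hist.train_loss[0])
        assert len(hist.val_loss) == 1

    def test_end_to_end_determinism(self, rng):
        x, y = _toy_arrays(rng)
        cfg = TrainConfig(epochs=2, batch_size=6, n_sessions=1, lr_start=1e-3, lr_end=5e-4)
        m1, h1 = train_session(TINY_MODEL, (x, y), (x[:4], y[:4]), cfg, 7)
        m2, h2 = train_session(TINY_MODEL, (x, y), (x[:4], y[:4]), cfg, 7)
        assert h1.train_loss == h2.train_loss
        for pa, pb in zip(m1.params(), m2.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_empty_partition_rejected(self, rng):
        x, y = _toy_arrays(rng)
        cfg = TrainConfig(epochs=1)
        with pytest.raises(ValueError):
            train_session(TINY_MODEL, (x[:0], y[:0]), (x, y), cfg, 0)


class TestTrainEnsemble:
    def test_three_sessions_report_mean_and_sd(self, rng):
        x, y = _toy_arrays(rng)
        cfg = TrainConfig(epochs=1, batch_size=6, n_sessions=3)
        models, hists, reports, agg = train_ensemble(
            TINY_MODEL, (x, y), (x[:4], y[:4]), (x[:6], y[:6]), cfg
        )
        assert len(models) == len(hists) == len(reports) == 3
        assert set(agg.mean) == {"accuracy", "sensitivity", "specificity", "precision", "f1"}
        assert all(v >= 0 for v in agg.sd.values())

    def test_single_session_sd_zero(self, rng):
        x, y = _toy_arrays(rng)
        cfg = TrainConfig(epochs=1, batch_size=6, n_sessions=1)
        *_, agg = train_ensemble(TINY_MODEL, (x, y), (x[:4], y[:4]), (x[:6], y[:6]), cfg)
        assert all(v == 0.0 for v in agg.sd.values())

    def test_forced_identical_sessions_sd_zero(self, rng):
        x, y = _toy_arrays(rng)
        cfg = TrainConfig(epochs=1, batch_size=6, n_sessions=1, seed=3)
        reports = []
        for _ in range(2):
            model, _ = train_session(TINY_MODEL, (x, y), (x[:4], y[:4]), cfg, 3)
            from lungsound.evaluation import confusion, metrics
            from lungsound.model import predict_batch

            reports.append(metrics(confusion(y[:6], predict_batch(model, x[:6]))))
        agg = aggregate_reports(reports)
        assert all(v == 0.0 for v in agg.sd.values())


class TestPrepareInputs:
    def test_shapes_and_labels(self, small_cohort):
        _, recordings, _ = small_cohort
        x, y = prepare_inputs(recordings[:4])
        assert x.shape == (4, 1, 128, 350)
        assert x.dtype == np.float32
        assert set(y) <= {0, 1, 2}

    def test_timeseries_kind(self, small_cohort):
        _, recordings, _ = small_cohort
        x, y = prepare_inputs(recordings[:2], input_kind="timeseries")
        assert x.shape == (2, 1, 128, 350)

    def test_unknown_kind(self, small_cohort):
        _, recordings, _ = small_cohort
        with pytest.raises(ValueError):
            prepare_inputs(recordings[:1], input_kind="stft")
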