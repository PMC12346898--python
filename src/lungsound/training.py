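"""Data splitting, seeded training sessions and the 3-session ensemble.

The protocol: split recordings 70:15:15 (stratified per class by
largest-remainder rounding, grouped by subject), train for 50 epochs with
batch size 20 under categorical cross-entropy and rectified Adam
(epsilon 1e-6), learning rate decaying linearly from 1e-4 to 5e-5 across
epochs, keep the best-validation-loss checkpoint, and repeat for three
independently seeded sessions whose evaluation metrics are reported as
mean +/- sd.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .audio_io import MultiChannelRecording
from .features import MfccParams, recording_to_model_input, timeseries_to_model_input
from .model import LungSoundNet, ModelConfig, build_model, predict_batch
from .nn import RAdam, softmax_cross_entropy
from .vocab import LABEL_TO_INDEX
from .evaluation import aggregate_reports, confusion, metrics
from .synth import largest_remainder_counts

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "TrainHistory",
    "DivergenceError",
    "split",
    "prepare_inputs",
    "train_session",
    "train_ensemble",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    stratified: bool = True
    group_by_subject: bool = True
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if f.size != 3 or np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError(f"fractions must be 3 non-negative values summing to 1, got {self.fractions}")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 20
    lr_start: float = 1e-4
    lr_end: float = 5e-5
    radam_eps: float = 1e-6
    n_sessions: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.lr_end <= self.lr_start:
            raise ValueError("need 0 < lr_end <= lr_start")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")

    def lr_at_epoch(self, epoch: int) -> float:
        """Linear decay from lr_start (epoch 0) to lr_end (final epoch)."""
        if self.epochs == 1:
            return self.lr_start
        frac = epoch / (self.epochs - 1)
        return self.lr_start + frac * (self.lr_end - self.lr_start)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.val_loss))


def split(
    dataset: list[MultiChannelRecording], spec: SplitSpec
) -> tuple[list, list, list]:
    """Disjoint, exhaustive train/val/test partition of the recordings.

    Stratified per class with largest-remainder rounding of the 70:15:15
    fractions; all recordings of one subject land in the same partition when
    ``group_by_subject`` (augmented variants carry their source subject's
    id prefix, so quarantining them is the caller's concern — see
    ``augment.rebalance``).
    """
    if not dataset:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)

    def base_subject(rec):
        return rec.subject_id.split("-aug")[0]

    if spec.group_by_subject:
        groups: dict[str, list] = {}
        for rec in dataset:
            groups.setdefault(base_subject(rec), []).append(rec)
        units = [(sid, recs, recs[0].label) for sid, recs in groups.items()]
    else:
        units = [(rec.subject_id, [rec], rec.label) for rec in dataset]

    parts: tuple[list, list, list] = ([], [], [])
    if spec.stratified:
        classes = sorted({lab for _, _, lab in units}, key=lambda l: LABEL_TO_INDEX[l])
        for lab in classes:
            members = [u for u in units if u[2] == lab]
            if len(members) < 3:
                raise ValueError(
                    f"class {lab!r} has only {len(members)} subjects; need >= 3 to stratify"
                )
            _assign(members, spec.fractions, rng, parts)
    else:
        _assign(units, spec.fractions, rng, parts)
    return parts


def _assign(units, fractions, rng, parts):
    order = rng.permutation(len(units))
    counts = largest_remainder_counts(len(units), fractions)
    bounds = np.cumsum(counts)
    for rank, idx in enumerate(order):
        part = int(np.searchsorted(bounds, rank, side="right"))
        parts[part].extend(units[idx][1])


def prepare_inputs(
    recordings: list[MultiChannelRecording],
    input_kind: str = "mfcc",
    params: MfccParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature grids and integer labels as network-ready arrays.

    Returns ``X`` of shape (n, 1, 128, 350) float32 and ``y`` of shape (n,).
    """
    xs, ys = [], []
    for rec in recordings:
        if input_kind == "mfcc":
            mi = recording_to_model_input(rec, params)
        elif input_kind == "timeseries":
            mi = timeseries_to_model_input(rec)
        else:
            raise ValueError(f"unknown input_kind {input_kind!r}")
        xs.append(mi.grid.astype(np.float32))
        ys.append(LABEL_TO_INDEX[rec.label])
    x = np.stack(xs)[:, None] if xs else np.empty((0, 1, 128, 350), np.float32)
    return x, np.asarray(ys, dtype=np.int64)


def _eval_loss_acc(model, x, y, batch_size):
    losses, correct = [], 0
    for i in range(0, x.shape[0], batch_size):
        logits = model.forward(x[i : i + batch_size], train=False)
        loss, _ = softmax_cross_entropy(logits, y[i : i + batch_size])
        losses.append(loss * (logits.shape[0]))
        correct += int((np.argmax(logits, axis=1) == y[i : i + batch_size]).sum())
    n = x.shape[0]
    return float(np.sum(losses) / n), correct / n


def train_session(
    model_config: ModelConfig,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    session_seed: int,
    log=None,
) -> tuple[LungSoundNet, TrainHistory]:
    """One fully seeded training session.

    Per-epoch train/validation loss and accuracy are logged; the parameters
    with the best validation loss are restored before returning.
    """
    x_tr, y_tr = train_data
    x_val, y_val = val_data
    if x_tr.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("train and validation partitions must be non-empty")
    model = build_model(model_config, seed=session_seed)
    opt = RAdam(model.params(), lr=config.lr_start, eps=config.radam_eps)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([session_seed, 0x5F]))
    history = TrainHistory()
    best = (np.inf, None)
    for epoch in range(config.epochs):
        opt.lr = config.lr_at_epoch(epoch)
        order = shuffle_rng.permutation(x_tr.shape[0])
        epoch_loss, correct = 0.0, 0
        for i in range(0, order.size, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(x_tr[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * idx.size
            correct += int((np.argmax(logits, axis=1) == y_tr[idx]).sum())
        val_loss, val_acc = _eval_loss_acc(model, x_val, y_val, config.batch_size)
        history.train_loss.append(epoch_loss / order.size)
        history.train_acc.append(correct / order.size)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        history.lr.append(opt.lr)
        if val_loss < best[0]:
            best = (val_loss, copy.deepcopy(model.state_arrays()))
        if log is not None:
            log(
                f"epoch {epoch + 1}/{config.epochs} lr={opt.lr:.2e} "
                f"train_loss={history.train_loss[-1]:.4f} train_acc={history.train_acc[-1]:.3f} "
                f"val_loss={val_loss:.4f} val_acc={val_acc:.3f}"
            )
    if best[1] is not None:
        model.load_state_arrays(best[1])
    return model, history


def train_ensemble(
    model_config: ModelConfig,
    train_data,
    val_data,
    test_data,
    config: TrainConfig,
    log=None,
):
    """``n_sessions`` independent sessions (seeds = base seed + index).

    Each session's model is evaluated on the test partition; the per-session
    reports are aggregated to mean +/- sd, matching the ensemble-of-3
    reporting convention.
    """
    x_te, y_te = test_data
    models, histories, reports = [], [], []
    for s in range(config.n_sessions):
        seed = config.seed + s
        model, hist = train_session(model_config, train_data, val_data, config, seed, log=log)
        y_pred = predict_batch(model, x_te, config.batch_size)
        reports.append(metrics(confusion(y_te, y_pred)))
        models.append(model)
        histories.append(hist)
    return models, histories, reports, aggregate_reports(reports)
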