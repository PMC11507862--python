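"""Trainable fragment-intensity and retention-time predictors.

Both predictors are scikit-learn-style estimators: hyperparameters in
``__init__`` (so ``get_params``/``set_params`` and cloning work), state
learned by ``fit`` stored in trailing-underscore attributes, deterministic
``predict``. Training minimizes a mask-aware L1 loss with Adam under linear
learning-rate warmup; masked cells (shared peaks, out-of-scan-range ions,
padding) contribute exactly zero gradient.

The fragment model is a transformer encoder over the residue sequence with
modification and metadata channels (charge, NCE, instrument); its output is
the (L-1) x ion-column intensity grid. The RT model is a 1-D convolution
followed by a BiLSTM and a pooled sigmoid head predicting normalized RT in
[0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .chem import Peptidoform
from .fragments import FragmentColumnLayout
from .training_data import RTExample, TrainingExample

AA_VOCAB = {aa: i + 1 for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}  # 0 = pad
MOD_VOCAB = {0: 0, 4: 1, 21: 2, 35: 3}  # unimod id -> channel index
INSTRUMENT_VOCAB = {"Lumos": 0, "QE": 1, "timsTOF": 2, "Eclipse": 3}
DEFAULT_MAX_LEN = 35


class EncodingError(ValueError):
    pass


def encode_peptidoform(
    p: Peptidoform,
    charge: int,
    nce: float,
    instrument: str,
    max_len: int = DEFAULT_MAX_LEN,
) -> dict:
    """Deterministic model input encoding.

    Per-residue token and modification channels plus broadcast metadata
    (charge, NCE, instrument). Instruments outside the supported vocabulary
    fall back to the "Lumos" channel, mirroring how unsupported instrument
    metadata is handled upstream.
    """
    L = len(p.sequence)
    if L > max_len:
        raise EncodingError(f"sequence length {L} exceeds max_len {max_len}")
    try:
        aa_idx = np.array([AA_VOCAB[a] for a in p.sequence], dtype=int)
    except KeyError as exc:
        raise EncodingError(f"unsupported residue in {p.sequence}") from exc
    mod_idx = np.zeros(L, dtype=int)
    for pos, uid, _ in p.mods:
        if uid not in MOD_VOCAB:
            raise EncodingError(f"unsupported modification UniMod:{uid}")
        mod_idx[pos - 1] = MOD_VOCAB[uid]
    return {
        "aa_idx": aa_idx,
        "mod_idx": mod_idx,
        "charge": float(charge),
        "nce": float(nce),
        "instrument_idx": INSTRUMENT_VOCAB.get(instrument, 0),
        "length": L,
    }


def _pad_batch(encodings: list[dict], max_len: int):
    B = len(encodings)
    L = max(e["length"] for e in encodings)
    aa = np.zeros((B, L), dtype=int)
    mod = np.zeros((B, L), dtype=int)
    inst = np.zeros(B, dtype=int)
    meta = np.zeros((B, 2))
    pad = np.ones((B, L), dtype=bool)
    for i, e in enumerate(encodings):
        n = e["length"]
        aa[i, :n] = e["aa_idx"]
        mod[i, :n] = e["mod_idx"]
        inst[i] = e["instrument_idx"]
        meta[i] = (e["charge"] / 4.0, e["nce"] / 40.0)
        pad[i, :n] = False
    return aa, mod, inst, meta, pad


def masked_l1_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute error over unmasked cells (mask True = excluded)."""
    if pred.shape != target.shape or pred.shape != mask.shape:
        raise ValueError("pred, target and mask must be congruent")
    keep = ~mask
    n = int(keep.sum())
    if n == 0:
        raise ValueError("all cells are masked; loss undefined")
    return float(np.abs(pred - target)[keep].sum() / n)


def _sinusoidal(max_len: int, d: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.zeros((max_len, d))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


@dataclass
class ModelConfig:
    """Training hyperparameters. The fragment / RT defaults follow the
    fine-tuning recipe (20/40 epochs, 10 warmup epochs, lr 1e-4, batch 512/
    1024); depth and width knobs are desk-scale by default."""

    frag: dict = field(
        default_factory=lambda: dict(
            epochs=20, warmup_epochs=10, lr=1e-4, batch_size=512,
            n_layers=2, d_model=64, n_heads=4, d_ff=128,
        )
    )
    rt: dict = field(
        default_factory=lambda: dict(
            epochs=40, warmup_epochs=10, lr=1e-4, batch_size=1024,
            conv_channels=64, hidden=64,
        )
    )
    seed: int = 0

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "ModelConfig":
        """Training recipe for from-scratch fitting of the desk-scale models
        on synthetic data (more steps, higher learning rate than the
        fine-tuning defaults, smaller batches)."""
        return cls(
            frag=dict(
                epochs=20, warmup_epochs=5, lr=1e-3, batch_size=64,
                n_layers=2, d_model=64, n_heads=4, d_ff=128,
            ),
            rt=dict(
                epochs=25, warmup_epochs=5, lr=3e-3, batch_size=128,
                conv_channels=64, hidden=64,
            ),
            seed=seed,
        )


class _FragNet(nn.Module):
    def __init__(self, rng, n_layers, d_model, n_heads, d_ff, n_columns, max_len):
        self.aa_emb = nn.Embedding(rng, len(AA_VOCAB) + 1, d_model)
        self.mod_emb = nn.Embedding(rng, len(MOD_VOCAB), d_model)
        self.inst_emb = nn.Embedding(rng, len(INSTRUMENT_VOCAB), d_model)
        self.meta_proj = nn.Linear(rng, 2, d_model)
        self.layers = [
            nn.TransformerEncoderLayer(rng, d_model, n_heads, d_ff)
            for _ in range(n_layers)
        ]
        self.head1 = nn.Linear(rng, 2 * d_model, d_model)
        self.head2 = nn.Linear(rng, d_model, n_columns)
        self.pos = _sinusoidal(max_len, d_model)

    def __call__(self, aa, mod, inst, meta, pad) -> nn.Tensor:
        B, L = aa.shape
        x = (
            self.aa_emb(aa)
            + self.mod_emb(mod)
            + nn.Tensor(self.pos[None, :L, :])
            + self.inst_emb(inst).reshape(B, 1, -1)
            + self.meta_proj(nn.Tensor(meta)).reshape(B, 1, -1)
        )
        for layer in self.layers:
            x = layer(x, pad)
        pairs = nn.concat([x[:, :-1, :], x[:, 1:, :]], axis=-1)  # cleavage sites
        return self.head2(self.head1(pairs).relu())


class FragmentIntensityPredictor(BaseEstimator):
    """Transformer-style fragment ion intensity model with peak masking.

    ``fit`` consumes :class:`~diaforge.training_data.TrainingExample`
    objects whose matrices share one column layout. Prediction returns the
    (L-1) x columns grid clipped at 0 and rescaled to max 1.
    """

    def __init__(
        self,
        n_layers: int = 2,
        d_model: int = 64,
        n_heads: int = 4,
        d_ff: int = 128,
        epochs: int = 20,
        warmup_epochs: int = 10,
        lr: float = 1e-4,
        batch_size: int = 512,
        max_len: int = DEFAULT_MAX_LEN,
        seed: int = 0,
    ):
        self.n_layers = n_layers
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.epochs = epochs
        self.warmup_epochs = warmup_epochs
        self.lr = lr
        self.batch_size = batch_size
        self.max_len = max_len
        self.seed = seed

    # -- fitting ------------------------------------------------------------

    def fit(self, examples: list[TrainingExample], init: str | list | None = None):
        if not examples:
            raise ValueError("training set is empty")
        if self.warmup_epochs > self.epochs and self.epochs > 0:
            raise ValueError("warmup_epochs must be <= epochs")
        layout = examples[0].matrix.layout
        for ex in examples:
            if ex.matrix.layout != layout:
                raise ValueError("all examples must share one column layout")
        rng = np.random.default_rng(self.seed)
        net = _FragNet(
            rng, self.n_layers, self.d_model, self.n_heads, self.d_ff,
            layout.n_columns, self.max_len,
        )
        if init is not None:
            net.load_state_arrays(_load_init(init))
        self.layout_ = layout
        self.net_ = net
        self.history_ = []
        opt = nn.Adam(net.parameters(), lr=self.lr)
        order = np.arange(len(examples))
        for epoch in range(self.epochs):
            rng.shuffle(order)
            scale = nn.warmup_scale(epoch, self.warmup_epochs)
            losses = []
            for lo in range(0, len(order), self.batch_size):
                batch = [examples[i] for i in order[lo : lo + self.batch_size]]
                loss = self._batch_loss(batch)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"training diverged (loss NaN) at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step(lr_scale=scale)
                losses.append(float(loss.data))
            self.history_.append(float(np.mean(losses)))
        return self

    def _batch_loss(self, batch: list[TrainingExample]) -> nn.Tensor:
        encs = [
            encode_peptidoform(ex.peptidoform, ex.charge, ex.nce, ex.instrument, self.max_len)
            for ex in batch
        ]
        aa, mod, inst, meta, pad = _pad_batch(encs, self.max_len)
        out = self.net_(aa, mod, inst, meta, pad)
        B, rows, C = out.shape
        target = np.zeros((B, rows, C))
        keep = np.zeros((B, rows, C), dtype=bool)
        for i, ex in enumerate(batch):
            r = ex.matrix.intensity.shape[0]
            target[i, :r] = ex.matrix.intensity
            keep[i, :r] = ~ex.matrix.mask
        return nn.masked_mean_abs(out, target, keep)

    # -- prediction ---------------------------------------------------------

    def predict(
        self,
        peptidoforms: list[Peptidoform],
        charges: list[int],
        nce: float,
        instrument: str,
    ) -> list[np.ndarray]:
        """Per-peptidoform intensity grids, each clipped to >= 0 and rescaled
        so the maximum equals 1. Prediction runs in fixed-size chunks to keep
        memory flat on large libraries."""
        results = []
        chunk = 256
        for lo in range(0, len(peptidoforms), chunk):
            peps = peptidoforms[lo : lo + chunk]
            encs = [
                encode_peptidoform(p, z, nce, instrument, self.max_len)
                for p, z in zip(peps, charges[lo : lo + chunk])
            ]
            aa, mod, inst, meta, pad = _pad_batch(encs, self.max_len)
            out = self.net_(aa, mod, inst, meta, pad).data
            for i, p in enumerate(peps):
                grid = np.clip(out[i, : len(p.sequence) - 1], 0.0, None)
                m = grid.max()
                results.append(grid / m if m > 0 else grid)
        return results

    def predict_single(
        self, p: Peptidoform, charge: int, nce: float, instrument: str
    ) -> np.ndarray:
        return self.predict([p], [charge], nce, instrument)[0]

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        _save_model(self, path, extra={"layout": self.layout_.to_dict()})

    @classmethod
    def load(cls, path: str) -> "FragmentIntensityPredictor":
        model, meta, arrays = _load_model(cls, path)
        layout = FragmentColumnLayout.from_dict(meta["extra"]["layout"])
        rng = np.random.default_rng(model.seed)
        model.net_ = _FragNet(
            rng, model.n_layers, model.d_model, model.n_heads, model.d_ff,
            layout.n_columns, model.max_len,
        )
        model.net_.load_state_arrays(arrays)
        model.layout_ = layout
        model.history_ = meta["history"]
        return model


class _RTNet(nn.Module):
    def __init__(self, rng, conv_channels, hidden, d_emb=32):
        self.aa_emb = nn.Embedding(rng, len(AA_VOCAB) + 1, d_emb)
        self.mod_emb = nn.Embedding(rng, len(MOD_VOCAB), d_emb)
        self.conv = nn.Conv1d(rng, d_emb, conv_channels, kernel=3)
        self.lstm = nn.BiLSTM(rng, conv_channels, hidden)
        self.head = nn.Linear(rng, 2 * hidden, 1)

    def __call__(self, aa, mod, pad) -> nn.Tensor:
        valid = (~pad).astype(float)[:, :, None]
        x = (self.aa_emb(aa) + self.mod_emb(mod)) * nn.Tensor(valid)
        h = self.lstm(self.conv(x).relu() * nn.Tensor(valid), valid=~pad)
        pooled = (h * nn.Tensor(valid)).sum(axis=1) * nn.Tensor(
            1.0 / valid.sum(axis=1)
        )
        return self.head(pooled).sigmoid().reshape(-1)


class RetentionTimePredictor(BaseEstimator):
    """Conv + BiLSTM retention-time model predicting normalized RT in [0, 1]."""

    def __init__(
        self,
        conv_channels: int = 64,
        hidden: int = 64,
        epochs: int = 40,
        warmup_epochs: int = 10,
        lr: float = 1e-4,
        batch_size: int = 1024,
        max_len: int = DEFAULT_MAX_LEN,
        seed: int = 0,
    ):
        self.conv_channels = conv_channels
        self.hidden = hidden
        self.epochs = epochs
        self.warmup_epochs = warmup_epochs
        self.lr = lr
        self.batch_size = batch_size
        self.max_len = max_len
        self.seed = seed

    def fit(self, examples: list[RTExample], init: str | list | None = None,
            rt_norm_max: float | None = None):
        if not examples:
            raise ValueError("training set is empty")
        rng = np.random.default_rng(self.seed)
        net = _RTNet(rng, self.conv_channels, self.hidden)
        if init is not None:
            net.load_state_arrays(_load_init(init))
        self.net_ = net
        self.history_ = []
        self.rt_norm_max_ = rt_norm_max
        opt = nn.Adam(net.parameters(), lr=self.lr)
        order = np.arange(len(examples))
        targets = np.array([ex.rt_norm for ex in examples])
        for epoch in range(self.epochs):
            rng.shuffle(order)
            scale = nn.warmup_scale(epoch, self.warmup_epochs)
            losses = []
            for lo in range(0, len(order), self.batch_size):
                idx = order[lo : lo + self.batch_size]
                out = self._forward([examples[i].peptidoform for i in idx])
                loss = (out - nn.Tensor(targets[idx])).abs().mean()
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"training diverged (loss NaN) at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step(lr_scale=scale)
                losses.append(float(loss.data))
            self.history_.append(float(np.mean(losses)))
        return self

    def _forward(self, peptidoforms: list[Peptidoform]) -> nn.Tensor:
        encs = [
            encode_peptidoform(p, 2, 0.0, "Lumos", self.max_len) for p in peptidoforms
        ]
        aa, mod, _, _, pad = _pad_batch(encs, self.max_len)
        return self.net_(aa, mod, pad)

    def predict(self, peptidoforms: list[Peptidoform]) -> np.ndarray:
        """Normalized RT per peptidoform, clipped to [0, 1]."""
        out = []
        chunk = 512
        for lo in range(0, len(peptidoforms), chunk):
            out.append(
                np.clip(self._forward(peptidoforms[lo : lo + chunk]).data, 0.0, 1.0)
            )
        return np.concatenate(out) if out else np.zeros(0)

    def predict_single(self, p: Peptidoform) -> float:
        return float(self.predict([p])[0])

    def save(self, path: str) -> None:
        _save_model(self, path, extra={"rt_norm_max": self.rt_norm_max_})

    @classmethod
    def load(cls, path: str) -> "RetentionTimePredictor":
        model, meta, arrays = _load_model(cls, path)
        rng = np.random.default_rng(model.seed)
        model.net_ = _RTNet(rng, model.conv_channels, model.hidden)
        model.net_.load_state_arrays(arrays)
        model.history_ = meta["history"]
        model.rt_norm_max_ = meta["extra"].get("rt_norm_max")
        return model


# ---------------------------------------------------------------------------
# persistence helpers (self-describing checkpoints: config + parameters)
# ---------------------------------------------------------------------------


def _save_model(model, path: str, extra: dict) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(model.net_.state_arrays())}
    meta = {
        "class": type(model).__name__,
        "params": model.get_params(),
        "history": model.history_,
        "extra": extra,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def _load_model(cls, path: str):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    if meta["class"] != cls.__name__:
        raise ValueError(f"checkpoint holds a {meta['class']}, expected {cls.__name__}")
    model = cls(**meta["params"])
    return model, meta, arrays


def _load_init(init) -> list[np.ndarray]:
    """Optional warm-start hook: a checkpoint path or a list of arrays."""
    if isinstance(init, (list, tuple)):
        return list(init)
    with np.load(init) as data:
        return [data[f"p{i}"] for i in range(len(data.files) - ("__meta__" in data.files))]


# -- thin functional wrappers ------------------------------------------------


def fine_tune_fragment_model(
    train: list[TrainingExample], config: ModelConfig, init=None
) -> FragmentIntensityPredictor:
    return FragmentIntensityPredictor(seed=config.seed, **config.frag).fit(train, init=init)


def fine_tune_rt_model(
    train: list[RTExample], config: ModelConfig, init=None, rt_norm_max: float | None = None
) -> RetentionTimePredictor:
    return RetentionTimePredictor(seed=config.seed, **config.rt).fit(
        train, init=init, rt_norm_max=rt_norm_max
    )


def predict_fragment_intensities(
    m: FragmentIntensityPredictor, p: Peptidoform, charge: int, nce: float, instrument: str
) -> np.ndarray:
    return m.predict_single(p, charge, nce, instrument)


def predict_rt(m: RetentionTimePredictor, p: Peptidoform) -> float:
    return m.predict_single(p)
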