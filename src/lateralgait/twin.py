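"""The dual-task "Twin Brother" model.

The *Elder Brother* classifies the current lateral-gait phase from the
48-dimensional time-domain EMG feature vector with a CNN + channel
attention (SEAM) + LSTM stack; the *Younger Brother* regresses a
continuous target (hip angle, or within-phase percentage) from the same 48
features concatenated with the Elder's phase decision, a 49-dimensional
input feeding a 20-12-6 dense stack.

Architecture (Elder): input 48x1x1 -> conv 3x3/32 ReLU -> conv 3x3/64 ReLU
with squeeze-excitation reweighting (weights from the first conv's maps,
applied to the second's) -> 2x1 max-pool -> 22-step sequence of 64-dim
vectors -> LSTM(48) -> dense 64 ReLU -> dense 16 ReLU -> dense 4 softmax.
Per-layer trainable parameter counts: 320, 18,496, 3,136, 1,040, 68.

A ``statsmodels``-style surface is provided by :class:`TwinBrotherModel` /
:class:`TwinResults`; the module-level functions are the functional API.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from ._nn import (LSTM, Adam, Conv2dH, Dense, MaxPool2, SEGate, sigmoid,
                  softmax, train_network)
from .features import FeatureScaler, feature_columns
from .simulate import PHASES


@dataclass
class ElderConfig:
    """Phase-classifier hyperparameters (printed training recipe)."""

    input_dim: int = 48
    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel: tuple = (3, 3)
    seam_reduction: int = 4
    seam_placement: str = "conv"  # {"conv", "post_lstm"}
    lstm_hidden: int = 48
    fc1: int = 64
    fc2: int = 16
    classes: int = 4
    epochs: int = 850
    lr: float = 0.01
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 700
    batch_size: int = 128
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes != 4:
            raise ValueError("the phase classifier has exactly 4 classes")
        if self.conv1_filters % self.seam_reduction:
            raise ValueError("conv1_filters must divide by seam_reduction")
        if self.seam_placement not in ("conv", "post_lstm"):
            raise ValueError(f"unknown seam placement {self.seam_placement!r}")


@dataclass
class YoungerConfig:
    """Regressor hyperparameters: 49 -> 20 -> 12 -> 6 -> 1, ReLU hidden."""

    input_dim: int = 49
    hidden: tuple = (20, 12, 6)
    epochs: int = 850
    lr: float = 0.01
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 700
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim != 49:
            raise ValueError("younger input is 48 features + 1 phase code")
        if tuple(self.hidden) != (20, 12, 6):
            raise ValueError("hidden sizes are fixed at (20, 12, 6)")


# ---------------------------------------------------------------------------
# networks

class ElderNet:
    """CNN + SEAM + LSTM phase classifier producing 4-class logits."""

    def __init__(self, cfg: ElderConfig) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10]))
        kh, kw = cfg.kernel
        self.cfg = cfg
        self.conv1 = Conv2dH(kh, kw, 1, cfg.conv1_filters, rng, name="conv1")
        self.conv2 = Conv2dH(kh, kw, cfg.conv1_filters, cfg.conv2_filters,
                             rng, name="conv2")
        bottleneck = cfg.conv1_filters // cfg.seam_reduction
        if cfg.seam_placement == "conv":
            self.se = SEGate(cfg.conv1_filters, cfg.conv2_filters, bottleneck,
                             rng, name="seam")
        else:
            self.se = SEGate(cfg.lstm_hidden, cfg.lstm_hidden,
                             max(1, cfg.lstm_hidden // cfg.seam_reduction),
                             rng, name="seam")
        self.pool = MaxPool2()
        self.lstm = LSTM(cfg.conv2_filters, cfg.lstm_hidden, rng, name="lstm")
        self.fc1 = Dense(cfg.lstm_hidden, cfg.fc1, rng, relu=True, name="fc1")
        self.fc2 = Dense(cfg.fc1, cfg.fc2, rng, relu=True, name="fc2")
        self.out = Dense(cfg.fc2, cfg.classes, rng, name="output")

    def params(self):
        return (self.conv1.params() + self.conv2.params() + self.se.params()
                + self.lstm.params() + self.fc1.params() + self.fc2.params()
                + self.out.params())

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        h = x.reshape(n, self.cfg.input_dim, 1)
        c1 = self.conv1.forward(h)
        c2 = self.conv2.forward(c1)
        if self.cfg.seam_placement == "conv":
            gated = self.se.forward(c1, c2)
        else:
            gated = c2
        p = self.pool.forward(gated)
        hlast = self.lstm.forward(p)
        if self.cfg.seam_placement == "post_lstm":
            hlast = self.se.forward(hlast[:, None, :], hlast[:, None, :])[:, 0, :]
        return self.out.forward(self.fc2.forward(self.fc1.forward(hlast)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.fc1.backward(self.fc2.backward(self.out.backward(dout)))
        if self.cfg.seam_placement == "post_lstm":
            dsrc, dtgt = self.se.backward(dh[:, None, :])
            dh = (dsrc + dtgt)[:, 0, :]
        dp = self.lstm.backward(dh)
        dgated = self.pool.backward(dp)
        if self.cfg.seam_placement == "conv":
            dc1_attn, dc2 = self.se.backward(dgated)
            dc1 = self.conv2.backward(dc2) + dc1_attn
        else:
            dc1 = self.conv2.backward(dgated)
        return self.conv1.backward(dc1).reshape(dout.shape[0], -1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(np.asarray(x, float)))

    def layer_table(self) -> list[tuple[str, int]]:
        named = [self.conv1, self.conv2, self.se, self.lstm, self.fc1,
                 self.fc2, self.out]
        return [(lay.name, sum(p.size for p in lay.params())) for lay in named]


class YoungerNet:
    """49 -> 20 -> 12 -> 6 -> 1 dense regressor, ReLU hidden, linear out."""

    def __init__(self, cfg: YoungerConfig, input_dim: int | None = None) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 20]))
        dims = [input_dim or cfg.input_dim, *cfg.hidden, 1]
        # targets are standardized for training; predictions are mapped back
        self.target_mean = 0.0
        self.target_scale = 1.0
        self.layers = []
        for i in range(len(dims) - 1):
            relu = i < len(dims) - 2
            name = f"hidden{i+1}" if relu else "output"
            self.layers.append(Dense(dims[i], dims[i + 1], rng, relu=relu,
                                     name=name))

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    def predict(self, x: np.ndarray) -> np.ndarray:
        out = self.forward(np.asarray(x, float))[:, 0]
        return out * self.target_scale + self.target_mean

    def layer_table(self) -> list[tuple[str, int]]:
        return [(lay.name, sum(p.size for p in lay.params()))
                for lay in self.layers]


def fit_younger_head(net: YoungerNet, X: np.ndarray, target: np.ndarray,
                     cfg: YoungerConfig, seed: int | None = None) -> list:
    """Train a regressor head on a standardized target.

    The target is z-scored for training (so convergence is independent of
    whether the quantity is a hip angle in degrees or a percentage) and the
    statistics are stored on the network, which maps predictions back to
    physical units.  Returns the per-epoch loss trace in standardized units.
    """
    t = np.asarray(target, float)
    tm = float(t.mean())
    ts = float(t.std()) or 1.0
    losses = train_network(
        net, X, (t - tm) / ts, loss="mse", epochs=cfg.epochs, lr=cfg.lr,
        batch_size=cfg.batch_size, lr_drop_factor=cfg.lr_drop_factor,
        lr_drop_period=cfg.lr_drop_period,
        seed=cfg.seed if seed is None else seed)
    net.target_mean, net.target_scale = tm, ts
    return losses


def build_elder(config: ElderConfig | None = None) -> ElderNet:
    return ElderNet(config or ElderConfig())


def build_younger(config: YoungerConfig | None = None,
                  input_dim: int | None = None) -> YoungerNet:
    return YoungerNet(config or YoungerConfig(), input_dim=input_dim)


def count_parameters(net) -> pd.DataFrame:
    """Per-layer trainable parameter counts (weights + biases)."""
    table = net.layer_table()
    return pd.DataFrame(table, columns=["layer", "parameters"])


# ---------------------------------------------------------------------------
# spec'd operations

def seam(channel_maps: np.ndarray, params: SEGate | None = None,
         seed: int = 0) -> np.ndarray:
    """Classic squeeze-excitation: gate maps with weights from themselves.

    ``channel_maps`` is (N, H, C) with C divisible by 4.  A fresh gate is
    built (seeded) when ``params`` is not supplied.
    """
    maps = np.asarray(channel_maps, float)
    c = maps.shape[-1]
    if c % 4:
        raise ValueError("channel count must be divisible by 4")
    if params is None:
        params = SEGate(c, c, c // 4, np.random.default_rng(seed))
    return params.forward(maps, maps)


def cross_entropy(predicted_probs: np.ndarray,
                  one_hot_labels: np.ndarray) -> float:
    """L = -(1/G) sum_i sum_j h_ij log(H_ij), probabilities clamped at 1e-12."""
    p = np.clip(np.asarray(predicted_probs, float), 1e-12, None)
    h = np.asarray(one_hot_labels, float)
    if p.shape != h.shape:
        raise ValueError("probability and label matrices must match in shape")
    return float(-(h * np.log(p)).sum() / len(p))


def mse_loss(predicted: np.ndarray, true: np.ndarray) -> float:
    """(1/T) sum (w_t - W_t)^2."""
    p = np.asarray(predicted, float)
    t = np.asarray(true, float)
    if p.shape != t.shape:
        raise ValueError("length mismatch between predicted and true values")
    return float(np.mean((t - p) ** 2))


# ---------------------------------------------------------------------------
# training and prediction

@dataclass
class TwinModel:
    """Trained Elder + Younger pair with their shared feature scaler."""

    elder: ElderNet
    youngers: dict            # target name -> YoungerNet
    scaler: FeatureScaler
    elder_cfg: ElderConfig
    younger_cfg: YoungerConfig
    elder_losses: list = field(default_factory=list)
    younger_losses: dict = field(default_factory=dict)
    phase_encoding: str = "code"  # {"code", "soft"}
    seed: int = 0


def _phase_input(model_or_enc, probs: np.ndarray) -> np.ndarray:
    """Encode the elder's output for the younger: hard code in [0,1] or the
    full softmax vector."""
    enc = model_or_enc if isinstance(model_or_enc, str) \
        else model_or_enc.phase_encoding
    if enc == "soft":
        return probs
    return (probs.argmax(axis=1) / 3.0)[:, None]


def train_twin(features: np.ndarray, phase_labels: np.ndarray,
               targets: dict, elder_cfg: ElderConfig | None = None,
               younger_cfg: YoungerConfig | None = None,
               phase_encoding: str = "code",
               teacher_forcing: bool = False) -> TwinModel:
    """Train the cascaded pair.

    ``features`` is the raw (n, 48) feature matrix (z-scored internally),
    ``phase_labels`` integer codes 0..3, ``targets`` a mapping of target
    name to an (n,) continuous vector (e.g. ``{"theta_left": ...}``).  The
    younger is trained, per target, on the elder's *predicted* phases so
    training matches deployment; ``teacher_forcing=True`` uses the ground
    truth labels instead.
    """
    elder_cfg = elder_cfg or ElderConfig()
    younger_cfg = younger_cfg or YoungerConfig()
    X = np.asarray(features, float)
    y = np.asarray(phase_labels, int)
    scaler = FeatureScaler()
    Xn = scaler.fit_transform(X)

    elder = build_elder(elder_cfg)
    elder_losses = train_network(
        elder, Xn, y, loss="softmax_ce", epochs=elder_cfg.epochs,
        lr=elder_cfg.lr, batch_size=elder_cfg.batch_size,
        lr_drop_factor=elder_cfg.lr_drop_factor,
        lr_drop_period=elder_cfg.lr_drop_period,
        shuffle=elder_cfg.shuffle_each_epoch, seed=elder_cfg.seed)

    if teacher_forcing:
        probs = np.eye(4)[y]
    else:
        probs = elder.predict_proba(Xn)
    pin = _phase_input(phase_encoding, probs)
    Xy = np.hstack([Xn, pin])

    youngers, younger_losses = {}, {}
    for k, (name, target) in enumerate(targets.items()):
        cfg = YoungerConfig(**{**younger_cfg.__dict__,
                               "seed": younger_cfg.seed + 1000 * k})
        net = build_younger(cfg, input_dim=Xy.shape[1])
        younger_losses[name] = fit_younger_head(net, Xy, target, cfg)
        youngers[name] = net

    return TwinModel(elder=elder, youngers=youngers, scaler=scaler,
                     elder_cfg=elder_cfg, younger_cfg=younger_cfg,
                     elder_losses=elder_losses, younger_losses=younger_losses,
                     phase_encoding=phase_encoding, seed=elder_cfg.seed)


def predict_dual(model: TwinModel, features: np.ndarray):
    """(phase probabilities, hard phase codes, {target: predictions})."""
    if model.scaler.mean_ is None:
        raise RuntimeError("model has no fitted normalization statistics")
    Xn = model.scaler.transform(np.asarray(features, float))
    probs = model.elder.predict_proba(Xn)
    labels = probs.argmax(axis=1)
    Xy = np.hstack([Xn, _phase_input(model, probs)])
    angles = {name: net.predict(Xy) for name, net in model.youngers.items()}
    return probs, labels, angles


# ---------------------------------------------------------------------------
# statsmodels-style surface

class TwinBrotherModel:
    """Dual-task gait model built from a feature matrix.

    Parameters
    ----------
    features : (n, 48) array
        Raw time-domain EMG features (z-scored internally during fit).
    phase : (n,) array of str or int
        Gait-phase labels (NDS/GFS/WDS/FLS or codes 0..3).
    targets : mapping of name -> (n,) array
        Continuous regression targets (hip angles, phase percentage).
    """

    def __init__(self, features, phase, targets,
                 elder_config: ElderConfig | None = None,
                 younger_config: YoungerConfig | None = None) -> None:
        self.features = np.asarray(features, float)
        phase = np.asarray(phase)
        if phase.dtype.kind in "USO":
            phase = np.array([PHASES.index(str(p)) for p in phase])
        self.phase = phase.astype(int)
        self.targets = {k: np.asarray(v, float) for k, v in targets.items()}
        self.elder_config = elder_config or ElderConfig()
        self.younger_config = younger_config or YoungerConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       target_cols: tuple = ("theta_left_deg",
                                             "theta_right_deg"),
                       **kwargs) -> "TwinBrotherModel":
        """Build from the feature table written by the featurizer."""
        feats = df[feature_columns()].to_numpy()
        targets = {c: df[c].to_numpy() for c in target_cols}
        return cls(feats, df["phase"].to_numpy(), targets, **kwargs)

    def fit(self, epochs: int | None = None, seed: int | None = None,
            **train_kwargs) -> "TwinResults":
        ecfg, ycfg = self.elder_config, self.younger_config
        if epochs is not None:
            ecfg = ElderConfig(**{**ecfg.__dict__, "epochs": epochs})
            ycfg = YoungerConfig(**{**ycfg.__dict__, "epochs": epochs})
        if seed is not None:
            ecfg = ElderConfig(**{**ecfg.__dict__, "seed": seed})
            ycfg = YoungerConfig(**{**ycfg.__dict__, "seed": seed})
        model = train_twin(self.features, self.phase, self.targets,
                           elder_cfg=ecfg, younger_cfg=ycfg, **train_kwargs)
        return TwinResults(self, model)


class TwinResults:
    """Fit results: trained parameters, losses, and evaluation helpers."""

    def __init__(self, model_spec: TwinBrotherModel, fitted: TwinModel) -> None:
        self.model = model_spec
        self.fitted = fitted
        self.elder_losses = fitted.elder_losses
        self.younger_losses = fitted.younger_losses

    def predict(self, features=None):
        feats = self.model.features if features is None else features
        return predict_dual(self.fitted, feats)

    def evaluate(self, features=None, phase=None, targets=None) -> dict:
        """Accuracy / per-phase metrics / RMSE / R2 on the given data."""
        from .evaluation import confusion_and_scores, r_squared, rmse

        feats = self.model.features if features is None else features
        true_phase = self.model.phase if phase is None else np.asarray(phase)
        tgts = self.model.targets if targets is None else targets
        probs, labels, angles = self.predict(feats)
        cm, acc = confusion_and_scores(true_phase, labels)
        out = {"accuracy": acc, "confusion": cm}
        for name, pred in angles.items():
            if name in tgts:
                out[f"rmse_{name}"] = rmse(tgts[name], pred)
                out[f"r2_{name}"] = r_squared(tgts[name], pred)
        return out

    def summary(self) -> str:
        ev = self.evaluate()
        lines = [
            "Twin Brother dual-task model",
            "=" * 46,
            f"samples:            {len(self.model.features)}",
            f"elder epochs:       {self.fitted.elder_cfg.epochs}"
            f"   final CE loss: {self.elder_losses[-1]:.4f}",
            f"training accuracy:  {ev['accuracy']:.4f}",
        ]
        for name in self.fitted.youngers:
            lines.append(
                f"{name}: RMSE {ev[f'rmse_{name}']:.4f}"
                f"   R2 {ev[f'r2_{name}']:.4f}"
                f"   final MSE loss {self.younger_losses[name][-1]:.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# checkpointing

def save_model(model: TwinModel, path: str | Path) -> Path:
    """Serialize parameters, configs, and scaler statistics to one archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {"scaler_mean": model.scaler.mean_,
              "scaler_scale": model.scaler.scale_}
    for i, p in enumerate(model.elder.params()):
        arrays[f"elder_{i}"] = p.v
    for name, net in model.youngers.items():
        for i, p in enumerate(net.params()):
            arrays[f"younger_{name}_{i}"] = p.v
        arrays[f"younger_{name}_tstats"] = np.array([net.target_mean,
                                                     net.target_scale])
    import json
    meta = {"schema": 1,
            "elder_cfg": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in model.elder_cfg.__dict__.items()},
            "younger_cfg": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in model.younger_cfg.__dict__.items()},
            "targets": list(model.youngers),
            "phase_encoding": model.phase_encoding,
            "seed": model.seed}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_model(path: str | Path) -> TwinModel:
    import json
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        ecfg_d = dict(meta["elder_cfg"])
        ecfg_d["kernel"] = tuple(ecfg_d["kernel"])
        ecfg = ElderConfig(**ecfg_d)
        ycfg_d = dict(meta["younger_cfg"])
        ycfg_d["hidden"] = tuple(ycfg_d["hidden"])
        ycfg = YoungerConfig(**ycfg_d)
        elder = build_elder(ecfg)
        for i, p in enumerate(elder.params()):
            p.v[...] = data[f"elder_{i}"]
        in_dim = 48 + (4 if meta["phase_encoding"] == "soft" else 1)
        youngers = {}
        for name in meta["targets"]:
            net = build_younger(ycfg, input_dim=in_dim)
            for i, p in enumerate(net.params()):
                p.v[...] = data[f"younger_{name}_{i}"]
            net.target_mean, net.target_scale = data[
                f"younger_{name}_tstats"]
            youngers[name] = net
        scaler = FeatureScaler()
        scaler.mean_ = data["scaler_mean"]
        scaler.scale_ = data["scaler_scale"]
    return TwinModel(elder=elder, youngers=youngers, scaler=scaler,
                     elder_cfg=ecfg, younger_cfg=ycfg,
                     phase_encoding=meta["phase_encoding"],
                     seed=meta["seed"])
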