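"""Dense-block 3-D U-Net dose prediction and the four input arms.

The network is an encoder--decoder over 3-D patches: at each level a
*dense block* (repeated ReLU -> 3x3x3 conv -> batch norm -> concatenate,
a fixed growth of channels per layer), 2x2x2 max-pool downsampling,
symmetric 2x2x2 transposed-convolution upsampling with skip
concatenation, and a single-channel linear 1x1x1 output head.  The
clinical-scale configuration is 4 levels, growth 16, deconvolution at 128
channels, 96x96x32 patches; every size scales down for desk-scale runs.

Training minimizes the voxel-wise mean squared error between predicted
and reference dose (both normalized by the prescription) with Adam and
an exponentially decaying learning rate; the retained checkpoint is the
epoch with the best *training* loss among validated epochs, mirroring
small-validation-set model selection.

Input arms (the ablation axis): TB (target + beam matrix), TBR (target
with halo rings + beam), CT+TB and CT+TBR.  All arms share one fixed
3-channel input head; two-channel arms zero-fill the unused channel, so
checkpoints are structurally compatible across arms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .grid import StructureRole, VolumeGrid
from .rtio import CaseBundle

__all__ = [
    "ARMS",
    "ExperimentConfig",
    "NetConfig",
    "TrainingCase",
    "assemble_channels",
    "sample_patches",
    "DenseUNet",
    "build_network",
    "DoseUNetRegressor",
    "save_checkpoint",
    "load_checkpoint",
]

ARMS = ("TB", "TBR", "CT+TB", "CT+TBR")

#: Channel semantics per arm; ZERO marks the padded unused channel.
_ARM_CHANNELS: Dict[str, Tuple[str, str, str]] = {
    "TB": ("TARGET", "BEAM", "ZERO"),
    "TBR": ("TARGET_RINGS", "BEAM", "ZERO"),
    "CT+TB": ("CT", "TARGET", "BEAM"),
    "CT+TBR": ("CT", "TARGET_RINGS", "BEAM"),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """One input-configuration arm and its channel assembly order."""

    arm: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")

    @property
    def channels(self) -> Tuple[str, str, str]:
        return _ARM_CHANNELS[self.arm]

    @property
    def needs_rings(self) -> bool:
        return "TARGET_RINGS" in self.channels

    @property
    def needs_ct(self) -> bool:
        return "CT" in self.channels


@dataclass
class NetConfig:
    """Architecture and training hyperparameters.

    The defaults are the clinical-scale configuration; use
    :meth:`tiny` for the desk-scale variant used throughout the tests.
    ``patch_shape`` must be divisible by ``2**levels`` on every axis.
    """

    levels: int = 4
    growth: int = 16
    dense_layers: int = 3
    deconv_channels: int = 128
    patch_shape: Tuple[int, int, int] = (96, 96, 32)
    batch_size: int = 2
    epochs: int = 30
    patches_per_case: int = 100
    lr_init: float = 1e-4
    lr_final: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        f = 2**self.levels
        if any(s % f != 0 for s in self.patch_shape):
            raise ValueError(
                f"patch shape {self.patch_shape} not divisible by 2^levels={f}"
            )
        for name in ("levels", "growth", "dense_layers", "deconv_channels",
                     "batch_size", "epochs", "patches_per_case"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def tiny(cls, **overrides) -> "NetConfig":
        """Desk-scale configuration: 2 levels, growth 4, 32x32x16 patches."""
        base = dict(
            levels=2, growth=4, dense_layers=2, deconv_channels=8,
            patch_shape=(32, 32, 16), batch_size=2, epochs=2,
            patches_per_case=60, lr_init=3e-3, lr_final=3e-4,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainingCase:
    """One normalized (channels, ground-truth) example on its grid."""

    case_id: str
    channels: np.ndarray  # (3, nx, ny, nz), all values in [0, 1]
    truth: Optional[np.ndarray]  # dose / prescription, or None at inference
    prescription: float
    grid: VolumeGrid
    target: np.ndarray
    arm: str

    def __post_init__(self) -> None:
        if self.channels.shape[0] != 3:
            raise ValueError("expected exactly 3 input channels")
        if self.channels.min() < -1e-6 or self.channels.max() > 1 + 1e-6:
            raise ValueError("channel values must lie in [0, 1]")
        if self.truth is not None and self.truth.min() < 0:
            raise ValueError("ground-truth dose must be nonnegative")


def _ring_composite(structures) -> np.ndarray:
    """Target + halo rings as one graded channel: target 1, rings fading."""
    ring_names = structures.names_with_role(StructureRole.RING)
    if not ring_names:
        raise ValueError("arm requires halo rings but the case has none")
    out = structures.target.astype(np.float32)
    n = len(ring_names)
    for i, name in enumerate(sorted(ring_names), start=1):
        out = np.maximum(out, structures.masks[name] * np.float32((n - i + 1) / (n + 1)))
    return out


def assemble_channels(
    case: CaseBundle,
    beam_matrix: VolumeGrid,
    arm: str,
    case_id: str = "",
) -> TrainingCase:
    """Build the 3-channel network input for one case and arm.

    Normalizations (recorded once, applied everywhere): CT windowed to
    [-1000, 1000] HU and mapped to [0, 1]; target/ring masks as graded
    indicators; beam matrix min--max scaled per case; ground-truth dose
    divided by the prescription.
    """
    cfg = ExperimentConfig(arm)
    if not beam_matrix.same_geometry(case.ct):
        raise ValueError("beam matrix is not co-registered with the case")
    shape = case.ct.shape
    planes: List[np.ndarray] = []
    for ch in cfg.channels:
        if ch == "CT":
            planes.append(((np.clip(case.ct.values, -1000, 1000) + 1000) / 2000).astype(np.float32))
        elif ch == "TARGET":
            planes.append(case.structures.target.astype(np.float32))
        elif ch == "TARGET_RINGS":
            planes.append(_ring_composite(case.structures))
        elif ch == "BEAM":
            bm = beam_matrix.values.astype(np.float32)
            top = float(bm.max())
            planes.append(bm / top if top > 0 else bm)
        else:  # ZERO padding channel
            planes.append(np.zeros(shape, dtype=np.float32))
    rx = case.plan.prescription_dose if case.plan is not None else 1.0
    truth = None
    if case.dose is not None:
        truth = (case.dose.values / rx).astype(np.float32)
    return TrainingCase(
        case_id=case_id,
        channels=np.stack(planes),
        truth=truth,
        prescription=float(rx),
        grid=case.ct,
        target=case.structures.target,
        arm=arm,
    )


def sample_patches(
    case: TrainingCase,
    n: int,
    patch_shape: Tuple[int, int, int],
    seed: int,
    target_bias: float = 0.5,
) -> np.ndarray:
    """Deterministic patch-corner sampling, biased towards the target.

    Corners are uniform over valid positions, except that a
    ``target_bias`` fraction of patches is centered on a random target
    voxel (clipped to valid corners): uniform sampling over a mostly
    empty head volume would starve the small-target signal.
    Returns ``(n, 3)`` integer corners, every patch fully inside.
    """
    shape = np.array(case.grid.shape)
    patch = np.array(patch_shape)
    if np.any(shape < patch):
        raise ValueError(f"volume {tuple(shape)} smaller than patch {tuple(patch)}")
    rng = np.random.default_rng(seed)
    hi = shape - patch  # inclusive upper corner
    corners = rng.integers(0, hi + 1, size=(n, 3))
    n_bias = int(round(n * target_bias))
    tvox = np.argwhere(case.target)
    if n_bias and tvox.size:
        picks = tvox[rng.integers(0, tvox.shape[0], size=n_bias)]
        centered = np.clip(picks - patch // 2, 0, hi)
        corners[:n_bias] = centered
    return corners


class _DenseBlock:
    """ReLU -> 3x3x3 conv -> batch norm -> concatenate, repeated."""

    def __init__(self, c_in: int, growth: int, n_layers: int, rng: np.random.Generator):
        self.layers = []
        c = c_in
        for _ in range(n_layers):
            self.layers.append((nn.ReLU(), nn.Conv3d(c, growth, 3, rng), nn.BatchNorm3d(growth)))
            c += growth
        self.c_out = c
        self._widths: List[int] = []

    def params(self) -> List[nn.Param]:
        out = []
        for relu, conv, bn in self.layers:
            out += conv.params() + bn.params()
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._widths = []
        for relu, conv, bn in self.layers:
            self._widths.append(x.shape[-1])
            h = bn.forward(conv.forward(relu.forward(x, train), train), train)
            x = np.concatenate([x, h], axis=-1)
        return x

    def backward(self, gx: np.ndarray) -> np.ndarray:
        for (relu, conv, bn), c_prev in zip(reversed(self.layers), reversed(self._widths)):
            g_prev, g_new = gx[..., :c_prev], gx[..., c_prev:]
            g = relu.backward(conv.backward(bn.backward(g_new)))
            gx = g_prev + g
        return gx


class DenseUNet:
    """The dense-block encoder--decoder with a linear single-channel head."""

    def __init__(self, cfg: NetConfig, in_channels: int = 3):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.enc: List[_DenseBlock] = []
        self.pools: List[nn.MaxPool2] = []
        c = in_channels
        enc_out = []
        for _ in range(cfg.levels):
            block = _DenseBlock(c, cfg.growth, cfg.dense_layers, rng)
            self.enc.append(block)
            enc_out.append(block.c_out)
            self.pools.append(nn.MaxPool2())
            c = block.c_out
        self.bottleneck = _DenseBlock(c, cfg.growth, cfg.dense_layers, rng)
        c = self.bottleneck.c_out
        self.deconvs: List[nn.Deconv2] = []
        self.dec: List[_DenseBlock] = []
        for lvl in reversed(range(cfg.levels)):
            self.deconvs.append(nn.Deconv2(c, cfg.deconv_channels, rng))
            block = _DenseBlock(cfg.deconv_channels + enc_out[lvl], cfg.growth, cfg.dense_layers, rng)
            self.dec.append(block)
            c = block.c_out
        self.head = nn.Conv3d(c, 1, 1, rng)
        self._skip_widths = enc_out

    def params(self) -> List[nn.Param]:
        out: List[nn.Param] = []
        for b in self.enc:
            out += b.params()
        out += self.bottleneck.params()
        for d, b in zip(self.deconvs, self.dec):
            out += d.params() + b.params()
        out += self.head.params()
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for deconv, block, skip in zip(self.deconvs, self.dec, reversed(skips)):
            x = deconv.forward(x, train)
            x = np.concatenate([x, skip], axis=-1)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, gout: np.ndarray) -> None:
        g = self.head.backward(gout)
        g_skips: List[np.ndarray] = []
        dcfg = self.cfg.deconv_channels
        for deconv, block in zip(reversed(self.deconvs), reversed(self.dec)):
            g = block.backward(g)
            g_skips.append(g[..., dcfg:])
            g = deconv.backward(g[..., :dcfg])
        g = self.bottleneck.backward(g)
        # g_skips is collected in level order 0..levels-1; walk it backwards
        for block, pool, g_skip in zip(reversed(self.enc), reversed(self.pools), reversed(g_skips)):
            g = pool.backward(g) + g_skip
            g = block.backward(g)

    def state(self) -> List[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        for b in self._bn_layers():
            arrays += [b.running_mean.copy(), b.running_var.copy()]
        return arrays

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrays[: len(ps)]):
            p.value = a.astype(np.float32).copy()
        rest = list(arrays[len(ps):])
        for b in self._bn_layers():
            b.running_mean = rest.pop(0).astype(np.float32).copy()
            b.running_var = rest.pop(0).astype(np.float32).copy()

    def _bn_layers(self) -> List[nn.BatchNorm3d]:
        out = []
        for block in [*self.enc, self.bottleneck, *self.dec]:
            out += [bn for _, _, bn in block.layers]
        return out


def build_network(cfg: NetConfig, in_channels: int = 3) -> DenseUNet:
    """Construct the network; raises at once on patch/levels mismatch."""
    return DenseUNet(cfg, in_channels)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


def _cosine_window(shape: Tuple[int, int, int]) -> np.ndarray:
    ws = [np.hanning(s + 2)[1:-1] for s in shape]
    w = ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]
    return (w + 1e-4).astype(np.float32)


class DoseUNetRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn-style dose predictor wrapping the dense 3-D U-Net.

    ``fit`` takes lists of :class:`TrainingCase` (all of the same arm),
    ``predict`` returns a Gy :class:`~cyberbeam.grid.VolumeGrid` for one
    case via overlapping sliding-window inference with cosine blending.

    Fitted attributes: ``net_``, ``loss_log_`` (per-epoch train/val MSE),
    ``best_epoch_``, ``n_parameters_``.
    """

    def __init__(
        self,
        arm: str = "CT+TB",
        levels: int = 2,
        growth: int = 4,
        dense_layers: int = 2,
        deconv_channels: int = 8,
        patch_shape: Tuple[int, int, int] = (32, 32, 16),
        batch_size: int = 2,
        epochs: int = 2,
        patches_per_case: int = 60,
        lr_init: float = 3e-3,
        lr_final: float = 3e-4,
        target_bias: float = 0.5,
        seed: int = 0,
    ):
        self.arm = arm
        self.levels = levels
        self.growth = growth
        self.dense_layers = dense_layers
        self.deconv_channels = deconv_channels
        self.patch_shape = patch_shape
        self.batch_size = batch_size
        self.epochs = epochs
        self.patches_per_case = patches_per_case
        self.lr_init = lr_init
        self.lr_final = lr_final
        self.target_bias = target_bias
        self.seed = seed

    # -- internals ----------------------------------------------------------

    def _net_config(self) -> NetConfig:
        return NetConfig(
            levels=self.levels,
            growth=self.growth,
            dense_layers=self.dense_layers,
            deconv_channels=self.deconv_channels,
            patch_shape=tuple(self.patch_shape),
            batch_size=self.batch_size,
            epochs=self.epochs,
            patches_per_case=self.patches_per_case,
            lr_init=self.lr_init,
            lr_final=self.lr_final,
            seed=self.seed,
        )

    @staticmethod
    def _extract(case: TrainingCase, corner: np.ndarray, patch: np.ndarray):
        sl = tuple(slice(int(c), int(c + p)) for c, p in zip(corner, patch))
        x = np.moveaxis(case.channels[(slice(None),) + sl], 0, -1)
        y = case.truth[sl]
        return x, y

    def case_loss(self, case: TrainingCase, n_patches: int = 32, seed: int = 0) -> float:
        """Mean patch MSE of the current network on one case (eval mode)."""
        patch = np.array(self.patch_shape)
        corners = sample_patches(case, n_patches, tuple(patch), seed, self.target_bias)
        losses = []
        for corner in corners:
            x, y = self._extract(case, corner, patch)
            pred = self.net_.forward(x[None], train=False)[0, ..., 0]
            losses.append(float(np.mean((pred - y) ** 2)))
        return float(np.mean(losses))

    # -- estimator API ------------------------------------------------------

    def fit(self, cases: Sequence[TrainingCase], val_cases: Sequence[TrainingCase] = ()):
        """Train on ``cases``; log per-epoch train/val loss; keep the best.

        The retained state is the epoch with the lowest training loss
        among epochs whose validation loss is finite ("passed
        validation"); training aborts with a diagnostic on divergence.
        """
        if not cases:
            raise ValueError("need at least one training case")
        for c in cases:
            if c.arm != self.arm:
                raise ValueError(f"case {c.case_id!r} was assembled for arm {c.arm!r}, not {self.arm!r}")
            if c.truth is None:
                raise ValueError(f"case {c.case_id!r} has no ground-truth dose")
        cfg = self._net_config()
        self.net_ = build_network(cfg)
        self.n_parameters_ = self.net_.n_parameters
        opt = nn.Adam(self.net_.params())
        rng = np.random.default_rng(cfg.seed)
        patch = np.array(cfg.patch_shape)

        steps_per_epoch = max(1, (len(cases) * cfg.patches_per_case) // cfg.batch_size)
        total_steps = cfg.epochs * steps_per_epoch
        decay = (cfg.lr_final / cfg.lr_init) ** (1.0 / max(1, total_steps - 1))

        log = []
        best = (np.inf, None, -1)
        step = 0
        for epoch in range(cfg.epochs):
            order = []
            for ci, case in enumerate(cases):
                corners = sample_patches(
                    case, cfg.patches_per_case, tuple(patch),
                    seed=int(rng.integers(2**31)), target_bias=self.target_bias,
                )
                order += [(ci, corner) for corner in corners]
            perm = rng.permutation(len(order))
            epoch_losses = []
            for start in range(0, len(perm) - cfg.batch_size + 1, cfg.batch_size):
                xs, ys = [], []
                for idx in perm[start: start + cfg.batch_size]:
                    ci, corner = order[idx]
                    x, y = self._extract(cases[ci], corner, patch)
                    xs.append(x)
                    ys.append(y)
                xb = np.stack(xs)
                yb = np.stack(ys)[..., None]
                lr = cfg.lr_init * decay**step
                pred = self.net_.forward(xb, train=True)
                diff = pred - yb
                loss = float(np.mean(diff**2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (loss={loss}) at epoch {epoch}, step {step}"
                    )
                epoch_losses.append(loss)
                opt.zero_grad()
                self.net_.backward((2.0 / diff.size) * diff.astype(np.float32))
                opt.step(lr)
                step += 1
            train_loss = float(np.mean(epoch_losses))
            val_loss = (
                float(np.mean([self.case_loss(v, seed=cfg.seed) for v in val_cases]))
                if val_cases else np.nan
            )
            log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
            validated = np.isfinite(val_loss) or not val_cases
            if validated and train_loss < best[0]:
                best = (train_loss, self.net_.state(), epoch)
        if best[1] is not None:
            self.net_.load_state(best[1])
        self.best_epoch_ = best[2]
        self.loss_log_ = pd.DataFrame(log)
        return self

    def predict(self, case: TrainingCase) -> VolumeGrid:
        """Sliding-window inference (50 % overlap, cosine blending) in Gy."""
        if not hasattr(self, "net_"):
            raise RuntimeError("predictor is not fitted")
        if case.arm != self.arm:
            raise ValueError(f"case arm {case.arm!r} does not match model arm {self.arm!r}")
        shape = np.array(case.grid.shape)
        patch = np.array(self.patch_shape)
        if np.any(shape < patch):
            raise ValueError("case volume smaller than the inference patch")
        stride = np.maximum(1, patch // 2)
        starts = [
            sorted(set(list(range(0, int(s - p), int(st))) + [int(s - p)]))
            for s, p, st in zip(shape, patch, stride)
        ]
        acc = np.zeros(tuple(shape), dtype=np.float64)
        wacc = np.zeros(tuple(shape), dtype=np.float64)
        window = _cosine_window(tuple(patch))
        for i in starts[0]:
            for j in starts[1]:
                for k in starts[2]:
                    sl = (slice(i, i + patch[0]), slice(j, j + patch[1]), slice(k, k + patch[2]))
                    x = np.moveaxis(case.channels[(slice(None),) + sl], 0, -1)
                    pred = self.net_.forward(x[None], train=False)[0, ..., 0]
                    acc[sl] += pred * window
                    wacc[sl] += window
        out = np.clip(acc / wacc, 0.0, None) * case.prescription
        return case.grid.with_values(out.astype(np.float32))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: DoseUNetRegressor, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "config.json").write_text(json.dumps(model.get_params(), indent=2))
    np.savez_compressed(
        directory / "weights.npz",
        **{f"arr_{i:04d}": a for i, a in enumerate(model.net_.state())},
    )
    model.loss_log_.to_csv(directory / "loss_log.csv", index=False)


def load_checkpoint(directory) -> DoseUNetRegressor:
    directory = Path(directory)
    params = json.loads((directory / "config.json").read_text())
    if isinstance(params.get("patch_shape"), list):
        params["patch_shape"] = tuple(params["patch_shape"])
    model = DoseUNetRegressor(**params)
    model.net_ = build_network(model._net_config())
    model.n_parameters_ = model.net_.n_parameters
    data = np.load(directory / "weights.npz")
    model.net_.load_state([data[k] for k in sorted(data.files)])
    model.loss_log_ = pd.read_csv(directory / "loss_log.csv")
    model.best_epoch_ = int(model.loss_log_["train_loss"].idxmin()) if len(model.loss_log_) else -1
    return model
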