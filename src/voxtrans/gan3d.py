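"""3D pix2pix: u-net generator, PatchGAN discriminator, cGAN + L1 training.

The generator is an encoder-decoder with skip concatenations: stride-2
convolutions of size k^3 halve resolution per level while filters double
from the base count f (capped at 8f); the decoder mirrors with stride-2
transpose convolutions and ends in tanh, so a 1-channel cube in [-1, 1]
maps to a 1-channel cube of identical shape in (-1, 1).  The conditional
discriminator scores the channel-concatenation of condition (MR) and
candidate (CT or synthetic) on a coarse grid of sigmoid outputs, each
judging only its own receptive field.

Named production presets: k4_f80, k6_f60, k8_f30 (kernel size / base
filters); stride is (2, 2, 2) everywhere and batch size is 1.  Training
minimizes the non-saturating cGAN loss plus lambda * L1 (lambda = 100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .augmentation import RotationSchedule, rotate_pair
from .volume_io import Volume

__all__ = ["GeneratorConfig", "PRESETS", "UNetGenerator3D", "PatchDiscriminator3D",
           "ModelEntry", "ModelBundle", "build_generator", "build_discriminator",
           "cgan_losses", "train_model", "predict", "Pix2PixTranslator"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture hyperparameters of one translation model.

    kernel_size: cubic convolution kernel side, voxels.
    base_filters: filter count of the first encoder level; doubles per level,
        capped at ``filter_cap * base_filters``.
    depth: number of stride-2 encoder levels; ``None`` picks enough levels to
        reach a 2^3-4^3 bottleneck (6 for 128^3 inputs).
    dropout: decoder dropout rate, the stochastic "noise" input z.
    """

    kernel_size: int = 4
    base_filters: int = 80
    depth: int | None = None
    dropout: float = 0.5
    filter_cap: int = 8

    def resolve_depth(self, side: int) -> int:
        if self.depth is not None:
            d = self.depth
        else:
            d = max(2, min(6, int(math.log2(side)) - 1))
        if side % (2 ** d) != 0:
            raise ValueError(f"input side {side} not divisible by 2^{d}")
        return d

    def encoder_channels(self, depth: int) -> list[int]:
        return [self.base_filters * min(2 ** i, self.filter_cap) for i in range(depth)]

    def num_parameters(self, side: int = 128) -> int:
        """Analytic trainable-parameter count of the generator (no allocation)."""
        k3 = self.kernel_size ** 3
        depth = self.resolve_depth(side)
        c = self.encoder_channels(depth)
        n = 0
        prev = 1
        for i, ci in enumerate(c):          # encoder convs (+ IN except first)
            n += prev * ci * k3 + ci
            if i > 0:
                n += 2 * ci
            prev = ci
        for j in range(depth - 1, 0, -1):   # decoder transpose convs + IN
            cin = c[j] if j == depth - 1 else 2 * c[j]
            cout = c[j - 1]
            n += cin * cout * k3 + cout + 2 * cout
        n += (2 * c[0]) * 1 * k3 + 1        # final transpose conv to 1 channel
        return n


PRESETS: dict[str, GeneratorConfig] = {
    "k4_f80": GeneratorConfig(kernel_size=4, base_filters=80),
    "k6_f60": GeneratorConfig(kernel_size=6, base_filters=60),
    "k8_f30": GeneratorConfig(kernel_size=8, base_filters=30),
}


def _as_array(x) -> np.ndarray:
    if isinstance(x, Volume):
        x = x.data
    return np.asarray(x, dtype=np.float32)


class UNetGenerator3D:
    """U-net with manual backprop; channel-first, batch size 1."""

    def __init__(self, cfg: GeneratorConfig, input_side: int, rng=None):
        self.cfg = cfg
        self.input_side = int(input_side)
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        depth = cfg.resolve_depth(self.input_side)
        if depth < 2:
            raise ValueError("generator needs depth >= 2")
        self.depth = depth
        k = cfg.kernel_size
        c = cfg.encoder_channels(depth)
        self.channels = c
        self.enc = []
        prev = 1
        for i, ci in enumerate(c):
            conv = nn.Conv3d(prev, ci, k, stride=2, rng=rng)
            norm = nn.InstanceNorm3d(ci) if i > 0 else None
            self.enc.append((conv, norm, nn.LeakyReLU(0.2)))
            prev = ci
        self.dec = []
        n_drop = min(3, depth - 1)
        for idx, j in enumerate(range(depth - 1, 0, -1)):
            cin = c[j] if j == depth - 1 else 2 * c[j]
            convt = nn.ConvTranspose3d(cin, c[j - 1], k, rng=rng)
            norm = nn.InstanceNorm3d(c[j - 1])
            drop = nn.Dropout(cfg.dropout, rng=np.random.default_rng(rng.integers(2 ** 31))) \
                if idx < n_drop and cfg.dropout > 0 else None
            self.dec.append((convt, norm, drop, nn.ReLU()))
        self.final = nn.ConvTranspose3d(2 * c[0], 1, k, rng=rng)
        self.out_act = nn.Tanh()

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[0] != 1:
            raise ValueError(f"expected (1, d, h, w) input, got {x.shape}")
        for s in x.shape[1:]:
            if s % (2 ** self.depth) != 0:
                raise ValueError(
                    f"input side {s} not divisible by 2^{self.depth}")
        skips = []
        h = x
        for conv, norm, act in self.enc:
            h = conv.forward(h, train)
            if norm is not None:
                h = norm.forward(h, train)
            h = act.forward(h, train)
            skips.append(h)
        self._skip_channels = [s.shape[0] for s in skips]
        h = skips[-1]
        for idx, (convt, norm, drop, act) in enumerate(self.dec):
            level = self.depth - 1 - idx
            inp = h if idx == 0 else np.concatenate([h, skips[level]], axis=0)
            h = convt.forward(inp, train)
            h = norm.forward(h, train)
            if drop is not None:
                h = drop.forward(h, train)
            h = act.forward(h, train)
        inp = np.concatenate([h, skips[0]], axis=0)
        return self.out_act.forward(self.final.forward(inp, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self.final.backward(self.out_act.backward(dy))
        c0 = self.channels[0]
        g_h, skip_grads = g[:c0], {0: g[c0:]}
        for idx in range(len(self.dec) - 1, -1, -1):
            convt, norm, drop, act = self.dec[idx]
            level = self.depth - 1 - idx
            g_h = act.backward(g_h)
            if drop is not None:
                g_h = drop.backward(g_h)
            g_h = norm.backward(g_h)
            g_in = convt.backward(g_h)
            if idx == 0:
                skip_grads[self.depth - 1] = g_in
            else:
                ch = self.channels[level]
                g_h = g_in[:ch]
                skip_grads[level] = g_in[ch:]
        g = skip_grads[self.depth - 1]
        for i in range(self.depth - 1, -1, -1):
            conv, norm, act = self.enc[i]
            g = act.backward(g)
            if norm is not None:
                g = norm.backward(g)
            g = conv.backward(g)
            if i > 0:
                g = g + skip_grads.get(i - 1, 0.0)
        return g

    def params(self):
        ps = []
        for conv, norm, _ in self.enc:
            ps += conv.params() + (norm.params() if norm else [])
        for convt, norm, drop, _ in self.dec:
            ps += convt.params() + norm.params()
        ps += self.final.params()
        return ps

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.params())


class PatchDiscriminator3D:
    """Conditional PatchGAN: 3 stride-2 k^3 conv levels, then a 1^3 conv to a
    single sigmoid score channel — an M^3 grid of probability-real scores."""

    def __init__(self, cfg: GeneratorConfig, rng=None):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        k, f = cfg.kernel_size, cfg.base_filters
        self.layers = [
            nn.Conv3d(2, f, k, stride=2, rng=rng), None, nn.LeakyReLU(0.2),
            nn.Conv3d(f, 2 * f, k, stride=2, rng=rng), nn.InstanceNorm3d(2 * f), nn.LeakyReLU(0.2),
            nn.Conv3d(2 * f, 4 * f, k, stride=2, rng=rng), nn.InstanceNorm3d(4 * f), nn.LeakyReLU(0.2),
            nn.Conv3d(4 * f, 1, 1, stride=1, pad=0, rng=rng), None, nn.Sigmoid(),
        ]

    def forward(self, condition: np.ndarray, candidate: np.ndarray,
                train: bool = True) -> np.ndarray:
        if condition.shape != candidate.shape:
            raise ValueError(
                f"condition {condition.shape} and candidate {candidate.shape} differ")
        h = np.concatenate([condition, candidate], axis=0)
        for layer in self.layers:
            if layer is not None:
                h = layer.forward(h, train)
        return h

    def backward(self, dy: np.ndarray):
        """Returns (grad_condition, grad_candidate)."""
        g = dy
        for layer in reversed(self.layers):
            if layer is not None:
                g = layer.backward(g)
        return g[:1], g[1:]

    def params(self):
        ps = []
        for layer in self.layers:
            if layer is not None:
                ps += layer.params()
        return ps


def build_generator(cfg: GeneratorConfig, input_side: int = 128,
                    seed: int | None = None) -> UNetGenerator3D:
    return UNetGenerator3D(cfg, input_side, rng=np.random.default_rng(seed))


def build_discriminator(cfg: GeneratorConfig, seed: int | None = None) -> PatchDiscriminator3D:
    return PatchDiscriminator3D(cfg, rng=np.random.default_rng(seed))


# -- losses ------------------------------------------------------------------

_EPS = 1e-7


def cgan_losses(d_real, d_fake, target, prediction, lam: float = 100.0):
    """Conditional-GAN losses at one training step (batch size 1).

    loss_D = -mean log D(c, x) - mean log(1 - D(c, G(c, z)))
    loss_G = -mean log D(c, G(c, z)) + lam * mean |x - G(c, z)|

    The generator term uses the non-saturating form; scores at exactly 0 or 1
    are clamped away from the log singularity by 1e-7.
    """
    d_real = np.clip(np.asarray(d_real, dtype=np.float64), _EPS, 1.0 - _EPS)
    d_fake = np.clip(np.asarray(d_fake, dtype=np.float64), _EPS, 1.0 - _EPS)
    target = _as_array(target).astype(np.float64)
    prediction = _as_array(prediction).astype(np.float64)
    if target.shape != prediction.shape:
        raise ValueError("target and prediction shapes differ")
    l1 = np.abs(target - prediction).mean()
    loss_d = float(-np.log(d_real).mean() - np.log1p(-d_fake).mean())
    loss_g = float(-np.log(d_fake).mean() + lam * l1)
    return loss_d, loss_g


# -- bundle bookkeeping ------------------------------------------------------

@dataclass
class ModelEntry:
    """One trained generator plus its observed output range and history."""

    generator: UNetGenerator3D
    config: GeneratorConfig
    output_range: tuple[float, float]
    history: list = field(default_factory=list)


class ModelBundle:
    """The (patch index, preset) -> trained model mapping.

    A complete bundle for full synthesis holds n_patches x n_presets entries
    (5 x 3 = 15 in the production configuration).
    """

    def __init__(self, n_patches: int = 5, presets=("k4_f80", "k6_f60", "k8_f30")):
        self.n_patches = n_patches
        self.presets = tuple(presets)
        self.entries: dict[tuple[int, str], ModelEntry] = {}

    def add(self, patch_index: int, preset: str, entry: ModelEntry) -> None:
        if not 1 <= patch_index <= self.n_patches:
            raise IndexError(f"patch index {patch_index} outside 1..{self.n_patches}")
        if preset not in self.presets:
            raise KeyError(f"unknown preset {preset!r}; bundle holds {self.presets}")
        self.entries[(patch_index, preset)] = entry

    def get(self, patch_index: int, preset: str) -> ModelEntry:
        return self.entries[(patch_index, preset)]

    def missing(self) -> list[tuple[int, str]]:
        return [(p, s) for p in range(1, self.n_patches + 1) for s in self.presets
                if (p, s) not in self.entries]

    @property
    def is_complete(self) -> bool:
        return not self.missing()

    def __len__(self) -> int:
        return len(self.entries)


# -- training ----------------------------------------------------------------

def _mean_mssim(gen: UNetGenerator3D, pairs) -> float:
    from .metrics import SsimParams, mssim

    side = min(pairs[0].mr.shape)
    win = 11 if side >= 11 else (side if side % 2 else side - 1)
    params = SsimParams(window_size=win)
    scores = []
    for pair in pairs:
        pred = gen.forward(_as_array(pair.mr.data)[None], train=False)[0]
        a = (np.asarray(pair.ct.data) + 1.0) / 2.0
        b = (pred.astype(np.float64) + 1.0) / 2.0
        scores.append(mssim(a, b, params=params, data_range=1.0))
    return float(np.mean(scores))


def train_model(dataset, cfg: GeneratorConfig, iterations: int,
                schedule: RotationSchedule | None = None,
                eval_every: int | None = None, seed: int = 0,
                test_dataset=None, lam: float = 100.0,
                lr: float = 2e-4, beta1: float = 0.5) -> ModelEntry:
    """Adversarial training of one patch model (batch size 1).

    One iteration consumes one subject pair; one epoch is one pass over the
    dataset.  If a rotation schedule is given, each epoch's pairs are rotated
    by that epoch's angle triple before use.  Every ``eval_every`` iterations
    the mean MSSIM against the training pairs (and ``test_dataset`` if given)
    is recorded in the history together with the current losses.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    side = dataset[0].mr.shape[0]
    rng = np.random.default_rng(seed)
    gen = UNetGenerator3D(cfg, side, rng=np.random.default_rng(rng.integers(2 ** 31)))
    disc = PatchDiscriminator3D(cfg, rng=np.random.default_rng(rng.integers(2 ** 31)))
    opt_g = nn.Adam(gen.params(), lr=lr, beta1=beta1)
    opt_d = nn.Adam(disc.params(), lr=lr, beta1=beta1)
    n = len(dataset)
    history: list[dict] = []
    rotated: list = list(dataset)
    cur_epoch = -1

    for it in range(iterations):
        epoch, idx = divmod(it, n)
        if schedule is not None and epoch != cur_epoch:
            angles = schedule.draw_angles(epoch)
            rotated = [None] * n
            cur_epoch = epoch
        if schedule is not None:
            if rotated[idx] is None:  # lazy: rotate only the pairs actually used
                rotated[idx] = rotate_pair(dataset[idx], angles)
            pair = rotated[idx]
        else:
            pair = dataset[idx]
        c = _as_array(pair.mr.data)[None]
        x = _as_array(pair.ct.data)[None]

        fake = gen.forward(c, train=True)

        # discriminator update
        d_real = disc.forward(c, x, train=True)
        m = d_real.size
        disc.backward(-1.0 / (m * np.clip(d_real, _EPS, None)))
        d_fake = disc.forward(c, fake, train=True)
        disc.backward(1.0 / (m * np.clip(1.0 - d_fake, _EPS, None)))
        opt_d.step()
        opt_d.zero_grad()

        # generator update (non-saturating + lambda * L1)
        d_fake2 = disc.forward(c, fake, train=True)
        _, g_fake = disc.backward(-1.0 / (m * np.clip(d_fake2, _EPS, None)))
        g_fake = g_fake + lam * np.sign(fake - x) / fake.size
        gen.backward(g_fake.astype(np.float32))
        opt_g.step()
        opt_g.zero_grad()
        opt_d.zero_grad()  # discard D grads accumulated through the G pass

        loss_d, loss_g = cgan_losses(d_real, d_fake, x, fake, lam=lam)
        if not (np.isfinite(loss_d) and np.isfinite(loss_g)):
            raise RuntimeError(
                f"non-finite loss at iteration {it}: loss_D={loss_d}, loss_G={loss_g}, "
                f"|G(c)| max={np.abs(fake).max():.3g}")

        if eval_every and (it + 1) % eval_every == 0:
            rec = {"iteration": it + 1, "epoch": epoch,
                   "loss_D": loss_d, "loss_G": loss_g,
                   "train_mssim": _mean_mssim(gen, dataset)}
            if test_dataset:
                rec["test_mssim"] = _mean_mssim(gen, test_dataset)
            history.append(rec)

    lo, hi = np.inf, -np.inf
    for pair in dataset:
        pred = gen.forward(_as_array(pair.mr.data)[None], train=False)
        lo, hi = min(lo, float(pred.min())), max(hi, float(pred.max()))
    return ModelEntry(generator=gen, config=cfg, output_range=(lo, hi), history=history)


def predict(generator: UNetGenerator3D, mr_patch: Volume) -> Volume:
    """Deterministic inference (dropout inactive) on one MR patch."""
    arr = _as_array(mr_patch)
    out = generator.forward(arr[None], train=False)[0].astype(np.float64)
    if isinstance(mr_patch, Volume):
        return mr_patch.copy_with(data=out)
    return Volume(data=out)


# -- checkpointing -----------------------------------------------------------

def save_entry(entry: ModelEntry, path) -> None:
    """Checkpoint one trained model: weights + config + output range (npz)."""
    cfg = entry.config
    arrays = {f"param_{i}": p.data for i, p in enumerate(entry.generator.params())}
    np.savez_compressed(
        path, output_range=np.asarray(entry.output_range, dtype=np.float64),
        config=np.asarray([cfg.kernel_size, cfg.base_filters,
                           -1 if cfg.depth is None else cfg.depth,
                           cfg.dropout, cfg.filter_cap], dtype=np.float64),
        input_side=np.asarray(entry.generator.input_side), **arrays)


def load_entry(path) -> ModelEntry:
    """Inverse of :func:`save_entry` (history is not persisted)."""
    with np.load(path) as data:
        kernel, filters, depth, dropout, cap = data["config"]
        cfg = GeneratorConfig(kernel_size=int(kernel), base_filters=int(filters),
                              depth=None if depth < 0 else int(depth),
                              dropout=float(dropout), filter_cap=int(cap))
        gen = UNetGenerator3D(cfg, int(data["input_side"]),
                              rng=np.random.default_rng(0))
        params = gen.params()
        for i, p in enumerate(params):
            stored = data[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ValueError(f"checkpoint parameter {i} has shape "
                                 f"{stored.shape}, expected {p.data.shape}")
            p.data[...] = stored
        rng_lo, rng_hi = data["output_range"]
        return ModelEntry(generator=gen, config=cfg,
                          output_range=(float(rng_lo), float(rng_hi)))


# -- sklearn-style estimator -------------------------------------------------

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore
        pass


class Pix2PixTranslator(BaseEstimator):
    """Scikit-learn-style wrapper around one patch translation model.

    ``fit`` takes a list of preprocessed :class:`PairedSample` patches (MR is
    the condition, CT the target) and trains the adversarial pair; ``predict``
    maps an MR patch to a synthetic CT patch deterministically.

    Parameters mirror :func:`train_model`; fitted attributes are
    ``generator_``, ``history_``, ``output_range_`` and ``n_iter_``.
    """

    def __init__(self, kernel_size: int = 4, base_filters: int = 8,
                 depth: int | None = 3, dropout: float = 0.5,
                 iterations: int = 200, lam: float = 100.0, lr: float = 2e-4,
                 beta1: float = 0.5, eval_every: int | None = None,
                 augment: bool = True, seed: int = 0):
        self.kernel_size = kernel_size
        self.base_filters = base_filters
        self.depth = depth
        self.dropout = dropout
        self.iterations = iterations
        self.lam = lam
        self.lr = lr
        self.beta1 = beta1
        self.eval_every = eval_every
        self.augment = augment
        self.seed = seed

    def _config(self) -> GeneratorConfig:
        return GeneratorConfig(kernel_size=self.kernel_size,
                               base_filters=self.base_filters,
                               depth=self.depth, dropout=self.dropout)

    def fit(self, pairs, test_pairs=None) -> "Pix2PixTranslator":
        schedule = RotationSchedule(rng_seed=self.seed) if self.augment else None
        entry = train_model(list(pairs), self._config(), iterations=self.iterations,
                            schedule=schedule, eval_every=self.eval_every,
                            seed=self.seed, test_dataset=test_pairs,
                            lam=self.lam, lr=self.lr, beta1=self.beta1)
        self.generator_ = entry.generator
        self.history_ = entry.history
        self.output_range_ = entry.output_range
        self.n_iter_ = self.iterations
        return self

    def predict(self, mr_patch):
        if not hasattr(self, "generator_"):
            raise RuntimeError("estimator is not fitted")
        return predict(self.generator_, mr_patch)

    def to_entry(self) -> ModelEntry:
        return ModelEntry(generator=self.generator_, config=self._config(),
                          output_range=self.output_range_, history=self.history_)
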