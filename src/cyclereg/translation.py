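"""Cycle-adversarial CT <-> TEE image translation.

Two generators (CT->TEE-like and TEE->CT-like) are trained on *unpaired*
patch sets against two discriminators.  Each discriminator has a shared
5-layer convolutional trunk and two scalar heads:

* head D1 scores real vs. generated ("is this a real image?");
* head D2 scores the modality ("is this a TEE or a CT image?").

Both heads use a least-squares objective; the discriminative loss is

    E[(D1(real) - 1)^2] + E[D1(fake)^2]
        + alpha * (E[(D2(real) - 1)^2] + E[D2(fake)^2]),

with ``alpha`` balancing the realness and modality parts.  As printed in
the source formulation all four expectations range over the target domain,
which leaves the generated-sample terms unbound; here the real terms are
taken over real target-domain samples and the fake terms over translated
source-domain samples — the only consistent reading (see docs/methods.md).
Generators additionally minimize the L1 cycle-consistency loss between each
image and its round-trip reconstruction, weighted by ``lambda_cyc``.  D2 is
trained on real and generated images with equal weight.

Training is plain Adam (batch size 2, learning rate 2e-4 by default), fully
seeded and bit-reproducible; checkpoints round-trip exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field as dc_field
from typing import Dict, List, Tuple

import numpy as np

from . import nn
from .grids import ImageGrid
from .io import PatchSet

__all__ = ["GeneratorSpec", "DiscriminatorSpec", "TrainConfig",
           "TranslationModel", "Generator", "TwoHeadDiscriminator",
           "build_generator", "build_discriminator", "adversarial_loss",
           "cycle_loss", "train_cyclegan", "translate",
           "save_model", "load_model"]


@dataclass
class GeneratorSpec:
    """7 convolution-BatchNorm-ReLU stages: encoder(3) with stride-2
    downsampling, one residual stage, decoder(3) with nearest-neighbour
    upsampling and a tanh output mapping to [-1, 1]."""

    n_layers: int = 7
    channels: Tuple[int, int, int] = (32, 64, 64)
    kernel: int = 3

    def __post_init__(self):
        if self.n_layers != 7:
            raise ValueError("the generator architecture is fixed at 7 conv stages")
        if len(self.channels) != 3:
            raise ValueError("channels must list the three encoder widths")


@dataclass
class DiscriminatorSpec:
    """5 convolution-BatchNorm-ReLU stages: a shared 4-layer trunk and two
    parallel scalar-map heads (D1 realness, D2 modality)."""

    n_layers: int = 5
    channels: Tuple[int, int, int, int] = (16, 32, 64, 64)
    kernel: int = 3

    def __post_init__(self):
        if self.n_layers != 5:
            raise ValueError("the discriminator architecture is fixed at 5 conv stages")
        if len(self.channels) != 4:
            raise ValueError("channels must list the four trunk widths")


@dataclass
class TrainConfig:
    alpha: float = 1.0
    lambda_cyc: float = 10.0
    learning_rate: float = 2e-4
    batch_size: int = 2
    max_iterations: int = 300
    seed: int = 0
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None
    generator: GeneratorSpec = dc_field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = dc_field(default_factory=DiscriminatorSpec)

    def __post_init__(self):
        if self.alpha < 0 or self.lambda_cyc < 0:
            raise ValueError("alpha and lambda_cyc must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _conv_bn_relu(in_ch, out_ch, kernel, stride, rng):
    return nn.Sequential([nn.Conv2d(in_ch, out_ch, kernel, stride, rng),
                          nn.BatchNorm2d(out_ch), nn.ReLU()])


class Generator(nn.Sequential):
    """Image-to-image generator mapping [-1, 1] inputs to [-1, 1] outputs.

    Seven conv-BatchNorm-ReLU stages: a 3-stage encoder with one stride-2
    downsampling, a residual stage at half resolution, then a decoder that
    upsamples back and maps to one channel through tanh.  Keeping a single
    down/up pair preserves the fine texture the cycle reconstruction needs.
    """

    def __init__(self, spec: GeneratorSpec, seed: int):
        rng = np.random.default_rng([seed, 101])
        c1, c2, c3 = spec.channels
        k = spec.kernel
        super().__init__([
            _conv_bn_relu(1, c1, k, 1, rng),
            _conv_bn_relu(c1, c2, k, 2, rng),
            _conv_bn_relu(c2, c3, k, 1, rng),
            nn.Residual(_conv_bn_relu(c3, c3, k, 1, rng)),
            _conv_bn_relu(c3, c2, k, 1, rng),
            nn.Sequential([nn.Upsample2x(), *_conv_bn_relu(c2, c1, k, 1, rng).layers]),
            nn.Sequential([nn.Conv2d(c1, 1, k, 1, rng), nn.Tanh()]),
        ])
        self.spec = spec
        self.seed = seed


class TwoHeadDiscriminator:
    """Shared conv trunk with a realness head (D1) and a modality head (D2)."""

    def __init__(self, spec: DiscriminatorSpec, seed: int):
        rng = np.random.default_rng([seed, 202])
        c1, c2, c3, c4 = spec.channels
        k = spec.kernel
        self.trunk = nn.Sequential([
            _conv_bn_relu(1, c1, k, 2, rng),
            _conv_bn_relu(c1, c2, k, 2, rng),
            _conv_bn_relu(c2, c3, k, 2, rng),
            _conv_bn_relu(c3, c4, k, 1, rng),
        ])
        self.head1 = nn.Conv2d(c4, 1, k, 1, rng)
        self.head2 = nn.Conv2d(c4, 1, k, 1, rng)
        self.spec = spec
        self.seed = seed

    def forward(self, x, train=True):
        t = self.trunk.forward(x, train)
        if train:
            self._trunk_out_shape = t.shape
        return self.head1.forward(t, train), self.head2.forward(t, train)

    def backward(self, d1_grad, d2_grad):
        gt = self.head1.backward(d1_grad) + self.head2.backward(d2_grad)
        return self.trunk.backward(gt)

    def params(self):
        return self.trunk.params() + self.head1.params() + self.head2.params()

    def state(self):
        return {f"trunk.{k}": v for k, v in self.trunk.state().items()}

    def zero_grad(self):
        self.trunk.zero_grad()
        self.head1.zero_grad()
        self.head2.zero_grad()


def build_generator(spec: GeneratorSpec | None = None, seed: int = 0) -> Generator:
    """Seeded generator; same spec and seed give identical parameters."""
    return Generator(spec or GeneratorSpec(), seed)


def build_discriminator(spec: DiscriminatorSpec | None = None,
                        seed: int = 0) -> TwoHeadDiscriminator:
    """Seeded two-head discriminator."""
    return TwoHeadDiscriminator(spec or DiscriminatorSpec(), seed)


def adversarial_loss(d1_real, d1_fake, d2_real, d2_fake, alpha: float = 1.0) -> float:
    """Least-squares discriminative loss with weighted modality head.

    ``E[(d1_real - 1)^2] + E[d1_fake^2]
    + alpha * (E[(d2_real - 1)^2] + E[d2_fake^2])``.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    terms = [np.asarray(t, dtype=float) for t in (d1_real, d1_fake, d2_real, d2_fake)]
    if not all(np.all(np.isfinite(t)) for t in terms):
        raise ValueError("scores must be finite")
    r1, f1, r2, f2 = terms
    return float(np.mean((r1 - 1.0) ** 2) + np.mean(f1 ** 2)
                 + alpha * (np.mean((r2 - 1.0) ** 2) + np.mean(f2 ** 2)))


def cycle_loss(original, cyclic) -> float:
    """Mean absolute pixel difference between an image and its round trip."""
    a = original.pixels if isinstance(original, ImageGrid) else np.asarray(original, float)
    b = cyclic.pixels if isinstance(cyclic, ImageGrid) else np.asarray(cyclic, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


@dataclass
class TranslationModel:
    """Both generators, both two-head discriminators and training metadata."""

    G_ct2tee: Generator
    G_tee2ct: Generator
    D_tee: TwoHeadDiscriminator
    D_ct: TwoHeadDiscriminator
    config: TrainConfig
    iteration: int = 0
    loss_history: List[Dict[str, float]] = dc_field(default_factory=list)

    @classmethod
    def initialize(cls, config: TrainConfig) -> "TranslationModel":
        s = config.seed
        return cls(
            G_ct2tee=build_generator(config.generator, s),
            G_tee2ct=build_generator(config.generator, s + 1),
            D_tee=build_discriminator(config.discriminator, s + 2),
            D_ct=build_discriminator(config.discriminator, s + 3),
            config=config,
        )


def _check_range(x: np.ndarray, what: str) -> None:
    if x.min() < -1.0 - 1e-6 or x.max() > 1.0 + 1e-6:
        raise ValueError(f"{what} must be normalized to [-1, 1]; "
                         f"got range [{x.min():.3g}, {x.max():.3g}]")


def _pad_to_multiple(x: np.ndarray, m: int = 4):
    H, W = x.shape
    ph = (-H) % m
    pw = (-W) % m
    return np.pad(x, ((0, ph), (0, pw)), mode="edge"), H, W


def translate(model: TranslationModel, img: ImageGrid, direction: str) -> ImageGrid:
    """Run one generator in inference mode (running batchnorm statistics).

    Input must be normalized to [-1, 1]; output is a same-size image in
    [-1, 1] tagged TEE_LIKE (ct2tee) or CT_LIKE (tee2ct).  Deterministic:
    repeated calls are bit-identical.
    """
    if direction not in ("ct2tee", "tee2ct"):
        raise ValueError(f"direction must be ct2tee or tee2ct, got {direction!r}")
    _check_range(img.pixels, "translate() input")
    gen = model.G_ct2tee if direction == "ct2tee" else model.G_tee2ct
    padded, H, W = _pad_to_multiple(img.pixels, 2)
    out = gen.forward(padded[None, None], train=False)[0, 0, :H, :W]
    tag = "TEE_LIKE" if direction == "ct2tee" else "CT_LIKE"
    return ImageGrid(out, img.spacing, img.origin, tag)


def _lsq_grad(score: np.ndarray, target: float, weight: float) -> np.ndarray:
    return weight * 2.0 * (score - target) / score.size


def _abort_if_bad(value: float, term: str) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss in term '{term}'; aborting training")


def train_cyclegan(ct: PatchSet, tee: PatchSet,
                   config: TrainConfig | None = None) -> TranslationModel:
    """Train the cycle-adversarial translator on unpaired patch sets.

    Patches are expected in [0, 1] (the package's image convention) and are
    mapped linearly to [-1, 1] internally.  Each iteration alternates a
    generator update (adversarial terms against both discriminators plus
    ``lambda_cyc`` times both cycle losses) and a discriminator update (the
    least-squares two-head loss on real and generated samples).  The loss
    history is logged per iteration; with ``checkpoint_every > 0`` and a
    ``checkpoint_dir``, checkpoints are written during training.
    """
    config = config or TrainConfig()
    if len(ct) == 0 or len(tee) == 0:
        raise ValueError("both patch sets must be non-empty")
    model = TranslationModel.initialize(config)
    if config.max_iterations == 0:
        return model
    rng = np.random.default_rng([config.seed, 7])
    ct_arr = ct.as_array() * 2.0 - 1.0
    tee_arr = tee.as_array() * 2.0 - 1.0
    G1, G2 = model.G_ct2tee, model.G_tee2ct
    D_tee, D_ct = model.D_tee, model.D_ct
    opt_G = nn.Adam(G1.params() + G2.params(), lr=config.learning_rate)
    opt_D = nn.Adam(D_tee.params() + D_ct.params(), lr=config.learning_rate)
    alpha, lam = config.alpha, config.lambda_cyc
    B = config.batch_size

    for it in range(config.max_iterations):
        xi = rng.integers(0, len(ct_arr), B)
        yi = rng.integers(0, len(tee_arr), B)
        x = ct_arr[xi][:, None]
        y = tee_arr[yi][:, None]

        # ---- generator update -------------------------------------------
        fy = G1.forward(x)          # TEE-like from CT
        fx = G2.forward(y)          # CT-like from TEE
        cx = G2.forward(fy)         # cyclic CT
        cy = G1.forward(fx)         # cyclic TEE
        s1_ty, s2_ty = D_tee.forward(fy)
        s1_cx, s2_cx = D_ct.forward(fx)
        g_adv = (np.mean((s1_ty - 1) ** 2) + alpha * np.mean((s2_ty - 1) ** 2)
                 + np.mean((s1_cx - 1) ** 2) + alpha * np.mean((s2_cx - 1) ** 2))
        cyc = cycle_loss(x, cx) + cycle_loss(y, cy)
        _abort_if_bad(g_adv, "generator adversarial loss")
        _abort_if_bad(cyc, "cycle-consistency loss")

        g_fx = G1.backward(lam * np.sign(cy - y) / cy.size)
        g_fy = G2.backward(lam * np.sign(cx - x) / cx.size)
        g_fy = g_fy + D_tee.backward(_lsq_grad(s1_ty, 1.0, 1.0),
                                     _lsq_grad(s2_ty, 1.0, alpha))
        g_fx = g_fx + D_ct.backward(_lsq_grad(s1_cx, 1.0, 1.0),
                                    _lsq_grad(s2_cx, 1.0, alpha))
        G2.backward(g_fx)
        G1.backward(g_fy)
        opt_G.step()
        G1.zero_grad(); G2.zero_grad()
        D_tee.zero_grad(); D_ct.zero_grad()   # drop grads leaked by G pass

        # ---- discriminator update ---------------------------------------
        r1_t, r2_t = D_tee.forward(y)
        f1_t, f2_t = D_tee.forward(fy)        # fy held fixed
        r1_c, r2_c = D_ct.forward(x)
        f1_c, f2_c = D_ct.forward(fx)
        d_tee_loss = adversarial_loss(r1_t, f1_t, r2_t, f2_t, alpha)
        d_ct_loss = adversarial_loss(r1_c, f1_c, r2_c, f2_c, alpha)
        _abort_if_bad(d_tee_loss, "D_tee discriminative loss")
        _abort_if_bad(d_ct_loss, "D_ct discriminative loss")
        D_tee.backward(_lsq_grad(f1_t, 0.0, 1.0), _lsq_grad(f2_t, 0.0, alpha))
        D_tee.backward(_lsq_grad(r1_t, 1.0, 1.0), _lsq_grad(r2_t, 1.0, alpha))
        D_ct.backward(_lsq_grad(f1_c, 0.0, 1.0), _lsq_grad(f2_c, 0.0, alpha))
        D_ct.backward(_lsq_grad(r1_c, 1.0, 1.0), _lsq_grad(r2_c, 1.0, alpha))
        opt_D.step()
        D_tee.zero_grad(); D_ct.zero_grad()

        model.iteration = it + 1
        model.loss_history.append({
            "iteration": it + 1,
            "generator_adv": float(g_adv),
            "cycle": float(cyc),
            "d_tee": float(d_tee_loss),
            "d_ct": float(d_ct_loss),
        })
        if (config.checkpoint_every > 0 and config.checkpoint_dir
                and (it + 1) % config.checkpoint_every == 0):
            save_model(model, os.path.join(config.checkpoint_dir,
                                           f"checkpoint_{it + 1:06d}"))
    return model


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _module_arrays(module, prefix: str) -> Dict[str, np.ndarray]:
    out = {}
    for i, p in enumerate(module.params()):
        out[f"{prefix}.param{i}"] = p.data
    for k, v in module.state().items():
        out[f"{prefix}.state.{k}"] = v
    return out


def _load_module_arrays(module, prefix: str, arrays) -> None:
    for i, p in enumerate(module.params()):
        p.data[...] = arrays[f"{prefix}.param{i}"]
    for k in module.state():
        module_state = module.state()[k]
        module_state[...] = arrays[f"{prefix}.state.{k}"]


def save_model(model: TranslationModel, path: str) -> None:
    """Write a checkpoint directory: parameters (npz) + config (json)."""
    os.makedirs(path, exist_ok=True)
    arrays = {}
    for name, mod in (("G_ct2tee", model.G_ct2tee), ("G_tee2ct", model.G_tee2ct),
                      ("D_tee", model.D_tee), ("D_ct", model.D_ct)):
        arrays.update(_module_arrays(mod, name))
    np.savez(os.path.join(path, "weights.npz"), **arrays)
    cfg = asdict(model.config)
    meta = {"config": cfg, "iteration": model.iteration,
            "loss_history": model.loss_history}
    with open(os.path.join(path, "model.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(path: str) -> TranslationModel:
    """Load a checkpoint; translation outputs are bit-identical to the
    model that was saved."""
    with open(os.path.join(path, "model.json")) as fh:
        meta = json.load(fh)
    cfg = dict(meta["config"])
    cfg["generator"] = GeneratorSpec(**{**cfg["generator"],
                                        "channels": tuple(cfg["generator"]["channels"])})
    cfg["discriminator"] = DiscriminatorSpec(
        **{**cfg["discriminator"],
           "channels": tuple(cfg["discriminator"]["channels"])})
    config = TrainConfig(**cfg)
    model = TranslationModel.initialize(config)
    arrays = np.load(os.path.join(path, "weights.npz"))
    for name, mod in (("G_ct2tee", model.G_ct2tee), ("G_tee2ct", model.G_tee2ct),
                      ("D_tee", model.D_tee), ("D_ct", model.D_ct)):
        _load_module_arrays(mod, name, arrays)
    model.iteration = meta["iteration"]
    model.loss_history = meta["loss_history"]
    return model
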