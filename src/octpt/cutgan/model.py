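"""Contrastive unpaired translation: model fitting, checkpointing, conversion.

:class:`CUTModel` is built from two unpaired image sets (source preset X,
target preset Y) plus a :class:`TrainingConfig`; ``fit()`` runs the
alternating discriminator/generator schedule and returns a
:class:`CUTResults` carrying the loss trace (the six standard series: G_GAN,
D_real, D_fake, G, NCE, NCE_Y), the saved checkpoints and the conversion API.

The generator objective is

    L_G = L_GAN(G, D) + 0.5 * (lambda_X * L_patch(X) + lambda_Y * L_patch(Y))

where L_patch(Y) feeds target-class images through G (an identity-style
regulariser).  Training runs for ``epochs`` epochs at a constant learning rate
that decays linearly to zero over the final ``epochs - decay_start_epoch``
epochs, with Adam(beta1=0.5, beta2=0.999, lr=2e-4) by default and a generator
checkpoint every ``checkpoint_interval`` epochs plus the final epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from ..nn import Tensor, Adam
from ..nn.autograd import set_default_dtype, get_default_dtype
from ..phantom import BScanImage
from .networks import ResnetGenerator, PatchDiscriminator, ProjectionHeads
from .losses import (generator_gan_loss, embed_tap_t, patch_nce_loss_t,
                     sample_locations, DEFAULT_TAU)

__all__ = ["TrainingConfig", "CheckpointRecord", "CUTModel", "CUTResults",
           "lr_at_epoch", "checkpoint_epochs", "train", "convert"]

LOSS_COLUMNS = ["epoch", "G_GAN", "D_real", "D_fake", "G", "NCE", "NCE_Y"]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters and schedule constants.

    Full-scale defaults follow the published recipe (400 epochs with linear
    decay over the last 200, Adam(0.5, 0.999) at 2e-4, 286->256 resize/crop,
    checkpoints every 20 epochs, tau=0.07, encoder taps {0,4,8,12,16} on the
    9-res-block backbone).  :meth:`desk` returns the reduced configuration
    used for CPU-scale experiments.
    """

    epochs: int = 400
    decay_start_epoch: int = 200
    lr: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    resize: int = 286
    crop: int = 256
    checkpoint_interval: int = 20
    tau: float = DEFAULT_TAU
    nce_layers: tuple[int, ...] = (0, 4, 8, 12, 16)
    patches_per_layer: int = 256
    lambda_nce_x: float = 1.0
    lambda_nce_y: float = 1.0
    gan_mode: str = "least_squares"
    seed: int = 0
    base_width: int = 64
    n_res_blocks: int = 9
    stem_kernel: int = 7
    embed_dim: int = 256
    disc_width: int = 64
    batch_size: int = 1

    def __post_init__(self):
        if self.decay_start_epoch > self.epochs:
            raise ValueError("decay_start_epoch must be <= epochs")
        if self.crop > self.resize:
            raise ValueError("crop must be <= resize")
        positives = dict(lr=self.lr, tau=self.tau,
                         lambda_nce_x=self.lambda_nce_x,
                         lambda_nce_y=self.lambda_nce_y,
                         patches_per_layer=self.patches_per_layer,
                         checkpoint_interval=self.checkpoint_interval,
                         epochs=self.epochs, batch_size=self.batch_size)
        for name, val in positives.items():
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if self.gan_mode not in ("vanilla", "least_squares"):
            raise ValueError(f"unknown gan_mode {self.gan_mode!r}")
        n_enc = 10 + self.n_res_blocks
        for layer in self.nce_layers:
            if not (0 <= layer < n_enc):
                raise ValueError(
                    f"nce layer {layer} does not address an existing encoder "
                    f"layer (backbone with {self.n_res_blocks} res blocks has "
                    f"{n_enc} atomic layers)")

    @classmethod
    def desk(cls, seed: int = 0, epochs: int = 12,
             checkpoint_interval: int = 4) -> "TrainingConfig":
        """Reduced configuration for single-CPU runs on 64x64 phantoms:
        width-16 generator with 3 residual blocks and a 3x3 stem, taps
        (0,4,8,10,12) (the res-block tap indices of the small backbone),
        64 patches/layer, embedding dim 64, batch 1 as in the full-scale
        recipe, width-32 patch discriminator (capacity matters at this scale
        for the critic to keep resolving speckle statistics)."""
        return cls(epochs=epochs, decay_start_epoch=max(1, epochs // 2),
                   resize=64, crop=64, checkpoint_interval=checkpoint_interval,
                   nce_layers=(0, 4, 8, 10, 12), patches_per_layer=64,
                   seed=seed, base_width=16, n_res_blocks=3, stem_kernel=3,
                   embed_dim=64, disc_width=32, batch_size=1)


def lr_at_epoch(config: TrainingConfig, epoch: int) -> float:
    """Constant ``config.lr`` through ``decay_start_epoch``, then linear decay
    reaching exactly zero at the final epoch."""
    if not (1 <= epoch <= config.epochs):
        raise ValueError(f"epoch {epoch} outside [1, {config.epochs}]")
    if epoch <= config.decay_start_epoch:
        return config.lr
    span = config.epochs - config.decay_start_epoch
    return config.lr * (config.epochs - epoch) / span


def checkpoint_epochs(epochs: int, interval: int) -> list[int]:
    """Epochs at which generator checkpoints are saved: every ``interval``
    epochs plus the final epoch when it is not already a multiple."""
    out = list(range(interval, epochs + 1, interval))
    if not out or out[-1] != epochs:
        out.append(epochs)
    return out


@dataclass
class CheckpointRecord:
    epoch: int
    weights: dict[str, np.ndarray]
    losses: dict[str, float]
    path: Path | None = None


class TrainingDivergedError(RuntimeError):
    pass


def _prepare(pixels: np.ndarray, cfg: TrainingConfig,
             rng: np.random.Generator) -> np.ndarray:
    """Resize to cfg.resize, random-crop to cfg.crop, random horizontal flip."""
    img = pixels
    if img.shape != (cfg.resize, cfg.resize):
        img = _sk_resize(img, (cfg.resize, cfg.resize), anti_aliasing=True,
                         preserve_range=True)
    if cfg.crop < cfg.resize:
        r = rng.integers(0, cfg.resize - cfg.crop + 1)
        c = rng.integers(0, cfg.resize - cfg.crop + 1)
        img = img[r:r + cfg.crop, c:c + cfg.crop]
    if rng.random() < 0.5:
        img = img[:, ::-1]
    return np.clip(img, 0.0, 1.0)


class CUTModel:
    """Unpaired translation model from a source-preset image set to a
    target-preset image set."""

    def __init__(self, source_images: list[BScanImage],
                 target_images: list[BScanImage],
                 config: TrainingConfig | None = None):
        if not source_images or not target_images:
            raise ValueError("both image sets must be non-empty")
        self.config = config or TrainingConfig()
        self.source_images = list(source_images)
        self.target_images = list(target_images)
        self.source_preset = source_images[0].preset
        self.target_preset = target_images[0].preset

    # -- fitting --------------------------------------------------------------
    def fit(self, out_dir: Path | None = None, verbose: bool = False) -> "CUTResults":
        prev_dtype = get_default_dtype()
        set_default_dtype(np.float32)
        try:
            return self._fit(out_dir, verbose)
        finally:
            set_default_dtype(prev_dtype)

    def _fit(self, out_dir, verbose):
        cfg = self.config
        master = np.random.default_rng(cfg.seed)
        init_rng = np.random.default_rng(master.integers(0, 2 ** 31 - 1))
        data_rng = np.random.default_rng(master.integers(0, 2 ** 31 - 1))
        patch_rng = np.random.default_rng(master.integers(0, 2 ** 31 - 1))

        gen = ResnetGenerator(cfg.base_width, cfg.n_res_blocks,
                              cfg.stem_kernel, rng=init_rng)
        disc = PatchDiscriminator(cfg.disc_width, rng=init_rng)
        heads = ProjectionHeads(gen, cfg.nce_layers, cfg.embed_dim,
                                rng=init_rng)
        opt_g = Adam(gen.parameters() + heads.parameters(), lr=cfg.lr,
                     beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
        opt_d = Adam(disc.parameters(), lr=cfg.lr,
                     beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)

        xs = [img.pixels for img in self.source_images]
        ys = [img.pixels for img in self.target_images]
        n_iter = (len(xs) + cfg.batch_size - 1) // cfg.batch_size
        ckpt_at = set(checkpoint_epochs(cfg.epochs, cfg.checkpoint_interval))
        checkpoints: list[CheckpointRecord] = []
        trace_rows = []
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)

        for epoch in range(1, cfg.epochs + 1):
            lr = lr_at_epoch(cfg, epoch)
            opt_g.lr = lr
            opt_d.lr = lr
            order = data_rng.permutation(len(xs))
            y_order = data_rng.permutation(len(ys))
            sums = dict.fromkeys(LOSS_COLUMNS[1:], 0.0)
            for it in range(n_iter):
                bx = [xs[i] for i in order[it * cfg.batch_size:
                                           (it + 1) * cfg.batch_size]]
                by = [ys[y_order[(it * cfg.batch_size + j) % len(ys)]]
                      for j in range(len(bx))]
                losses = self._step(bx, by, gen, disc, heads, opt_g, opt_d,
                                    data_rng, patch_rng)
                for k, v in losses.items():
                    if not np.isfinite(v):
                        raise TrainingDivergedError(
                            f"non-finite loss {k}={v} at epoch {epoch}, "
                            f"iteration {it}")
                    sums[k] += v
            row = {"epoch": epoch, **{k: sums[k] / n_iter for k in sums}}
            trace_rows.append(row)
            if verbose:
                print("  ".join(f"{k}={v:.4g}" if k != "epoch" else f"e{v}"
                                for k, v in row.items()))
            if epoch in ckpt_at:
                rec = CheckpointRecord(epoch=epoch, weights=gen.state_dict(),
                                       losses={k: row[k] for k in
                                               LOSS_COLUMNS[1:]})
                if out_dir is not None:
                    stem = out_dir / f"ckpt_e{epoch:04d}"
                    np.savez(str(stem) + ".npz", **rec.weights)
                    with open(str(stem) + ".json", "w") as fh:
                        json.dump({"epoch": epoch, "config": asdict(cfg),
                                   "losses": rec.losses}, fh, indent=1)
                    rec.path = Path(str(stem) + ".npz")
                checkpoints.append(rec)

        trace = pd.DataFrame(trace_rows, columns=LOSS_COLUMNS)
        if out_dir is not None:
            trace.to_csv(out_dir / "loss_trace.csv", index=False)
        return CUTResults(model=self, generator=gen, checkpoints=checkpoints,
                          loss_trace=trace)

    def _step(self, bx, by, gen, disc, heads, opt_g, opt_d, data_rng,
              patch_rng):
        cfg = self.config
        xb = np.stack([_prepare(x, cfg, data_rng) for x in bx])[:, None]
        yb = np.stack([_prepare(y, cfg, data_rng) for y in by])[:, None]
        x_t, y_t = Tensor(xb), Tensor(yb)

        # generator forward on both domains (taps feed the contrastive terms)
        taps = cfg.nce_layers
        hx, feats_x = gen.encode(x_t, taps)
        fake = gen.decode(hx)
        hy, feats_y = gen.encode(y_t, taps)
        idt = gen.decode(hy)

        vanilla = cfg.gan_mode == "vanilla"

        def d_scores(img_t):
            raw = disc(img_t)
            return raw.sigmoid() if vanilla else raw

        # --- discriminator update (fake detached) ---
        d_real = d_scores(y_t)
        d_fake_det = d_scores(fake.detach())
        if vanilla:
            d_real_term = -(d_real.log().mean())
            d_fake_term = -((1.0 - d_fake_det).log().mean())
        else:
            d_real_term = ((d_real - 1.0) ** 2.0).mean()
            d_fake_term = (d_fake_det ** 2.0).mean()
        loss_d = (d_real_term + d_fake_term) * 0.5
        opt_d.zero_grad()
        loss_d.backward()
        opt_d.step()

        # --- generator + heads update ---
        g_gan = generator_gan_loss(d_scores(fake), cfg.gan_mode)
        _, feats_fake = gen.encode(fake, taps)
        _, feats_idt = gen.encode(idt, taps)
        nce_x = self._nce(feats_x, feats_fake, heads, patch_rng)
        nce_y = self._nce(feats_y, feats_idt, heads, patch_rng)
        loss_g = g_gan + (nce_x * cfg.lambda_nce_x +
                          nce_y * cfg.lambda_nce_y) * 0.5
        opt_g.zero_grad()
        loss_g.backward()
        opt_g.step()

        return {"G_GAN": g_gan.item(), "D_real": d_real_term.item(),
                "D_fake": d_fake_term.item(), "G": loss_g.item(),
                "NCE": nce_x.item(), "NCE_Y": nce_y.item()}

    def _nce(self, feats_orig, feats_trans, heads, patch_rng):
        """Patchwise contrastive loss between original-image and
        translated-image encoder taps, locations shared per layer and drawn
        fresh per image."""
        cfg = self.config
        queries, positives = [], []
        batch = feats_orig[cfg.nce_layers[0]].shape[0]
        for b in range(batch):
            for layer in cfg.nce_layers:
                fo = feats_orig[layer][b:b + 1]
                ft = feats_trans[layer][b:b + 1]
                _, _, h, w = fo.shape
                s = min(cfg.patches_per_layer, h * w)
                locs = sample_locations(patch_rng, h * w, s)
                head = heads.head_for(layer)
                positives.append(embed_tap_t(fo, locs, head))
                queries.append(embed_tap_t(ft, locs, head))
        return patch_nce_loss_t(queries, positives, cfg.tau)


@dataclass
class CUTResults:
    """Fitted translation model: loss trace, checkpoints, conversion."""

    model: CUTModel
    generator: ResnetGenerator
    checkpoints: list[CheckpointRecord]
    loss_trace: pd.DataFrame

    @property
    def config(self) -> TrainingConfig:
        return self.model.config

    def convert(self, image: BScanImage, epoch: int | None = None) -> BScanImage:
        """Translate one source-preset B-scan to the target preset using the
        final (default) or a specific checkpoint's generator weights."""
        gen = self._generator_at(epoch)
        return convert(gen, image, target_preset=self.model.target_preset)

    def convert_many(self, images, epoch: int | None = None):
        gen = self._generator_at(epoch)
        return [convert(gen, img, target_preset=self.model.target_preset)
                for img in images]

    def _generator_at(self, epoch: int | None) -> ResnetGenerator:
        if epoch is None:
            return self.generator
        for rec in self.checkpoints:
            if rec.epoch == epoch:
                self.generator.load_state_dict(rec.weights)
                return self.generator
        raise KeyError(f"no checkpoint at epoch {epoch}; have "
                       f"{[r.epoch for r in self.checkpoints]}")

    def summary(self) -> str:
        cfg = self.config
        last = self.loss_trace.iloc[-1]
        lines = [
            "Contrastive unpaired translation results",
            "=" * 44,
            f"direction:            {self.model.source_preset} -> "
            f"{self.model.target_preset}",
            f"images (src/tgt):     {len(self.model.source_images)} / "
            f"{len(self.model.target_images)}",
            f"epochs:               {cfg.epochs} (decay from "
            f"{cfg.decay_start_epoch})",
            f"gan mode:             {cfg.gan_mode}",
            f"generator params:     {self.generator.n_parameters()}",
            f"checkpoints saved:    {len(self.checkpoints)} at epochs "
            f"{[r.epoch for r in self.checkpoints]}",
            f"final losses:         " + "  ".join(
                f"{k}={last[k]:.4f}" for k in LOSS_COLUMNS[1:]),
        ]
        return "\n".join(lines)


def convert(gen: ResnetGenerator, image: BScanImage, *,
            target_preset: str) -> BScanImage:
    """Apply a trained generator to one B-scan.

    Arbitrary sizes are handled by reflection-padding both sides up to the
    generator's stride multiple (4) and cropping the output back; output is
    clipped to [0, 1] and tagged provenance=synthetic."""
    h, w = image.pixels.shape
    if min(h, w) < ResnetGenerator.MIN_SIZE:
        raise ValueError(f"image {h}x{w} smaller than the generator's minimum "
                         f"size {ResnetGenerator.MIN_SIZE}")
    ph = (-h) % 4
    pw = (-w) % 4
    arr = np.pad(image.pixels, ((0, ph), (0, pw)), mode="reflect")
    out = gen(Tensor(arr[None, None])).data[0, 0, :h, :w]
    return BScanImage(np.clip(np.asarray(out, dtype=np.float64), 0.0, 1.0),
                      preset=target_preset, provenance="synthetic",
                      source_id=image.source_id)


def train(config: TrainingConfig, source_set: list[BScanImage],
          target_set: list[BScanImage],
          out_dir: Path | None = None) -> "CUTResults":
    """Functional wrapper: fit a :class:`CUTModel` and return its results."""
    return CUTModel(source_set, target_set, config).fit(out_dir=out_dir)
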