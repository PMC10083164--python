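"""Adversarial and patchwise noise-contrastive losses.

The adversarial objective is the classic minimax value function: the
discriminator maximises  E[log D(y)] + E[log(1 - D(G(x)))]  over real targets
y and translations G(x); the generator uses the non-saturating form
-E[log D(G(x))].  A least-squares mode substitutes squared-error targets 1/0,
which is the conventional, more stable choice for this architecture family
and is the training default.

The contrastive term is an (N+1)-way cross-entropy over embedded patches: for
a query embedding q taken from the translated image at location s, the
positive q+ is the original image's embedding at the same location and the
negatives q- are the original's embeddings at the other sampled locations,
with similarities scaled by a temperature tau (default 0.07):

    l(q, q+, q-) = -log[ exp(q.q+/tau) / (exp(q.q+/tau) + sum_n exp(q.q_n-/tau)) ]

summed over the selected encoder layers and sampled locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Tensor

__all__ = ["adversarial_loss", "generator_gan_loss", "nce_term",
           "patchwise_nce_loss", "sample_patch_features", "PatchFeatureSet",
           "LayerPatchFeatures", "DomainError"]

DEFAULT_TAU = 0.07


class DomainError(ValueError):
    """Input outside the mathematical domain of a loss."""


def _mean_log(t: Tensor) -> Tensor:
    return t.log().mean()


def _check_open_unit(arr: np.ndarray, name: str) -> None:
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DomainError(f"vanilla mode requires {name} scores strictly "
                          "inside (0, 1)")


def adversarial_loss(d_on_real, d_on_fake, mode: str = "vanilla"):
    """Discriminator objective (the quantity D maximises).

    vanilla:        mean log d_real + mean log(1 - d_fake), scores in (0, 1).
    least_squares:  -0.5 [ mean (d_real - 1)^2 + mean d_fake^2 ]  (raw scores).

    Accepts NumPy arrays (returns float) or autodiff Tensors (returns Tensor).
    """
    tensor_in = isinstance(d_on_real, Tensor) or isinstance(d_on_fake, Tensor)
    r = d_on_real if isinstance(d_on_real, Tensor) else Tensor(np.asarray(d_on_real, float))
    f = d_on_fake if isinstance(d_on_fake, Tensor) else Tensor(np.asarray(d_on_fake, float))
    if mode == "vanilla":
        _check_open_unit(r.data, "real")
        _check_open_unit(f.data, "fake")
        out = _mean_log(r) + _mean_log(1.0 - f)
    elif mode == "least_squares":
        out = ((r - 1.0) ** 2.0).mean() * (-0.5) + (f ** 2.0).mean() * (-0.5)
    else:
        raise ValueError(f"unknown gan mode {mode!r}")
    return out if tensor_in else out.item()


def generator_gan_loss(d_on_fake, mode: str = "vanilla"):
    """Generator-side adversarial loss (to minimise): non-saturating
    -mean log d_fake in vanilla mode, mean (d_fake - 1)^2 in least-squares."""
    tensor_in = isinstance(d_on_fake, Tensor)
    f = d_on_fake if tensor_in else Tensor(np.asarray(d_on_fake, float))
    if mode == "vanilla":
        _check_open_unit(f.data, "fake")
        out = -_mean_log(f)
    elif mode == "least_squares":
        out = ((f - 1.0) ** 2.0).mean()
    else:
        raise ValueError(f"unknown gan mode {mode!r}")
    return out if tensor_in else out.item()


def nce_term(q: np.ndarray, q_plus: np.ndarray, q_minus: np.ndarray,
             tau: float = DEFAULT_TAU) -> float:
    """(N+1)-way cross-entropy with the positive as the true class, computed
    with a numerically stable log-sum-exp.  Always >= 0."""
    if tau <= 0:
        raise DomainError("tau must be positive")
    q = np.asarray(q, float)
    q_plus = np.asarray(q_plus, float)
    q_minus = np.atleast_2d(np.asarray(q_minus, float))
    if q.shape != q_plus.shape or q_minus.shape[1] != q.shape[0]:
        raise ValueError("embedding dimension mismatch")
    if q_minus.shape[0] < 1:
        raise ValueError("need at least one negative")
    logits = np.concatenate(([q @ q_plus], q_minus @ q)) / tau
    m = logits.max()
    return float(np.log(np.exp(logits - m).sum()) + m - logits[0])


@dataclass(frozen=True)
class LayerPatchFeatures:
    """Embedded patches of one encoder layer.

    ``queries`` come from the translated image, ``positives`` from the
    original image at the same spatial locations.  The negatives of query s
    are the original image's embeddings at the other locations, i.e.
    ``positives`` with row s removed.
    """

    layer_index: int
    queries: np.ndarray    # (S, D)
    positives: np.ndarray  # (S, D)
    locations: np.ndarray  # (S,) flat spatial indices

    def __post_init__(self):
        if self.queries.shape != self.positives.shape:
            raise ValueError("|queries| must equal |positives|")
        if len(self.locations) != len(self.queries):
            raise ValueError("one location per query required")
        if len(np.unique(self.locations)) != len(self.locations):
            raise ValueError("locations must be distinct (sampled without "
                             "replacement)")

    def negatives_for(self, s: int) -> np.ndarray:
        return np.delete(self.positives, s, axis=0)


@dataclass(frozen=True)
class PatchFeatureSet:
    layers: tuple[LayerPatchFeatures, ...]
    tau: float = DEFAULT_TAU

    def __post_init__(self):
        if self.tau <= 0:
            raise DomainError("tau must be positive")


def patchwise_nce_loss(pfs: PatchFeatureSet) -> float:
    """Mean of ``nce_term`` over all layers and sampled locations, computed
    as a batched similarity matrix with the positive on the diagonal."""
    if not pfs.layers:
        raise ValueError("patch feature set has no layers")
    terms = []
    for lf in pfs.layers:
        logits = (lf.queries @ lf.positives.T) / pfs.tau  # (S, S)
        m = logits.max(axis=1, keepdims=True)
        lse = np.log(np.exp(logits - m).sum(axis=1)) + m[:, 0]
        terms.append(lse - np.diag(logits))
    return float(np.concatenate(terms).mean())


def normalize_rows_t(z: Tensor, eps: float = 1e-12) -> Tensor:
    """Unit-normalise each row of a (S, D) Tensor (differentiably)."""
    norm = ((z * z).sum(axis=1, keepdims=True) + eps) ** 0.5
    return z * norm ** -1.0


def sample_locations(rng: np.random.Generator, n_available: int,
                     n_wanted: int) -> np.ndarray:
    if n_wanted > n_available:
        raise ValueError(f"requested {n_wanted} patch locations but only "
                         f"{n_available} exist")
    return rng.choice(n_available, size=n_wanted, replace=False)


def embed_tap_t(feat: Tensor, locations: np.ndarray, head) -> Tensor:
    """Gather feature columns of a (1, C, H, W) tap at flat spatial locations,
    project through the head MLP and unit-normalise.  Differentiable."""
    _, c, h, w = feat.shape
    cols = feat.reshape(c, h * w).T[locations]  # (S, C)
    return normalize_rows_t(head(cols))


def patch_nce_loss_t(queries: list[Tensor], positives: list[Tensor],
                     tau: float = DEFAULT_TAU) -> Tensor:
    """Differentiable patchwise loss over per-layer (S, D) embedding Tensors;
    numerically identical to :func:`patchwise_nce_loss` on the same data."""
    per_location = []
    for q, k in zip(queries, positives):
        s = q.shape[0]
        logits = (q @ k.T) * (1.0 / tau)
        lse = logits.logsumexp(axis=1)
        diag = logits[np.arange(s), np.arange(s)]
        per_location.append(lse - diag)
    out = per_location[0].sum()
    for t in per_location[1:]:
        out = out + t.sum()
    count = sum(t.shape[0] for t in per_location)
    return out * (1.0 / count)


def sample_patch_features(x_pixels: np.ndarray, xhat_pixels: np.ndarray,
                          generator, heads, layers: tuple[int, ...],
                          s_per_layer: int, seed: int,
                          tau: float = DEFAULT_TAU) -> PatchFeatureSet:
    """Extract a :class:`PatchFeatureSet` from an original/translated image
    pair: per layer, ``s_per_layer`` locations drawn uniformly without
    replacement (shared between the two feature maps), embedded through the
    layer's head and unit-normalised.  Detached NumPy output for analysis and
    tests; training uses the differentiable pieces directly."""
    if x_pixels.shape != xhat_pixels.shape:
        raise ValueError("original and translated images must share a shape")
    rng = np.random.default_rng(seed)
    x_t = Tensor(np.asarray(x_pixels, float)[None, None])
    xh_t = Tensor(np.asarray(xhat_pixels, float)[None, None])
    _, feats_x = generator.encode(x_t, tuple(layers))
    _, feats_xh = generator.encode(xh_t, tuple(layers))
    out = []
    for layer in layers:
        fx, fxh = feats_x[layer], feats_xh[layer]
        _, _, h, w = fx.shape
        locs = sample_locations(rng, h * w, s_per_layer)
        head = heads.head_for(layer)
        pos = embed_tap_t(fx, locs, head)
        qry = embed_tap_t(fxh, locs, head)
        out.append(LayerPatchFeatures(layer_index=layer,
                                      queries=qry.data.copy(),
                                      positives=pos.data.copy(),
                                      locations=locs))
    return PatchFeatureSet(tuple(out), tau=tau)
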