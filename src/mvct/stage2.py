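"""Stage 2: the single axial-view student trained under pseudo-supervision.

The student is itself a bidirectional translation model on unpaired axial
slices.  In addition to the adversarial and cycle terms it minimizes a
pseudo-supervised L1 term against fused pseudo-targets:

    L_G = lambda1 * L_gan + lambda2 * L_cyc + lambda3 * L_rec,
    lambda = (1, 10, 5) by default.

The teacher predictions (view-complementary triples) are frozen, computed
once after stage 1; the fusion *weights* are recomputed dynamically at every
iteration from the student's own current inverse generators, on the cropped
patches.  Pseudo-targets never enter the adversarial terms and no paired
ground truth is ever seen.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field

from ._nn import Adam
from ._training import (
    DEFAULT_HU_WINDOW,
    l1_value_and_grad,
    normalize,
)
from .fusion import DifferenceMaps, weight_maps_from_diffs
from .geometry import CTVolume
from .losses import l1_mean
from .networks import DiscriminatorSpec, GeneratorSpec
from .stage1 import (
    ImagePool,
    TranslationModel,
    ViewPredictionTriple,
    _build_model,
    _check_finite,
    denoise_volume,
    discriminator_step,
    generator_step,
)
from .synthetic import UnpairedSliceDataset


@dataclass
class Stage2Config:
    patch_size: int = 64
    batch_size: int = 3
    patches_per_slice: int = 10
    epochs: int = 100
    learning_rate: float = 1e-5
    d_learning_rate: float | None = None  # None: same as learning_rate
    lambda1: float = 1.0
    lambda2: float = 10.0
    lambda3: float = 5.0
    pool_size: int = 0  # image-history buffer for D updates (0 = off)
    seed: int = 0
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
    steps_per_epoch: int | None = None
    log_every: int = 1

    def __post_init__(self):
        if min(self.patch_size, self.batch_size, self.patches_per_slice, self.epochs) < 1:
            raise ValueError("patch/batch/epoch settings must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("balance factors must be nonnegative")


def pseudo_supervised_loss(x_batch, y_batch, pseudo_y, pseudo_x, g_xy, g_yx) -> float:
    """mean |G_xy(x) - pseudo_y|_1 + mean |G_yx(y) - pseudo_x|_1."""
    return l1_mean(g_xy(np.asarray(x_batch)), pseudo_y) + l1_mean(
        g_yx(np.asarray(y_batch)), pseudo_x
    )


def stage2_generator_objective(
    gan: float, cycle: float, rec: float, config: Stage2Config | None = None
) -> float:
    """lambda1 * gan + lambda2 * cycle + lambda3 * rec."""
    cfg = config or Stage2Config()
    for v in (gan, cycle, rec):
        if not np.isfinite(v):
            raise ValueError("loss components must be finite")
    return float(cfg.lambda1 * gan + cfg.lambda2 * cycle + cfg.lambda3 * rec)


PredictionStore = dict  # (volume_id, axial_index) -> ViewPredictionTriple


def index_triples(triples: list[ViewPredictionTriple]) -> PredictionStore:
    return {t.axial_index: t for t in triples}


@dataclass
class PseudoPairBatch:
    """Aligned patch crops for one training step of one direction."""

    real: np.ndarray          # (N,1,p,p) normalized real images
    predictions: np.ndarray   # (3,N,1,p,p) frozen teacher predictions
    pseudo: np.ndarray | None = None   # fused targets, filled per iteration
    weights: np.ndarray | None = None  # (3,N,1,p,p) fusion weights used


def _crop_group(rng, image: np.ndarray, preds, patch: int, per_image: int):
    """Identical crop coordinates for the real image and its three predictions."""
    h, w = image.shape
    if patch > h or patch > w:
        raise ValueError(f"patch_size {patch} exceeds slice dims {(h, w)}")
    reals, pred_crops = [], []
    for _ in range(per_image):
        i = int(rng.integers(0, h - patch + 1))
        j = int(rng.integers(0, w - patch + 1))
        reals.append(image[i : i + patch, j : j + patch])
        pred_crops.append([p[i : i + patch, j : j + patch] for p in preds])
    return reals, pred_crops


def _fuse_batch(real: np.ndarray, preds: np.ndarray, inverse_generator):
    """Dynamic cycle-consistency-weighted fusion on a patch batch.

    real (N,1,p,p); preds (3,N,1,p,p).  The inverse generator is applied to
    all 3N predictions in one forward pass; weights are treated as constants
    (no gradient flows through the weight computation).
    """
    three, n = preds.shape[0], preds.shape[1]
    flat = preds.reshape(three * n, *preds.shape[2:])
    recon = inverse_generator(flat).reshape(preds.shape)
    diffs = np.abs(recon - real[None])
    wm = weight_maps_from_diffs(DifferenceMaps(diffs[0], diffs[1], diffs[2]))
    weights = wm.stack()  # (3,N,1,p,p)
    pseudo = (weights * preds).sum(axis=0)
    return pseudo.astype(np.float32), weights


def train_single_view(
    unpaired: UnpairedSliceDataset,
    l2h_triples: PredictionStore,
    h2l_triples: PredictionStore,
    config: Stage2Config,
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
) -> TranslationModel:
    """Train the axial student with dynamic cycle-consistency-weighted
    pseudo-supervision from frozen stage-1 triples."""
    if unpaired.view != "axial":
        raise ValueError("the student is trained on the axial view")
    if unpaired.paired:
        raise ValueError("stage-2 training requires an unpaired dataset")
    gen_spec = gen_spec or GeneratorSpec(family="redcnn")
    disc_spec = disc_spec or DiscriminatorSpec()

    def _prep(records, store, names):
        out = []
        for r in records:
            key = (r.source_id, r.index)
            if key not in store:
                raise ValueError(f"missing view-complementary triple for slice {key}")
            t = store[key]
            preds = [normalize(getattr(t, f"from_{v}"), config.hu_window) for v in names]
            out.append((normalize(r.image, config.hu_window), preds))
        return out

    views = ("axial", "sagittal", "coronal")
    low = _prep(unpaired.low, l2h_triples, views)    # x with HD-prediction triples
    high = _prep(unpaired.high, h2l_triples, views)  # y with LD-prediction triples

    model = _build_model("axial", gen_spec, disc_spec, config.seed)
    model.hu_window = config.hu_window
    opt_g = Adam([model.g_xy, model.g_yx], lr=config.learning_rate)
    opt_d = Adam(
        [model.d_x, model.d_y], lr=config.d_learning_rate or config.learning_rate
    )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    pool_x = ImagePool(config.pool_size, rng)
    pool_y = ImagePool(config.pool_size, rng)

    steps = config.steps_per_epoch or max(
        1, min(len(low), len(high)) // config.batch_size
    )
    it = 0
    for epoch in range(config.epochs):
        for _ in range(steps):
            x_reals, x_preds = [], []
            for i in rng.integers(0, len(low), config.batch_size):
                r, p = _crop_group(
                    rng, low[i][0], low[i][1], config.patch_size, config.patches_per_slice
                )
                x_reals += r
                x_preds += p
            y_reals, y_preds = [], []
            for i in rng.integers(0, len(high), config.batch_size):
                r, p = _crop_group(
                    rng, high[i][0], high[i][1], config.patch_size, config.patches_per_slice
                )
                y_reals += r
                y_preds += p

            x = np.stack(x_reals)[:, None].astype(np.float32)
            y = np.stack(y_reals)[:, None].astype(np.float32)
            # (3,N,1,p,p)
            py = np.stack([np.stack([g[v] for g in x_preds]) for v in range(3)])[:, :, None]
            px = np.stack([np.stack([g[v] for g in y_preds]) for v in range(3)])[:, :, None]

            # dynamic weights from the student's current inverse generators
            pseudo_y, w_y = _fuse_batch(x, py.astype(np.float32), model.g_yx)
            pseudo_x, w_x = _fuse_batch(y, px.astype(np.float32), model.g_xy)

            def rec_grads(fake_y, fake_x):
                ly, gy = l1_value_and_grad(fake_y, pseudo_y)
                lx, gx = l1_value_and_grad(fake_x, pseudo_x)
                lam3 = config.lambda3
                return ly + lx, lam3 * gy, lam3 * gx

            g_out = generator_step(
                model, x, y, config.lambda2, opt_g,
                lam1=config.lambda1, rec_grads=rec_grads,
            )
            d_loss = discriminator_step(
                model, x, y,
                pool_x.query(g_out["fake_x"]), pool_y.query(g_out["fake_y"]),
                opt_d,
            )

            gan = g_out["gan_xy"] + g_out["gan_yx"]
            total = stage2_generator_objective(gan, g_out["cycle"], g_out["rec"], config)
            _check_finite(total, "generator", it)
            _check_finite(d_loss, "discriminator", it)
            if it % config.log_every == 0:
                model.history.append(
                    {
                        "iteration": it,
                        "epoch": epoch,
                        "cycle": g_out["cycle"],
                        "gan_g": gan,
                        "gan_d": d_loss,
                        "rec": g_out["rec"],
                        "total": total,
                        "mean_weights_y": [float(w_y[v].mean()) for v in range(3)],
                        "mean_weights_x": [float(w_x[v].mean()) for v in range(3)],
                    }
                )
            it += 1
    return model


def denoise_axial(student: TranslationModel, volume: CTVolume) -> CTVolume:
    """Inference path: slice-wise axial application of the student's
    low->high generator; no multi-view dependency."""
    if student.view != "axial":
        raise ValueError("student model must be an axial-view model")
    return denoise_volume(student, volume, direction="l2h")
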