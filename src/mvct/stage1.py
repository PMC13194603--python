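"""Stage 1: three view-independent unpaired translation models.

Each model is a bidirectional generator pair (low->high, high->low) with two
patch discriminators, trained on unpaired 2D slices from one anatomical view
with the least-squares adversarial losses plus cycle consistency.  Generators
and discriminators are updated in alternation: the generators take a step
while the discriminators are held fixed, then vice versa.

After training, view-complementary predictions for each axial slice are made
by denoising the whole volume slice-wise along each model's own view,
restacking to 3D and re-splitting axially.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam
from ._training import (
    DEFAULT_HU_WINDOW,
    apply_generator_slices,
    l1_value_and_grad,
    lsgan_target_grad,
    normalize,
    sample_patches,
)
from .geometry import CTVolume, resplit_axial, split_volume, stack_slices
from .losses import stage1_generator_objective
from .networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    build_discriminator,
    build_generator,
)
from .synthetic import UnpairedSliceDataset

DIRECTIONS = ("l2h", "h2l")


class ImagePool:
    """History buffer of generated images for discriminator updates.

    With probability 1/2 a query returns (and replaces) a buffered past fake
    instead of the current one, which decorrelates the discriminator's
    training stream from the generator's instantaneous output and damps the
    adversarial arms race.  ``size=0`` disables the pool (pass-through).
    """

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.buffer: list[np.ndarray] = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        if self.size == 0:
            return batch
        out = []
        for img in batch:
            if len(self.buffer) < self.size:
                self.buffer.append(img.copy())
                out.append(img)
            elif self.rng.random() < 0.5:
                i = int(self.rng.integers(len(self.buffer)))
                out.append(self.buffer[i])
                self.buffer[i] = img.copy()
            else:
                out.append(img)
        return np.stack(out)


@dataclass
class Stage1Config:
    patch_size: int = 256
    batch_size: int = 5
    patches_per_slice: int = 2
    epochs: int = 100
    learning_rate: float = 1e-5
    d_learning_rate: float | None = None  # None: same as learning_rate
    lam: float = 10.0
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
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


@dataclass
class ViewPredictionTriple:
    """The three view-model outputs aligned to one axial slice."""

    axial_index: tuple[str, int]
    from_axial: np.ndarray
    from_sagittal: np.ndarray
    from_coronal: np.ndarray
    direction: str = "l2h"

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not (
            self.from_axial.shape == self.from_sagittal.shape == self.from_coronal.shape
        ):
            raise ValueError("triple members must share the axial slice shape")


@dataclass
class TranslationModel:
    """Generator pair + discriminators + training history for one view."""

    g_xy: object  # low -> high
    g_yx: object  # high -> low
    d_x: object
    d_y: object
    view: str
    gen_spec: GeneratorSpec
    disc_spec: DiscriminatorSpec
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
    history: list[dict] = field(default_factory=list)

    def generator(self, direction: str):
        if direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        return self.g_xy if direction == "l2h" else self.g_yx

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {}
        for name, net in (("g_xy", self.g_xy), ("g_yx", self.g_yx),
                          ("d_x", self.d_x), ("d_y", self.d_y)):
            for k, v in net.state_dict().items():
                arrays[f"{name}/{k}"] = v
        meta = {
            "view": self.view,
            "hu_window": list(self.hu_window),
            "gen_spec": dataclasses.asdict(self.gen_spec),
            "disc_spec": dataclasses.asdict(self.disc_spec),
            "history": self.history,
        }
        np.savez(path, __meta__=json.dumps(meta), **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "TranslationModel":
        with np.load(str(path), allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        meta["gen_spec"]["base_channels"] = tuple(meta["gen_spec"]["base_channels"])
        gen_spec = GeneratorSpec(**meta["gen_spec"])
        disc_spec = DiscriminatorSpec(**meta["disc_spec"])
        nets = {}
        for name in ("g_xy", "g_yx", "d_x", "d_y"):
            net = (
                build_generator(gen_spec)
                if name.startswith("g")
                else build_discriminator(disc_spec)
            )
            net.load_state_dict(
                {k.split("/", 1)[1]: v for k, v in arrays.items() if k.startswith(name + "/")}
            )
            nets[name] = net
        return cls(
            view=meta["view"],
            hu_window=tuple(meta["hu_window"]),
            gen_spec=gen_spec,
            disc_spec=disc_spec,
            history=meta.get("history", []),
            **nets,
        )


def _build_model(view, gen_spec, disc_spec, seed) -> TranslationModel:
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0]) for c in ss.spawn(4)]
    return TranslationModel(
        g_xy=build_generator(dataclasses.replace(gen_spec, seed=seeds[0])),
        g_yx=build_generator(dataclasses.replace(gen_spec, seed=seeds[1])),
        d_x=build_discriminator(dataclasses.replace(disc_spec, seed=seeds[2])),
        d_y=build_discriminator(dataclasses.replace(disc_spec, seed=seeds[3])),
        view=view,
        gen_spec=gen_spec,
        disc_spec=disc_spec,
    )


def _check_finite(value: float, what: str, iteration: int):
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite {what} loss ({value}) at iteration {iteration}; aborting"
        )


def generator_step(model, x, y, lam, opt_g, lam1: float = 1.0, rec_grads=None):
    """One generator update (discriminators fixed).

    ``rec_grads``, if given, is a callable ``(fake_y, fake_x) -> (rec_loss,
    g_fake_y, g_fake_x)`` adding a pseudo-supervision term (stage 2).
    Returns a dict of scalar losses plus the intermediate fakes.
    """
    g_xy, g_yx, d_x, d_y = model.g_xy, model.g_yx, model.d_x, model.d_y
    opt_g.zero_grad()
    # clear discriminator grads polluted by backprop-through-D below
    d_x.zero_grad()
    d_y.zero_grad()

    fake_y, t_xy = g_xy.forward(x)
    rec_x, t_yx_rec = g_yx.forward(fake_y)
    fake_x, t_yx = g_yx.forward(y)
    rec_y, t_xy_rec = g_xy.forward(fake_x)

    s_fake_y, td_y = d_y.forward(fake_y)
    s_fake_x, td_x = d_x.forward(fake_x)

    gan_xy, g_sy = lsgan_target_grad(s_fake_y, 1.0)
    gan_yx, g_sx = lsgan_target_grad(s_fake_x, 1.0)
    cyc_f, g_rec_x = l1_value_and_grad(rec_x, x)
    cyc_b, g_rec_y = l1_value_and_grad(rec_y, y)
    cycle = cyc_f + cyc_b

    grad_fake_y = lam1 * d_y.backward(g_sy, td_y)
    grad_fake_x = lam1 * d_x.backward(g_sx, td_x)
    grad_fake_y = grad_fake_y + g_yx.backward((lam * g_rec_x).astype(np.float32), t_yx_rec)
    grad_fake_x = grad_fake_x + g_xy.backward((lam * g_rec_y).astype(np.float32), t_xy_rec)

    out = {"gan_xy": gan_xy, "gan_yx": gan_yx, "cycle": cycle}
    if rec_grads is not None:
        rec_loss, extra_y, extra_x = rec_grads(fake_y, fake_x)
        grad_fake_y = grad_fake_y + extra_y
        grad_fake_x = grad_fake_x + extra_x
        out["rec"] = rec_loss

    g_xy.backward(grad_fake_y.astype(np.float32), t_xy)
    g_yx.backward(grad_fake_x.astype(np.float32), t_yx)
    opt_g.step()
    out["fake_y"], out["fake_x"] = fake_y, fake_x
    return out


def discriminator_step(model, x, y, fake_x, fake_y, opt_d):
    """One discriminator update (generators fixed; fakes are detached)."""
    opt_d.zero_grad()
    d_loss = 0.0
    for d, real, fake in ((model.d_y, y, fake_y), (model.d_x, x, fake_x)):
        s_real, t_real = d.forward(real)
        s_fake, t_fake = d.forward(fake)
        l_real, g_real = lsgan_target_grad(s_real, 1.0)
        l_fake, g_fake = lsgan_target_grad(s_fake, 0.0)
        d.backward(g_real, t_real)
        d.backward(g_fake, t_fake)
        d_loss += l_real + l_fake
    opt_d.step()
    return 0.5 * d_loss  # each term already carries the 1/2 factor per Eq.


def train_view_model(
    dataset: UnpairedSliceDataset,
    config: Stage1Config,
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
    warm_start: TranslationModel | None = None,
) -> TranslationModel:
    """Train one view-specific unpaired translation model.

    ``warm_start`` continues training an existing model (fresh optimizer
    state) instead of building new networks.
    """
    if dataset.paired:
        raise ValueError("stage-1 training requires an unpaired dataset")
    gen_spec = gen_spec or GeneratorSpec()
    disc_spec = disc_spec or DiscriminatorSpec()

    h, w = dataset.slice_shape
    if config.patch_size > min(h, w):
        raise ValueError(
            f"patch_size {config.patch_size} exceeds slice dims {(h, w)}"
        )

    if warm_start is not None:
        if warm_start.view != dataset.view:
            raise ValueError("warm_start model view does not match the dataset")
        model = warm_start
    else:
        model = _build_model(dataset.view, gen_spec, disc_spec, config.seed)
    model.hu_window = config.hu_window
    low = [normalize(r.image, config.hu_window) for r in dataset.low]
    high = [normalize(r.image, config.hu_window) for r in dataset.high]

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
            xs = [low[i] for i in rng.integers(0, len(low), config.batch_size)]
            ys = [high[i] for i in rng.integers(0, len(high), config.batch_size)]
            x = sample_patches(rng, xs, config.patch_size, config.patches_per_slice)
            y = sample_patches(rng, ys, config.patch_size, config.patches_per_slice)

            g_out = generator_step(model, x, y, config.lam, opt_g)
            d_loss = discriminator_step(
                model, x, y,
                pool_x.query(g_out["fake_x"]), pool_y.query(g_out["fake_y"]),
                opt_d,
            )

            total = stage1_generator_objective(
                g_out["gan_xy"], g_out["gan_yx"], g_out["cycle"], config.lam
            )
            _check_finite(total, "generator", it)
            _check_finite(d_loss, "discriminator", it)
            if it % config.log_every == 0:
                model.history.append(
                    {
                        "iteration": it,
                        "epoch": epoch,
                        "cycle": g_out["cycle"],
                        "gan_g": g_out["gan_xy"] + g_out["gan_yx"],
                        "gan_d": d_loss,
                        "total": total,
                    }
                )
            it += 1
    return model


def denoise_volume(model: TranslationModel, volume: CTVolume, direction: str = "l2h") -> CTVolume:
    """Split along the model's view, run the chosen generator on full slices,
    stack back.  Shape-preserving."""
    gen = model.generator(direction)
    ss = split_volume(volume, model.view)
    out_slices = apply_generator_slices(gen, ss.slices, model.hu_window)
    out = dataclasses.replace(ss, slices=out_slices)
    return stack_slices(out)


def generate_view_complementary_predictions(
    models: dict[str, TranslationModel],
    volume: CTVolume,
    direction: str = "l2h",
) -> list[ViewPredictionTriple]:
    """Denoise the volume once per view model, re-split each result axially,
    and align the three axial slices per index into triples."""
    for view in ("axial", "sagittal", "coronal"):
        if view not in models:
            raise ValueError(f"missing model for view {view!r}")
        if models[view].view != view:
            raise ValueError(f"model registered under {view!r} has view {models[view].view!r}")
    per_view = {
        view: resplit_axial(denoise_volume(models[view], volume, direction)).slices
        for view in ("axial", "sagittal", "coronal")
    }
    n = volume.shape[0]
    return [
        ViewPredictionTriple(
            axial_index=(volume.volume_id, i),
            from_axial=per_view["axial"][i],
            from_sagittal=per_view["sagittal"][i],
            from_coronal=per_view["coronal"][i],
            direction=direction,
        )
        for i in range(n)
    ]
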