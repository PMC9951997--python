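"""Three-channel conditional GAN for MRI to synthetic-CT translation.

A U-net generator maps the MRI channel triplet (air/bone/soft, each in
[-1, 1]) to an sCT triplet; a PatchGAN discriminator judges (MRI, candidate)
pairs patch-wise.  The generator loss combines the adversarial cross-entropy
on the channel triplets with an L1 term evaluated after reassembling the slice
to Hounsfield units, weighted by lambda = 100.  Training alternates one Adam
step on the discriminator and one on the generator at batch size 1, where
batch normalization acts as instance normalization.  Dropout provides the
noise input z and stays active at inference.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import CHANNEL_NAMES, ChannelRanges, ChannelTriplet, resize_to_net, scale_channels, segment_channels
from .reconstruct import reassemble_slice, stack_volume
from .volume import ImageVolume


@dataclass(frozen=True)
class GanConfig:
    """Architecture and optimization settings.

    Defaults follow the clinical-scale setup (256x256x3 input, 70x70-receptive
    -field discriminator, lambda = 100, Adam beta1 = 0.5 / beta2 = 0.999,
    discriminator learning rate 2e-7, batch 1, 20 epochs).  The generator
    learning rate uses the customary Pix2Pix value 2e-4.
    """

    size: int = 256
    in_channels: int = 3
    out_channels: int = 3
    gen_base_filters: int = 64
    disc_base_filters: int = 64
    disc_strided_blocks: int = 3
    lambda_l1: float = 100.0
    lr_generator: float = 2e-4
    lr_discriminator: float = 2e-7
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 1
    epochs: int = 20
    dropout_rate: float = 0.5
    dropout_blocks: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.batch_size != 1:
            raise ValueError("the training schedule is defined for batch size 1")

    @classmethod
    def tiny(cls, **overrides) -> "GanConfig":
        """Reduced configuration (64x64, quarter filter counts) for CPU runs."""
        kw = dict(size=64, gen_base_filters=16, disc_base_filters=16,
                  disc_strided_blocks=2)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class GanState:
    """Trainable parameters of both networks plus training bookkeeping."""

    config: GanConfig
    generator: nn.UNet
    discriminator: nn.PatchGAN
    rng: np.random.Generator
    epoch: int = 0
    history: list[dict] = field(default_factory=list)

    @property
    def n_parameters(self) -> tuple[int, int]:
        return (
            sum(p.value.size for p in self.generator.params()),
            sum(p.value.size for p in self.discriminator.params()),
        )


def init_state(config: GanConfig) -> GanState:
    rng = np.random.default_rng(config.seed)
    gen = nn.UNet(
        in_ch=config.in_channels, out_ch=config.out_channels, size=config.size,
        base=config.gen_base_filters, dropout_rate=config.dropout_rate,
        n_dropout=config.dropout_blocks, rng=rng,
    )
    disc = nn.PatchGAN(
        in_ch=config.in_channels + config.out_channels,
        base=config.disc_base_filters, n_strided=config.disc_strided_blocks, rng=rng,
    )
    return GanState(config=config, generator=gen, discriminator=disc, rng=rng)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _triplet_from_stack(stack: np.ndarray, like: ChannelTriplet,
                        ranges: dict | None = None) -> ChannelTriplet:
    channels = {n: np.asarray(stack[i], dtype=np.float64)
                for i, n in enumerate(CHANNEL_NAMES)}
    return ChannelTriplet(
        channels, {n: like.masks[n].copy() for n in CHANNEL_NAMES},
        ranges if ranges is not None else dict(like.ranges), scaled=True,
    )


def generator_forward(state: GanState, y: ChannelTriplet,
                      stochastic: bool = True) -> ChannelTriplet:
    """Translate an MRI triplet into an sCT triplet (values in [-1, 1]).

    The output carries the input's masks but HU channel ranges, since the
    generated channels are CT-like by construction.  ``stochastic`` keeps the
    dropout noise z active; with it off the output is deterministic.
    """
    out, _ = state.generator.forward(y.stack(), train=stochastic, rng=state.rng)
    hu_ranges = {n: ChannelRanges().range_of(n) for n in CHANNEL_NAMES}
    return _triplet_from_stack(out, y, ranges=hu_ranges)


def discriminator_forward(state: GanState, y: ChannelTriplet,
                          candidate: ChannelTriplet) -> np.ndarray:
    """Patch score map (logits); each pixel judges one receptive-field patch."""
    if y.shape != candidate.shape:
        raise ValueError("conditioning and candidate shapes differ")
    inp = np.concatenate([y.stack(), candidate.stack()])
    out, _ = state.discriminator.forward(inp, train=False, rng=state.rng)
    return out.astype(np.float64)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def loss_l1(sct_slice_hu: np.ndarray, ct_slice_hu: np.ndarray) -> float:
    """Mean absolute HU difference between reassembled slices."""
    a = np.asarray(sct_slice_hu, dtype=np.float64)
    b = np.asarray(ct_slice_hu, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("slice shapes differ")
    return float(np.mean(np.abs(a - b)))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def loss_cgan(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Adversarial cross-entropy -[E log D(y,x) + E log(1 - D(y,G(y,z)))].

    Inputs are patch logit maps; expectations are means over patch pixels.
    Identically-zero logits (D maximally uncertain) give 2 ln 2.
    """
    real = np.asarray(d_real, dtype=np.float64)
    fake = np.asarray(d_fake, dtype=np.float64)
    return float(np.mean(_softplus(-real)) + np.mean(_softplus(fake)))


def loss_total(l1: float, lcgan: float, lam: float = 100.0) -> float:
    """L_tot = L_cGAN + lambda * L1."""
    return lcgan + lam * l1


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _l1_and_grad(fake: np.ndarray, x_trip: ChannelTriplet):
    """HU-space L1 between reassembled fake and target, with d(L1)/d(fake).

    Reassembly is per-channel affine inside each mask (clipping never binds
    because affine images of [-1, 1] are exactly the HU ranges), so the
    gradient is the sign of the HU residual times the channel half-width on
    owned pixels.
    """
    fake_trip = _triplet_from_stack(
        fake, x_trip, ranges={n: ChannelRanges().range_of(n) for n in CHANNEL_NAMES}
    )
    sct_hu = reassemble_slice(fake_trip)
    ct_hu = reassemble_slice(x_trip)
    resid = sct_hu - ct_hu
    npix = resid.size
    l1 = float(np.mean(np.abs(resid)))
    g = np.zeros_like(fake)
    sign = np.sign(resid) / npix
    for i, n in enumerate(CHANNEL_NAMES):
        lo, hi = fake_trip.ranges[n]
        m = x_trip.masks[n]
        g[i][m] = sign[m] * (hi - lo) / 2.0
    return l1, g.astype(nn.DTYPE)


def train(
    dataset: list[tuple[ChannelTriplet, ChannelTriplet]],
    config: GanConfig,
    progress_csv: str | Path | None = None,
) -> GanState:
    """Run the alternating adversarial schedule on (MRI, CT) triplet pairs.

    One discriminator Adam step then one generator Adam step per slice pair,
    for ``config.epochs`` passes in a seeded shuffled order.  The logged
    history records L1 (HU), L_cGAN and their lambda-weighted total at every
    step.  Raises ``RuntimeError`` if a loss turns NaN.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    state = init_state(config)
    lam = config.lambda_l1
    opt_d = nn.Adam(state.discriminator.params(), config.lr_discriminator,
                    config.beta1, config.beta2)
    opt_g = nn.Adam(state.generator.params(), config.lr_generator,
                    config.beta1, config.beta2)
    step = 0
    for epoch in range(config.epochs):
        order = state.rng.permutation(len(dataset))
        for idx in order:
            y_trip, x_trip = dataset[idx]
            y = y_trip.stack().astype(nn.DTYPE)
            x = x_trip.stack().astype(nn.DTYPE)

            fake, gcache = state.generator.forward(y, train=True, rng=state.rng)

            # --- discriminator step ---
            d_real, c_real = state.discriminator.forward(
                np.concatenate([y, x]), train=True, rng=state.rng)
            d_fake, c_fake = state.discriminator.forward(
                np.concatenate([y, fake]), train=True, rng=state.rng)
            lcgan = loss_cgan(d_real, d_fake)
            n_patch = d_real.size
            state.discriminator.backward(
                ((_sigmoid(d_real) - 1.0) / n_patch).astype(nn.DTYPE), c_real)
            state.discriminator.backward(
                (_sigmoid(d_fake) / n_patch).astype(nn.DTYPE), c_fake)
            opt_d.step()
            opt_d.zero_grad()

            # --- generator step (non-saturating adversarial + lambda * L1) ---
            # the adversarial gradient reuses the discriminator pass from just
            # before its own update; still one D step then one G step per pair
            g_inp = state.discriminator.backward(
                ((_sigmoid(d_fake) - 1.0) / n_patch).astype(nn.DTYPE), c_fake)
            opt_d.zero_grad()  # discard D gradients from the G pass
            g_adv = g_inp[config.in_channels:]
            l1, g_l1 = _l1_and_grad(fake, x_trip)
            state.generator.backward(g_adv + lam * g_l1, gcache)
            opt_g.step()
            opt_g.zero_grad()

            ltot = loss_total(l1, lcgan, lam)
            if not np.isfinite(ltot):
                raise RuntimeError(f"NaN/inf loss at step {step}")
            state.history.append(
                {"step": step, "epoch": epoch, "l1": l1, "lcgan": lcgan, "ltot": ltot}
            )
            step += 1
        state.epoch = epoch + 1
    if progress_csv is not None:
        write_history_csv(state.history, progress_csv)
    return state


def write_history_csv(history: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["step", "epoch", "l1", "lcgan", "ltot"])
        writer.writeheader()
        for row in history:
            writer.writerow({k: repr(v) if isinstance(v, float) else v
                             for k, v in row.items()})


# ---------------------------------------------------------------------------
# volume-level prediction
# ---------------------------------------------------------------------------

def predict_volume(
    state: GanState,
    mri: ImageVolume,
    masks: dict[str, np.ndarray],
    stochastic: bool = True,
) -> ImageVolume:
    """Full MRI-to-sCT pipeline for one conditioned MRI volume.

    Per transversal slice: decompose the MRI by the given tissue masks, scale
    to [-1, 1], resize to the network input size, run the generator, rescale
    each channel to its HU range, reassemble through the (resized) masks, and
    finally stack and resize back onto the original MRI grid.  ``masks`` come
    from the conditioned CT in the test scenario or from MRI segmentation in
    the MRI-only scenario.
    """
    if masks is None:
        raise ValueError("tissue masks are required to decompose the MRI")
    size = state.config.size
    triplets = segment_channels(mri, masks=masks)
    slices, bgs = [], []
    for t in triplets:
        t_net = resize_to_net(scale_channels(t, "to_unit"), size)
        fake = generator_forward(state, t_net, stochastic=stochastic)
        slices.append(reassemble_slice(fake))
        bgs.append(~fake.body_mask)
    return stack_volume(slices, mri, background_masks=bgs)


class CganTranslator:
    """fit/predict-style wrapper around the functional training API."""

    def __init__(self, config: GanConfig | None = None):
        self.config = config or GanConfig()
        self.state_: GanState | None = None

    def fit(self, dataset, progress_csv=None) -> "CganTranslator":
        self.state_ = train(dataset, self.config, progress_csv=progress_csv)
        return self

    def predict(self, mri: ImageVolume, masks, stochastic: bool = True) -> ImageVolume:
        if self.state_ is None:
            raise RuntimeError("translator is not fitted")
        return predict_volume(self.state_, mri, masks, stochastic=stochastic)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(state: GanState, path: str | Path) -> None:
    """Single-file archive: config JSON plus every parameter array."""
    arrays = {}
    for tag, net in (("g", state.generator), ("d", state.discriminator)):
        for i, p in enumerate(net.params()):
            arrays[f"{tag}{i}"] = p.value
    meta = json.dumps({"config": asdict(state.config), "epoch": state.epoch})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> GanState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = GanConfig(**meta["config"])
        state = init_state(config)
        for tag, net in (("g", state.generator), ("d", state.discriminator)):
            for i, p in enumerate(net.params()):
                p.value = np.ascontiguousarray(data[f"{tag}{i}"], dtype=nn.DTYPE)
        state.epoch = meta["epoch"]
    return state
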