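"""FPM-Net: a shallow dense-mesh segmentation network for retinal vessels.

The network departs from mirror encoder-decoder designs (U-Net, SegNet):

* an input convolution block extracts low-level edge features ``f_ei``;
* a chain of dense feature down-sampling blocks (DFB-A ... DFB-D) with
  2x2 max-poolings between the first blocks produces enhanced dense
  features ``f_ed``; deep blocks use depth-wise separable convolutions to
  keep the parameter budget small;
* a *shallow* feature up-sampling block (FUB) — strictly fewer learnable
  layers than the down-sampling path — restores resolution, giving
  ``T(f_ed)``;
* ``K = T(f_ed) (c) f_ei`` (depth-wise concatenation), then one convolution
  yields ``K'``;
* a feature-preserving block (FPB) carries near-full-resolution features:
  DFB-A's output ``f_b`` passes through a dilated convolution, then exactly
  three convolutions and one transposed convolution back to full size,
  giving preserved features ``f_p``;
* intermediate features ``f_if`` from DFB-B and DFB-D are channel-reduced
  (1x1 conv), bilinearly upsampled, and
  ``M_dense = K' (c) f_p (c) f_if`` feeds the pixel classification block
  (1x1 bottleneck + per-pixel softmax), trained with dice loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..config import ConfigurationError, NetworkConfig
from .layers import (BatchNorm2d, BilinearUpsample, Conv2d, ConvTranspose2d,
                     DepthwiseConv2d, MaxPool2d, Module, ReLU, Sequential)


class ShapeError(ValueError):
    """Feature-map spatial/shape mismatch."""


def depthwise_concat(*maps: np.ndarray) -> np.ndarray:
    """Depth-wise concatenation: stack feature maps along the channel axis.

    Values are copied, never mixed; channel ``i`` of each input is
    recoverable by slicing the output.
    """
    base = maps[0].shape[2:]
    for m in maps[1:]:
        if m.shape[2:] != base:
            raise ShapeError(
                f"spatial sizes differ: {base} vs {m.shape[2:]}")
    return np.concatenate(maps, axis=1)


def concat_eq1(t_f_ed: np.ndarray, f_ei: np.ndarray) -> np.ndarray:
    """K = T(f_ed) (c) f_ei — up-sampled dense features joined with edges."""
    return depthwise_concat(t_f_ed, f_ei)


def concat_eq2(k_prime: np.ndarray, f_p: Optional[np.ndarray],
               f_if: np.ndarray) -> np.ndarray:
    """M_dense = K' (c) f_p (c) f_if; ``f_p`` is absent when FPB is ablated."""
    if f_p is None:
        return depthwise_concat(k_prime, f_if)
    return depthwise_concat(k_prime, f_p, f_if)


@dataclass
class FeatureBundle:
    """Named intermediate features of one forward pass (all ``(N,C,H,W)``)."""

    f_ei: np.ndarray = None
    f_b: np.ndarray = None
    f_if: np.ndarray = None
    f_ed: np.ndarray = None
    t_f_ed: np.ndarray = None
    f_p: Optional[np.ndarray] = None
    k: np.ndarray = None
    k_prime: np.ndarray = None
    m_dense: np.ndarray = None


@dataclass
class PredictionOutput:
    """Per-pixel class probabilities and the thresholded binary vessel mask."""

    prob_map: np.ndarray  # (H, W, num_classes), rows sum to 1
    mask: np.ndarray      # (H, W) uint8, vessel=1

    threshold: float = 0.5
    features: Optional[FeatureBundle] = None


class ConvBNReLU(Module):
    """conv -> batch norm -> ReLU; optionally depth-wise separable."""

    def __init__(self, c_in, c_out, k, rng, stride=1, dilation=1,
                 separable=False, dtype=np.float32):
        super().__init__()
        mods = []
        if separable:
            mods.append(DepthwiseConv2d(c_in, k, rng, stride=stride,
                                        dilation=dilation, dtype=dtype))
            mods.append(Conv2d(c_in, c_out, 1, rng, dtype=dtype))
        else:
            mods.append(Conv2d(c_in, c_out, k, rng, stride=stride,
                               dilation=dilation, dtype=dtype))
        mods += [BatchNorm2d(c_out, dtype=dtype), ReLU()]
        self.body = self.add_child("body", Sequential(*mods))
        self.separable = separable

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, grad):
        return self.body.backward(grad)

    def conv_layer_count(self) -> int:
        return 2 if self.separable else 1


class DenseBlock(Module):
    """Mesh-connected dense block: every convolution's output is depth-wise
    concatenated onto the input of all later convolutions in the block, and
    the block output is the concatenation of all convolution outputs."""

    def __init__(self, c_in, c_out, n_convs, k, rng, separable=False,
                 dtype=np.float32):
        super().__init__()
        if c_out % n_convs:
            raise ConfigurationError("block channels must divide by convs_per_block")
        self.growth = c_out // n_convs
        self.c_in, self.c_out, self.n_convs = c_in, c_out, n_convs
        self.convs = []
        ch = c_in
        for i in range(n_convs):
            conv = ConvBNReLU(ch, self.growth, k, rng, separable=separable, dtype=dtype)
            self.convs.append(self.add_child(f"conv{i}", conv))
            ch += self.growth
        self._feat_channels = None

    def forward(self, x):
        feats = [x]
        outs = []
        for conv in self.convs:
            inp = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
            o = conv.forward(inp)
            feats.append(o)
            outs.append(o)
        self._feat_channels = [f.shape[1] for f in feats]
        return np.concatenate(outs, axis=1) if len(outs) > 1 else outs[0]

    def backward(self, grad):
        chans = self._feat_channels
        self._feat_channels = None
        # split output gradient back into per-conv chunks
        g_outs = np.split(grad, np.cumsum(chans[1:])[:-1], axis=1) \
            if len(chans) > 2 else [grad]
        acc = [None] * len(chans)  # gradient per feats[] entry
        for j in range(self.n_convs - 1, -1, -1):
            g_o = g_outs[j] if acc[j + 1] is None else g_outs[j] + acc[j + 1]
            g_inp = self.convs[j].backward(g_o)
            pieces = np.split(g_inp, np.cumsum(chans[:j])[:j], axis=1) \
                if j > 0 else [g_inp]
            for t, piece in enumerate(pieces):
                acc[t] = piece if acc[t] is None else acc[t] + piece
        return acc[0]

    def conv_layer_count(self) -> int:
        return sum(c.conv_layer_count() for c in self.convs)


class UpStage(Module):
    """One FUB stage: stride-2 transposed conv + one convolution."""

    def __init__(self, c_in, c_out, k, rng, dtype=np.float32):
        super().__init__()
        self.body = self.add_child("body", Sequential(
            ConvTranspose2d(c_in, c_out, rng, dtype=dtype),
            BatchNorm2d(c_out, dtype=dtype), ReLU(),
            Conv2d(c_out, c_out, k, rng, dtype=dtype),
            BatchNorm2d(c_out, dtype=dtype), ReLU(),
        ))

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, grad):
        return self.body.backward(grad)

    conv_layer_count = staticmethod(lambda: 2)


class FeaturePreservingBlock(Module):
    """Exactly three convolutions followed by one transposed convolution
    restoring the feature map to full input resolution."""

    def __init__(self, channels, k, rng, dtype=np.float32):
        super().__init__()
        self.body = self.add_child("body", Sequential(
            ConvBNReLU(channels, channels, k, rng, dtype=dtype),
            ConvBNReLU(channels, channels, k, rng, dtype=dtype),
            ConvBNReLU(channels, channels, k, rng, dtype=dtype),
            ConvTranspose2d(channels, channels, rng, dtype=dtype),
            BatchNorm2d(channels, dtype=dtype), ReLU(),
        ))

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, grad):
        return self.body.backward(grad)

    def layer_census(self) -> dict[str, int]:
        return {"convolutions": 3, "transposed_convolutions": 1}


def build_fpb(config: NetworkConfig,
              rng: Optional[np.random.Generator] = None,
              dtype=np.float32) -> FeaturePreservingBlock:
    """Construct the FPB subgraph (3 convs + 1 transposed conv)."""
    if not config.use_fpb:
        raise ConfigurationError("build_fpb requires use_fpb=true")
    rng = rng if rng is not None else np.random.default_rng(0)
    return FeaturePreservingBlock(config.fpb_channels, config.kernel_size,
                                  rng, dtype=dtype)


class FPMNet(Module):
    """The assembled network graph. Deterministic given ``config`` and the
    seed of ``rng`` (He-uniform initialization)."""

    def __init__(self, config: NetworkConfig,
                 rng: Optional[np.random.Generator] = None,
                 dtype=np.float32):
        super().__init__()
        config.validate()
        self.config = config
        self.dtype = dtype
        rng = rng if rng is not None else np.random.default_rng(0)
        k = config.kernel_size
        sched = config.fdb_channel_schedule

        # input convolution block -> f_ei (low-level edge features)
        self.input_block = self.add_child("input_block", ConvBNReLU(
            config.input_channels, sched[0], k, rng, dtype=dtype))

        # dense feature down-sampling blocks with interleaved 2x poolings
        self.dfb = []
        self.pools = []
        ch = sched[0]
        for i in range(config.fdb_blocks):
            sep = i >= config.depthwise_separable_from_block
            blk = DenseBlock(ch, sched[i], config.convs_per_block, k, rng,
                             separable=sep, dtype=dtype)
            self.dfb.append(self.add_child(f"dfb{i}", blk))
            ch = sched[i]
        for i in range(config.pooling_ops):
            self.pools.append(self.add_child(f"pool{i}", MaxPool2d()))

        # shallow up-sampling path (FUB): pooling_ops stride-2 stages
        self.fub_stages = []
        ch = sched[-1]
        for i, c_out in enumerate(config.fub_channel_schedule):
            st = UpStage(ch, c_out, k, rng, dtype=dtype)
            self.fub_stages.append(self.add_child(f"fub{i}", st))
            ch = c_out
        self.t_channels = ch

        # K' — one convolution on the Eq (1) concatenation
        self.kprime_conv = self.add_child("kprime_conv", ConvBNReLU(
            self.t_channels + sched[0], self.t_channels, k, rng, dtype=dtype))

        # f_if routing: 1x1 reduction + bilinear upsampling per source block
        n = config.fdb_blocks
        self.fif_sources = sorted({min(1, n - 1), n - 1})
        self.fif_reducers = []
        self.fif_upsamplers = []
        for idx in self.fif_sources:
            red = ConvBNReLU(sched[idx], config.fif_channels, 1, rng, dtype=dtype)
            self.fif_reducers.append(self.add_child(f"fif_reduce{idx}", red))
            factor = 2 ** min(idx, config.pooling_ops)
            self.fif_upsamplers.append(self.add_child(
                f"fif_up{idx}", BilinearUpsample(factor)))

        # FPB branch: dilated stride-2 convolution feeding the FPB
        if config.use_fpb:
            self.dilated_conv = self.add_child("dilated_conv", ConvBNReLU(
                sched[0], config.fpb_channels, k, rng, stride=2,
                dilation=config.dilation_rate, dtype=dtype))
            self.fpb = self.add_child("fpb", build_fpb(config, rng, dtype=dtype))
        else:
            self.dilated_conv = None
            self.fpb = None

        # pixel classification block: 1x1 bottleneck to the class channels
        fif_total = config.fif_channels * len(self.fif_sources)
        m_ch = self.t_channels + fif_total
        if config.use_fpb:
            m_ch += config.fpb_channels
        self.pcb = self.add_child("pcb", Conv2d(
            m_ch, config.bottleneck_channels, 1, rng, dtype=dtype))

        self._cache = None

    # ---------------------------------------------------------------- forward
    def forward_features(self, x: np.ndarray) -> tuple[np.ndarray, FeatureBundle]:
        """Run the graph on a batch ``(N, C, H, W)``; return logits + bundle."""
        cfg = self.config
        if x.shape[1:] != (cfg.input_channels, cfg.input_height, cfg.input_width):
            raise ShapeError(
                f"input shape {x.shape[1:]} does not match configured "
                f"({cfg.input_channels}, {cfg.input_height}, {cfg.input_width})")
        fb = FeatureBundle()
        fb.f_ei = self.input_block.forward(x)
        h = fb.f_ei
        block_outs = []
        for i, blk in enumerate(self.dfb):
            if 1 <= i <= cfg.pooling_ops:
                h = self.pools[i - 1].forward(h)
            h = blk.forward(h)
            block_outs.append(h)
        fb.f_b = block_outs[0]
        fb.f_ed = block_outs[-1]

        h = fb.f_ed
        for st in self.fub_stages:
            h = st.forward(h)
        fb.t_f_ed = h

        fb.k = concat_eq1(fb.t_f_ed, fb.f_ei)
        fb.k_prime = self.kprime_conv.forward(fb.k)

        fif_parts = []
        for red, up, idx in zip(self.fif_reducers, self.fif_upsamplers,
                                self.fif_sources):
            fif_parts.append(up.forward(red.forward(block_outs[idx])))
        fb.f_if = depthwise_concat(*fif_parts) if len(fif_parts) > 1 else fif_parts[0]

        if cfg.use_fpb:
            fb.f_p = self.fpb.forward(self.dilated_conv.forward(fb.f_b))

        fb.m_dense = concat_eq2(fb.k_prime, fb.f_p, fb.f_if)
        logits = self.pcb.forward(fb.m_dense)
        self._cache = {"n_blocks": len(block_outs)}
        return logits, fb

    def backward_from_logits(self, grad_logits: np.ndarray) -> None:
        """Route the loss gradient back through the whole mesh."""
        cfg = self.config
        g_m = self.pcb.backward(grad_logits)
        c_kp = self.t_channels
        c_fp = cfg.fpb_channels if cfg.use_fpb else 0
        g_kprime = g_m[:, :c_kp]
        g_fp = g_m[:, c_kp:c_kp + c_fp] if cfg.use_fpb else None
        g_fif = g_m[:, c_kp + c_fp:]

        n_blocks = cfg.fdb_blocks
        block_grads: list[Optional[np.ndarray]] = [None] * n_blocks

        # f_if branch
        splits = np.split(g_fif, len(self.fif_sources), axis=1) \
            if len(self.fif_sources) > 1 else [g_fif]
        for g, red, up, idx in zip(splits, self.fif_reducers,
                                   self.fif_upsamplers, self.fif_sources):
            gb = red.backward(up.backward(g))
            block_grads[idx] = gb if block_grads[idx] is None \
                else block_grads[idx] + gb

        # FPB branch back to DFB-A
        if cfg.use_fpb:
            gb = self.dilated_conv.backward(self.fpb.backward(g_fp))
            block_grads[0] = gb if block_grads[0] is None else block_grads[0] + gb

        # K' -> K -> (T(f_ed), f_ei)
        g_k = self.kprime_conv.backward(g_kprime)
        g_t = g_k[:, :self.t_channels]
        g_fei = g_k[:, self.t_channels:].copy()

        g = g_t
        for st in reversed(self.fub_stages):
            g = st.backward(g)
        block_grads[-1] = g if block_grads[-1] is None else block_grads[-1] + g

        # down-sampling chain in reverse
        g = None
        for i in range(n_blocks - 1, -1, -1):
            g_blk = block_grads[i] if g is None else block_grads[i] + g \
                if block_grads[i] is not None else g
            g = self.dfb[i].backward(g_blk)
            if 1 <= i <= cfg.pooling_ops:
                g = self.pools[i - 1].backward(g)
        g_fei = g_fei + g
        self.input_block.backward(g_fei)
        self._cache = None

    def forward(self, x):
        logits, _ = self.forward_features(x)
        return logits

    def predict(self, image: np.ndarray, threshold: float = 0.5,
                return_features: bool = False) -> PredictionOutput:
        """Inference on one RGB image ``(H, W, 3)`` in [0, 1].

        The vessel mask is 1 where the vessel-class probability meets the
        decision threshold (ties count as vessel).
        """
        was_training = self.training
        self.set_training(False)
        try:
            x = np.ascontiguousarray(
                image.transpose(2, 0, 1)[None].astype(self.dtype))
            logits, fb = self.forward_features(x)
        finally:
            self.set_training(was_training)
        z = logits[0].astype(np.float64)
        z -= z.max(axis=0, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=0, keepdims=True)  # (2, H, W)
        prob_map = probs.transpose(1, 2, 0)
        mask = (prob_map[:, :, 1] >= threshold).astype(np.uint8)
        return PredictionOutput(prob_map=prob_map, mask=mask,
                                threshold=threshold,
                                features=fb if return_features else None)

    # ------------------------------------------------------------- accounting
    def fdb_conv_layer_count(self) -> int:
        return (self.input_block.conv_layer_count()
                + sum(b.conv_layer_count() for b in self.dfb))

    def fub_conv_layer_count(self) -> int:
        return sum(s.conv_layer_count() for s in self.fub_stages)

    def parameter_census(self) -> dict[str, int]:
        """Trainable parameter totals per named submodule."""
        census: dict[str, int] = {}
        for name, child in self._children.items():
            census[name] = child.num_parameters()
        return census


def build_network(config: NetworkConfig, seed: int = 0,
                  dtype=np.float32) -> FPMNet:
    """Build the FPM-Net graph deterministically from a config and seed."""
    return FPMNet(config, np.random.default_rng(seed), dtype=dtype)


def count_parameters(net: FPMNet) -> int:
    """Total trainable scalars: conv/tconv weights and biases plus batch-norm
    scale/shift (running statistics are not trainable)."""
    return net.num_parameters()
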