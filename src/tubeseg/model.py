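"""The UARAI segmentation network.

A 3D U-Net in which pooling is replaced by learned stride-2 convolutions,
every stage carries an additive residual shortcut, and three optional
components refine the decoder:

* MSFA — multi-scale feature aggregation: the three deepest encoder
  features (f3 at 1/4 resolution with 4C channels, f2 at 1/8 with 8C, f1 at
  1/16 with 16C) are fused by learned stride-2 downsamplers D (which double
  channels) and elementwise products into a single-channel deep map fmf:

      x2_1 = D(f3) * f2
      x2_2 = Conv3[concat(x2_1, D(f3))]
      x3_1 = D(D(f3)) * D(f2) * f1
      x3_2 = Conv3[D(x2_2)]
      fmf  = Conv1{Conv3(Conv3[concat(x3_1, x3_2)])}

* Reverse attention — coefficients R = 1 - sigmoid(logits) that erase
  already-confident foreground and up-weight background/edges. R1 comes
  from fmf; deeper-to-shallower stages propagate the coefficient: the
  weighted feature of the previous stage is restored to one channel by a
  1x1x1 conv, convolved, summed with the previous coefficient, upsampled
  and re-squashed. Coefficients are broadcast across the skip's channels
  (MR) and multiply the skip feature before decoding.

* Inception sparse convolution — four parallel two-layer branches of
  convolutions with different kernel sizes/dilations, fused channel-wise;
  used on the attention path (and on fmf) to widen the receptive field at
  small parameter cost.

The network outputs a 2-channel softmax (background, foreground) at input
resolution, fusing the last three decoder levels. Input spatial dimensions
must be divisible by 16 (four halvings).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    Conv3d,
    Dropout,
    InstanceNorm3d,
    LeakyReLU,
    Module,
    Sequential,
    Tensor,
    Upsample2x,
    concat,
    no_grad,
)
from .volume_io import ValidationError

# (kernel, dilation) pairs for the two layers of each inception branch
DEFAULT_INCEPTION_SPEC = (
    ((1, 1), (3, 1)),
    ((3, 1), (3, 1)),
    ((3, 2), (3, 2)),
    ((3, 3), (3, 3)),
)


@dataclass
class ModelConfig:
    base_channels: int = 8
    depth: int = 4                  # encode/decode stages (fixed)
    dropout: float = 0.3
    leaky_slope: float = 0.01
    inception_spec: tuple = DEFAULT_INCEPTION_SPEC
    inception_width: int = 4
    msfa: bool = True
    ra: bool = True
    icp: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.base_channels < 1:
            raise ValidationError("base_channels must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must be in [0, 1)")
        if self.depth != 4:
            raise ValidationError("depth is fixed at 4 encode/decode stages")
        if self.icp and not (self.msfa or self.ra):
            raise ValidationError(
                "icp has no site without msfa or ra; enable one of them"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inception_spec"] = [list(map(list, b)) for b in self.inception_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "inception_spec" in d:
            d["inception_spec"] = tuple(
                tuple(tuple(l) for l in b) for b in d["inception_spec"]
            )
        return cls(**d)


def _cbl(cin, cout, rng, slope, stride=1):
    """conv -> instance norm -> leaky ReLU (conv bias off: IN cancels it)."""
    return Sequential(
        Conv3d(cin, cout, 3, stride=stride, bias=False, rng=rng),
        InstanceNorm3d(cout),
        LeakyReLU(slope),
    )


class ResidualStage(Module):
    """Two conv blocks with an additive shortcut (1x1x1 projection when the
    channel count changes), optional dropout on each block."""

    def __init__(self, cin, cout, rng, slope, dropout=0.0, drop_rng=None):
        super().__init__()
        self.block1 = _cbl(cin, cout, rng, slope)
        self.block2 = Sequential(
            Conv3d(cout, cout, 3, bias=False, rng=rng), InstanceNorm3d(cout)
        )
        self.proj = (
            Conv3d(cin, cout, 1, bias=False, rng=rng) if cin != cout else None
        )
        self.act = LeakyReLU(slope)
        self.drop1 = Dropout(dropout, drop_rng)
        self.drop2 = Dropout(dropout, drop_rng)

    def forward(self, x):
        h = self.drop1(self.block1(x))
        h = self.drop2(self.block2(h))
        s = self.proj(x) if self.proj is not None else x
        return self.act(h + s)


class Downsample(Module):
    """Learned stride-2 3x3x3 conv halving spatial dims, doubling channels."""

    def __init__(self, cin, rng, slope):
        super().__init__()
        self.op = _cbl(cin, 2 * cin, rng, slope, stride=2)

    def forward(self, x):
        return self.op(x)


class InceptionBlock(Module):
    """Four two-layer branches with differing kernels/dilations, channel
    concatenation, and a 1x1x1 fusion conv. Spatial dims preserved."""

    def __init__(self, cin, cout, spec, width, rng, slope):
        super().__init__()
        self.branches = []
        for bi, branch in enumerate(spec):
            layers = []
            c = cin
            for (k, d) in branch:
                layers += [Conv3d(c, width, k, dilation=d, rng=rng), LeakyReLU(slope)]
                c = width
            b = Sequential(*layers)
            setattr(self, f"branch{bi}", b)
            self.branches.append(b)
        self.fuse = Conv3d(width * len(spec), cout, 1, rng=rng)

    def forward(self, x):
        return self.fuse(concat([b(x) for b in self.branches], axis=1))


class MSFA(Module):
    """Multi-scale feature aggregation producing the 1-channel deep map."""

    def __init__(self, c, rng, slope):
        super().__init__()
        # learned downsamplers (double channels so products are well-typed)
        self.d_f3_a = Downsample(4 * c, rng, slope)     # f3: 4C/4 -> 8C/8
        self.d_f3_b = Downsample(8 * c, rng, slope)     # D(f3) -> 16C/16
        self.d_f2 = Downsample(8 * c, rng, slope)       # f2: 8C/8 -> 16C/16
        self.conv_x22 = _cbl(16 * c, 8 * c, rng, slope)
        self.d_x22 = Downsample(8 * c, rng, slope)      # x2_2 -> 16C/16
        self.conv_x32 = _cbl(16 * c, 16 * c, rng, slope)
        self.fuse1 = _cbl(32 * c, 16 * c, rng, slope)
        self.fuse2 = _cbl(16 * c, 8 * c, rng, slope)
        self.out = Conv3d(8 * c, 1, 1, rng=rng)

    def forward(self, f3, f2, f1):
        df3 = self.d_f3_a(f3)
        x2_1 = df3 * f2
        x2_2 = self.conv_x22(concat([x2_1, df3], axis=1))
        x3_1 = self.d_f3_b(df3) * self.d_f2(f2) * f1
        x3_2 = self.conv_x32(self.d_x22(x2_2))
        return self.out(self.fuse2(self.fuse1(concat([x3_1, x3_2], axis=1))))


class RAStage(Module):
    """One reverse-attention decoder stage.

    Stage 1 squashes the carried deep map into R1 = 1 - sigmoid(Icp(fmf)).
    Later stages propagate: restore the previous weighted feature to one
    channel (1x1x1), conv 3x3x3, add the previous coefficient, mix (1x1x1),
    upsample x2, Icp, 1 - sigmoid.
    """

    def __init__(self, prev_channels, rng, slope, icp, spec, width, first=False):
        super().__init__()
        self.first = first
        if not first:
            self.restore = Conv3d(prev_channels, 1, 1, rng=rng)
            self.prop = Conv3d(1, 1, 3, rng=rng)
            self.mix = Conv3d(1, 1, 1, rng=rng)
        self.up = Upsample2x()
        if icp:
            self.squash = InceptionBlock(1, 1, spec, width, rng, slope)
        else:
            self.squash = Conv3d(1, 1, 3, rng=rng)

    def coefficient(self, carry, w_prev, r_prev):
        if self.first:
            logits = self.squash(carry)
        else:
            s = self.prop(self.restore(w_prev)) + r_prev
            logits = self.squash(self.up(self.mix(s)))
        return 1.0 - logits.sigmoid()


class UARAI(Module):
    """Full network; see module docstring for the architecture."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        c = cfg.base_channels
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
        drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        sl = cfg.leaky_slope

        # ----- encoder: C, 2C, 4C, 8C at /1../8, bottleneck 16C at /16
        self.enc0 = ResidualStage(1, c, rng, sl)
        self.down0 = Downsample(c, rng, sl)
        self.enc1 = ResidualStage(2 * c, 2 * c, rng, sl)
        self.down1 = Downsample(2 * c, rng, sl)
        self.enc2 = ResidualStage(4 * c, 4 * c, rng, sl)
        self.down2 = Downsample(4 * c, rng, sl)
        self.enc3 = ResidualStage(8 * c, 8 * c, rng, sl)
        self.down3 = Downsample(8 * c, rng, sl)
        self.bottleneck = ResidualStage(
            16 * c, 16 * c, rng, sl, dropout=cfg.dropout, drop_rng=drop_rng
        )

        if cfg.msfa:
            self.msfa_mod = MSFA(c, rng, sl)
            if cfg.icp:
                self.fmf_icp = InceptionBlock(
                    1, 1, cfg.inception_spec, cfg.inception_width, rng, sl
                )
            # without reverse attention fmf gates the deepest skip
            # multiplicatively (parameter-free), see forward()

        if cfg.ra and not cfg.msfa:
            self.carry = Conv3d(16 * c, 1, 1, rng=rng)

        # ----- decoder: skip-fusion convs and up-convs
        skip_ch = [16 * c, 8 * c, 4 * c, 2 * c]
        self.skip_fuse = []
        self.dec = []
        for i, s in enumerate(skip_ch):
            if i > 0:
                f = _cbl(2 * s, s, rng, sl)  # concat(d_prev, enc skip) -> s
                setattr(self, f"skip_fuse{i}", f)
                self.skip_fuse.append(f)
            d = _cbl(s, s // 2, rng, sl)
            setattr(self, f"dec{i}", d)
            self.dec.append(d)
        self.full_fuse = _cbl(2 * c, c, rng, sl)  # concat(d4, enc0) -> C

        if cfg.ra:
            self.ra_stages = []
            prev = [None, 16 * c, 8 * c, 4 * c]
            for i in range(4):
                st = RAStage(
                    prev[i], rng, sl, cfg.icp, cfg.inception_spec,
                    cfg.inception_width, first=(i == 0),
                )
                setattr(self, f"ra{i}", st)
                self.ra_stages.append(st)

        # ----- output head: fuse last three decoder levels at full res
        self.head_fuse = _cbl(4 * c + 2 * c + c, c, rng, sl)
        self.head_out = Conv3d(c, 2, 1, rng=rng)
        # class-prior initialization: tubular foreground occupies a few
        # percent of voxels, so start the softmax heavily background-biased
        self.head_out.bias.data[:] = [1.5, -1.5]
        self.upsample = Upsample2x()

    # ------------------------------------------------------------ pieces
    def msfa_forward(self, f3, f2, f1):
        if not self.cfg.msfa:
            raise ValidationError("msfa is disabled in this configuration")
        fmf = self.msfa_mod(f3, f2, f1)
        if self.cfg.icp:
            fmf = self.fmf_icp(fmf)
        return fmf

    def inception_forward(self, x):
        if not self.cfg.icp:
            raise ValidationError("icp is disabled in this configuration")
        mod = self.fmf_icp if self.cfg.msfa else self.ra_stages[0].squash
        return mod(x)

    def reverse_attention_step(self, i, carry=None, w_prev=None, r_prev=None,
                               skip=None):
        """Compute (decoder feature, R_i) for decoder stage i (0-based)."""
        st = self.ra_stages[i]
        r = st.coefficient(carry, w_prev, r_prev)
        w = skip * r  # MR_i: coefficient broadcast across skip channels
        d = self.dec[i](self.upsample(w))
        return d, r, w

    def encode(self, x):
        e0 = self.enc0(x)
        e1 = self.enc1(self.down0(e0))
        e2 = self.enc2(self.down1(e1))          # f3: 4C at /4
        e3 = self.enc3(self.down2(e2))          # f2: 8C at /8
        f1 = self.bottleneck(self.down3(e3))    # f1: 16C at /16
        return e0, e1, e2, e3, f1

    # ------------------------------------------------------------ forward
    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 4:
            x = x.reshape((1,) + x.shape)
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValidationError(
                f"expected input (N, 1, X, Y, Z), got {x.shape}"
            )
        if any(s % 16 != 0 for s in x.shape[2:]):
            raise ValidationError(
                f"spatial dims {x.shape[2:]} must be divisible by 16"
            )
        e0, e1, e2, e3, f1 = self.encode(x)
        f3, f2 = e2, e3

        fmf = self.msfa_forward(f3, f2, f1) if self.cfg.msfa else None

        skips = [f1, e3, e2, e1]
        decs = []
        if self.cfg.ra:
            carry = fmf if self.cfg.msfa else self.carry(f1)
            w_prev = r_prev = None
            d = None
            for i in range(4):
                skip = skips[i]
                if i > 0:
                    skip = self.skip_fuse[i - 1](concat([d, skip], axis=1))
                st = self.ra_stages[i]
                r = st.coefficient(carry if i == 0 else None, w_prev, r_prev)
                w = skip * r
                d = self.dec[i](self.upsample(w))
                decs.append(d)
                w_prev, r_prev = w, r
        else:
            skip0 = skips[0]
            if self.cfg.msfa:
                skip0 = skip0 * fmf.sigmoid()
            d = self.dec[0](self.upsample(skip0))
            decs.append(d)
            for i in range(1, 4):
                skip = self.skip_fuse[i - 1](concat([d, skips[i]], axis=1))
                d = self.dec[i](self.upsample(skip))
                decs.append(d)

        d4 = self.full_fuse(concat([decs[3], e0], axis=1))
        # final three decoder levels -> full resolution -> fused
        u2 = self.upsample(self.upsample(decs[1]))  # 4C from /4
        u3 = self.upsample(decs[2])                 # 2C from /2
        fused = self.head_fuse(concat([u2, u3, d4], axis=1))
        return self.head_out(fused).softmax(axis=1)


def build_model(cfg: ModelConfig) -> UARAI:
    return UARAI(cfg)


def save_checkpoint(model: UARAI, path) -> None:
    """Single-file archive holding weights and the exact ModelConfig."""
    state = model.state_dict()
    np.savez(
        Path(path),
        __config__=np.frombuffer(
            json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8
        ),
        **state,
    )


def load_checkpoint(path) -> UARAI:
    with np.load(Path(path)) as f:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(f["__config__"].tobytes()).decode())
        )
        state = {k: f[k] for k in f.files if k != "__config__"}
    model = build_model(cfg)
    model.load_state_dict(state)
    return model
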