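"""Two-channel residual regression network (18-layer layout).

Stem: 7x7/stride-2 convolution + batch norm + ReLU + 3x3/stride-2 max
pool; four residual stages of two basic blocks each with base widths
64/128/256/512 (scaled by ``width_multiplier``); global average pooling
and a single linear output with no activation — the score head is a
plain regressor of the IoU.
"""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, BatchNorm2d, Conv2d, GlobalAvgPool, Linear, MaxPool2d, ReLU

__all__ = ["BasicBlock", "ResNetRegressor"]


class BasicBlock:
    """conv3-bn-relu-conv3-bn plus an (optionally projected) skip."""

    def __init__(self, cin: int, cout: int, stride: int, rng):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        if stride != 1 or cin != cout:
            self.proj_conv = Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj_conv = None
            self.proj_bn = None

    def modules(self):
        mods = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2]
        if self.proj_conv is not None:
            mods += [self.proj_conv, self.proj_bn]
        return mods

    def params(self):
        return [p for m in self.modules() for p in m.params()]

    def forward(self, x, train=True):
        out = self.conv1.forward(x, train)
        out = self.bn1.forward(out, train)
        out = self.relu1.forward(out, train)
        out = self.conv2.forward(out, train)
        out = self.bn2.forward(out, train)
        if self.proj_conv is not None:
            short = self.proj_bn.forward(self.proj_conv.forward(x, train), train)
        else:
            short = x
        return self.relu2.forward(out + short, train)

    def backward(self, dy):
        d = self.relu2.backward(dy)
        dshort = d
        dout = self.bn2.backward(d)
        dout = self.conv2.backward(dout)
        dout = self.relu1.backward(dout)
        dout = self.bn1.backward(dout)
        dx = self.conv1.backward(dout)
        if self.proj_conv is not None:
            dx = dx + self.proj_conv.backward(self.proj_bn.backward(dshort))
        else:
            dx = dx + dshort
        return dx


class ResNetRegressor:
    """The full network; ``forward`` maps (N, 2, H, W) -> (N,) scores."""

    BASE_WIDTHS = (64, 128, 256, 512)

    def __init__(
        self,
        in_channels: int = 2,
        width_multiplier: float = 1.0,
        depth: tuple = (2, 2, 2, 2),
        rng: np.random.Generator | None = None,
    ):
        if not 0.0 < width_multiplier <= 1.0:
            raise ValueError(f"width_multiplier must be in (0, 1], got {width_multiplier}")
        if len(depth) != 4 or any(d < 1 for d in depth):
            raise ValueError(f"depth must be four positive block counts, got {depth}")
        rng = rng or np.random.default_rng()
        widths = [max(4, int(round(w * width_multiplier))) for w in self.BASE_WIDTHS]
        self.widths = widths
        self.stem_conv = Conv2d(in_channels, widths[0], 7, stride=2, rng=rng)
        self.stem_bn = BatchNorm2d(widths[0])
        self.stem_relu = ReLU()
        self.pool = MaxPool2d(3, 2, 1)
        self.stages: list[list[BasicBlock]] = []
        cin = widths[0]
        for stage_idx, (w, nblocks) in enumerate(zip(widths, depth)):
            blocks = []
            for b in range(nblocks):
                stride = 2 if (stage_idx > 0 and b == 0) else 1
                blocks.append(BasicBlock(cin, w, stride, rng))
                cin = w
            self.stages.append(blocks)
        self.gap = GlobalAvgPool()
        self.fc = Linear(widths[-1], 1, rng=rng)

    # -- plumbing ----------------------------------------------------------
    def _modules(self):
        mods = [self.stem_conv, self.stem_bn, self.stem_relu, self.pool]
        for blocks in self.stages:
            for blk in blocks:
                mods.extend(blk.modules())
        mods += [self.gap, self.fc]
        return mods

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        out = self.stem_conv.forward(x, train)
        out = self.stem_bn.forward(out, train)
        out = self.stem_relu.forward(out, train)
        out = self.pool.forward(out, train)
        for blocks in self.stages:
            for blk in blocks:
                out = blk.forward(out, train)
        out = self.gap.forward(out, train)
        return self.fc.forward(out, train)[:, 0]

    def backward(self, dscore: np.ndarray) -> None:
        d = self.fc.backward(np.asarray(dscore, dtype=DTYPE)[:, None])
        d = self.gap.backward(d)
        for blocks in reversed(self.stages):
            for blk in reversed(blocks):
                d = blk.backward(d)
        d = self.pool.backward(d)
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        self.stem_conv.backward(d)

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, m in enumerate(self._modules()):
            for j, p in enumerate(m.params()):
                state[f"m{i}.p{j}"] = p.data.copy()
            if isinstance(m, BatchNorm2d):
                state[f"m{i}.running_mean"] = m.running_mean.copy()
                state[f"m{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self._modules()):
            for j, p in enumerate(m.params()):
                key = f"m{i}.p{j}"
                if state[key].shape != p.data.shape:
                    raise ValueError(
                        f"checkpoint shape mismatch at {key}: "
                        f"{state[key].shape} vs {p.data.shape}"
                    )
                p.data = np.ascontiguousarray(state[key], dtype=DTYPE)
                p.grad = np.zeros_like(p.data)
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.ascontiguousarray(state[f"m{i}.running_mean"], dtype=DTYPE)
                m.running_var = np.ascontiguousarray(state[f"m{i}.running_var"], dtype=DTYPE)
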