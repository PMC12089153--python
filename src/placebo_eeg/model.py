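"""The 8-block 1-D convolutional placebo-response classifier.

Each block is convolution -> batch normalization -> ReLU; blocks are named
``L1`` .. ``L8`` so late layers can be frozen individually during
fine-tuning.  After the blocks, pooling over time (global average by
default, adaptive max as an alternative) collapses the feature map to one
vector per segment, and a linear head emits a single logit.

The input contract is a ``[B x 19 x 2000]`` batch: 19 channels of the 10-20
montage, 2000 time points per segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .core import N_CHANNELS, SEGMENT_SAMPLES

N_BLOCKS = 8

#: (out_channels, kernel, stride) per block; sized so a full training epoch
#: stays cheap on one CPU while retaining a ~16x temporal reduction path.
DEFAULT_BLOCKS: tuple[tuple[int, int, int], ...] = (
    (8, 7, 2), (16, 7, 2), (16, 7, 2), (32, 7, 2),
    (32, 7, 2), (64, 7, 2), (64, 7, 2), (128, 7, 2),
)

#: Even smaller stack for smoke-profile runs.
SMOKE_BLOCKS: tuple[tuple[int, int, int], ...] = (
    (8, 7, 2), (8, 7, 2), (12, 7, 2), (12, 7, 2),
    (16, 7, 2), (16, 7, 2), (24, 7, 2), (24, 7, 2),
)


@dataclass
class ModelSpec:
    """Architecture description: exactly eight conv blocks plus the head."""

    blocks: tuple[tuple[int, int, int], ...] = DEFAULT_BLOCKS
    pooling: str = "global_average"  # or "adaptive_max"
    init_seed: int = 0
    n_channels: int = N_CHANNELS
    n_samples: int = SEGMENT_SAMPLES

    def validate(self) -> None:
        if len(self.blocks) != N_BLOCKS:
            raise ValueError(f"spec must define exactly {N_BLOCKS} conv blocks, got {len(self.blocks)}")
        if self.pooling not in ("global_average", "adaptive_max"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        length = self.n_samples
        for i, (c_out, kernel, stride) in enumerate(self.blocks, start=1):
            if c_out < 1 or kernel < 1 or stride < 1:
                raise ValueError(f"block L{i} has non-positive dimensions: {(c_out, kernel, stride)}")
            length = (length + 2 * (kernel // 2) - kernel) // stride + 1
            if length < 1:
                raise ValueError(
                    f"temporal length collapses to {length} at block L{i}; "
                    f"reduce strides for {self.n_samples}-sample input"
                )

    def to_dict(self) -> dict:
        return {
            "blocks": [list(b) for b in self.blocks],
            "pooling": self.pooling,
            "init_seed": self.init_seed,
            "n_channels": self.n_channels,
            "n_samples": self.n_samples,
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        return ModelSpec(
            blocks=tuple(tuple(b) for b in d["blocks"]),
            pooling=d["pooling"],
            init_seed=int(d["init_seed"]),
            n_channels=int(d.get("n_channels", N_CHANNELS)),
            n_samples=int(d.get("n_samples", SEGMENT_SAMPLES)),
        )


class Model:
    """Runnable network with named parameter groups L1..L8 and ``head``."""

    def __init__(self, spec: ModelSpec):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(spec.init_seed)
        self.layers: list[tuple[str, nn.Layer]] = []
        c_in = spec.n_channels
        for i, (c_out, kernel, stride) in enumerate(spec.blocks, start=1):
            self.layers.append((f"L{i}.conv", nn.Conv1d(c_in, c_out, kernel, stride, rng)))
            self.layers.append((f"L{i}.bn", nn.BatchNorm1d(c_out)))
            self.layers.append((f"L{i}.relu", nn.ReLU()))
            c_in = c_out
        pool = nn.GlobalAveragePool() if spec.pooling == "global_average" else nn.GlobalMaxPool()
        self.layers.append(("pool", pool))
        self.head = nn.Linear(c_in, 1, rng)
        self.training = True

    # --- mode & parameter plumbing -----------------------------------------

    def train_mode(self, frozen_blocks: set[str] | frozenset[str] = frozenset()) -> None:
        """Enter training mode; frozen blocks stay in eval mode so neither
        their parameters nor their batch-norm running stats can change."""
        self.training = True
        for name, layer in self.layers:
            layer.training = name.split(".")[0] not in frozen_blocks
        self.head.training = "head" not in frozen_blocks

    def eval_mode(self) -> None:
        self.training = False
        for _, layer in self.layers:
            layer.training = False
        self.head.training = False

    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for pname, p in layer.params.items():
                out[f"{name}.{pname}"] = p
        for pname, p in self.head.params.items():
            out[f"head.{pname}"] = p
        return out

    def named_buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for bname, b in layer.buffers.items():
                out[f"{name}.{bname}"] = b
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for pname, g in layer.grads.items():
                out[f"{name}.{pname}"] = g
        for pname, g in self.head.grads.items():
            out[f"head.{pname}"] = g
        return out

    def param_group(self, name: str) -> dict[str, np.ndarray]:
        """All parameters of one block (``L1``..``L8``) or ``head``."""
        return {k: v for k, v in self.named_params().items() if k.split(".")[0] == name}

    # --- forward / backward -------------------------------------------------

    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim != 3 or batch.shape[1:] != (self.spec.n_channels, self.spec.n_samples):
            raise ValueError(
                f"expected batch of shape [B x {self.spec.n_channels} x {self.spec.n_samples}], "
                f"got {batch.shape}"
            )
        return batch

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Logits, one per segment: [B x 19 x 2000] -> [B]."""
        x = self._check_batch(batch)
        for _, layer in self.layers:
            x = layer.forward(x)
        return self.head.forward(x)[:, 0]

    def backward(self, dlogits: np.ndarray, stop_block: str | None = None) -> None:
        """Backpropagate; with ``stop_block`` the pass ends after that block's
        convolution (everything earlier is frozen, so its gradients are never
        consumed)."""
        dx = self.head.backward(np.asarray(dlogits, dtype=np.float32)[:, None])
        for name, layer in reversed(self.layers):
            dx = layer.backward(dx)
            if stop_block is not None and name == f"{stop_block}.conv":
                break

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Sigmoid of the logits, in (0, 1)."""
        return nn.sigmoid(self.forward(batch))

    def predict_logits_batched(self, data: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Eval-mode logits over an arbitrary number of segments."""
        self.eval_mode()
        outs = [self.forward(data[i : i + batch_size]) for i in range(0, len(data), batch_size)]
        return np.concatenate(outs) if outs else np.zeros(0)

    # --- checkpointing -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.named_params().items()}
        state.update({f"buffer::{k}": v.copy() for k, v in self.named_buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        buffers = self.named_buffers()
        for k, v in state.items():
            if k.startswith("buffer::"):
                buffers[k[len("buffer::"):]][...] = v
            else:
                params[k][...] = v

    def save(self, path: str | Path) -> None:
        """Native .npz checkpoint plus a JSON sidecar holding the spec."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(self.spec.to_dict(), indent=2))

    @staticmethod
    def load(path: str | Path) -> "Model":
        path = Path(path)
        spec = ModelSpec.from_dict(json.loads(path.with_suffix(".json").read_text()))
        model = Model(spec)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def build(spec: ModelSpec | None = None) -> Model:
    """Construct a model; deterministic for a given spec (incl. init_seed)."""
    return Model(spec or ModelSpec())
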