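"""Model zoo: MLP, single-task transformer, multitask transformer.

The transformer path maps each of the 31 window tokens through a dense
"embedding" layer, adds the canonical sinusoidal positional encoding, runs
pre-norm encoder blocks with multi-head self-attention, flattens the 31
post-attention token vectors, and scores through a dense classification
head ending in a sigmoid. The multitask variant shares everything up to the
flatten and owns one head per PTM task; only the head matching the queried
task is evaluated.

Pad positions are masked out of attention (keys) and their token rows are
zeroed both at the input and before the flatten, so scores are exactly
invariant to pad-row content.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .embeddings import EmbeddedWindow
from .records import PTM_TASKS, ValidationError

#: Key under which a single-task model's lone head is stored.
SINGLE_TASK = "single"


def sinusoidal_positional_encoding(context: int, width: int) -> np.ndarray:
    """Canonical fixed positional encoding.

    PE[pos, 2i] = sin(pos / 10000^(2i/width)),
    PE[pos, 2i+1] = cos(pos / 10000^(2i/width)), with pos 0-based.
    """
    if width % 2 != 0:
        raise ValidationError(f"encoding width must be even, got {width}")
    pos = np.arange(context)[:, None]
    i = np.arange(width // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / width)
    pe = np.zeros((context, width))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


@dataclass(frozen=True)
class MLPSpec:
    """A dense classifier over a single pooled embedding vector."""

    input_dim: int
    hidden_widths: tuple[int, ...]
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if not self.hidden_widths:
            raise ValidationError("hidden_widths must be non-empty")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError(f"dropout {self.dropout} outside [0, 1)")

    def parameter_count(self) -> int:
        n, prev = 0, self.input_dim
        for w in self.hidden_widths:
            n += prev * w + w
            prev = w
        return n + prev + 1


@dataclass(frozen=True)
class TransformerSpec:
    """Shape of the window transformer trunk and its classification head."""

    token_dim: int
    embed_width: int
    n_blocks: int = 2
    n_heads: int = 4
    head_hidden_widths: tuple[int, ...] = ()
    dropout: float = 0.15
    context: int = 31
    mask_padding: bool = True

    def __post_init__(self) -> None:
        if self.embed_width % self.n_heads != 0:
            raise ValidationError(
                f"n_heads {self.n_heads} must divide embed_width "
                f"{self.embed_width}"
            )
        if self.embed_width % 2 != 0:
            raise ValidationError("embed_width must be even (positional encoding)")
        if self.n_blocks < 1:
            raise ValidationError("n_blocks must be >= 1")
        if self.context % 2 != 1:
            raise ValidationError("context must be odd")

    def trunk_parameter_count(self) -> int:
        e = self.embed_width
        n = self.token_dim * e + e            # pre-attention dense
        per_block = (
            2 * e                              # ln1
            + 4 * (e * e + e)                  # q, k, v, o projections
            + 2 * e                            # ln2
            + (e * 4 * e + 4 * e)              # ff1
            + (4 * e * e + e)                  # ff2
        )
        n += self.n_blocks * per_block
        n += 2 * e                             # final layer norm
        return n

    def head_parameter_count(self, widths: Sequence[int]) -> int:
        n, prev = 0, self.context * self.embed_width
        for w in widths:
            n += prev * w + w
            prev = w
        return n + prev + 1

    def parameter_count(self) -> int:
        return self.trunk_parameter_count() + self.head_parameter_count(
            self.head_hidden_widths
        )


@dataclass(frozen=True)
class MultitaskHeadSpec:
    """Hidden widths of the four PTM-specific classification heads."""

    heads: Mapping[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        if set(self.heads) != set(PTM_TASKS):
            raise ValidationError(
                f"heads must cover exactly the tasks {PTM_TASKS}, got "
                f"{sorted(self.heads)}"
            )


def methylsight2_default_spec() -> tuple[TransformerSpec, MultitaskHeadSpec]:
    """The shipped full-scale configuration.

    Two encoder blocks, 4 attention heads, a 1,600-wide pre-attention dense
    layer, dropout 0.15, over 1,024-D tokens; one single-hidden-layer head
    per task with widths 1,797 / 1,803 / 338 / 493 mapped onto methylation,
    ubiquitination, acetylation, sumoylation in that order.
    """
    spec = TransformerSpec(token_dim=1024, embed_width=1600, n_blocks=2,
                           n_heads=4, dropout=0.15, context=31)
    heads = MultitaskHeadSpec(heads={
        "methylation": (1797,),
        "ubiquitination": (1803,),
        "acetylation": (338,),
        "sumoylation": (493,),
    })
    return spec, heads


@dataclass(frozen=True)
class Prediction:
    """A predicted modification probability for one site and task."""

    score: float
    task: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score {self.score} outside [0, 1]")


class MLPModel:
    """Dense classifier over pooled site embeddings."""

    def __init__(self, spec: MLPSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng([seed, 0xA1])
        self.stack = nn.DenseStack(rng, spec.input_dim, spec.hidden_widths,
                                   spec.dropout)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[-1] != self.spec.input_dim:
            raise ValidationError(
                f"input dim {x.shape[-1]} != spec input_dim "
                f"{self.spec.input_dim}"
            )
        return self.stack.forward(x, train, rng)

    def backward(self, g: np.ndarray) -> None:
        self.stack.backward(g)

    def score(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward(x, train=False))

    def params(self) -> list[nn.Param]:
        return self.stack.params()

    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        return self.stack.state("mlp")

    def load_state_dict(self, arrays: dict[str, np.ndarray]) -> None:
        nn.load_layer_state(self.stack, "mlp", arrays)


class TransformerModel:
    """Window transformer with one classification head per task.

    For a single-task model pass ``head_spec=None``; the lone head then uses
    ``spec.head_hidden_widths``.
    """

    def __init__(self, spec: TransformerSpec,
                 head_spec: MultitaskHeadSpec | None = None, seed: int = 0):
        self.spec = spec
        self.head_spec = head_spec
        rng = np.random.default_rng([seed, 0xB2])
        e = spec.embed_width
        self.dense_in = nn.Dense(rng, spec.token_dim, e)
        self.pe = sinusoidal_positional_encoding(spec.context, e)
        self.blocks = [
            nn.EncoderBlock(rng, e, spec.n_heads, spec.dropout)
            for _ in range(spec.n_blocks)
        ]
        self.ln_out = nn.LayerNorm(e)
        if head_spec is None:
            head_widths = {SINGLE_TASK: tuple(spec.head_hidden_widths)}
        else:
            head_widths = {t: tuple(w) for t, w in head_spec.heads.items()}
        self.heads = {
            t: nn.DenseStack(rng, spec.context * e, w, spec.dropout)
            for t, w in head_widths.items()
        }

    # -- forward / backward -------------------------------------------------

    def _resolve_task(self, task: str | None) -> str:
        if self.head_spec is None:
            if task not in (None, SINGLE_TASK):
                raise ValidationError(
                    f"single-task model has no head for task {task!r}"
                )
            return SINGLE_TASK
        if task not in self.heads:
            raise ValidationError(f"unknown task {task!r}")
        return task

    def trunk_forward(self, tokens: np.ndarray, mask: np.ndarray | None,
                      train: bool = False,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        """Shared path up to (and including) the flatten. Returns (B, 31*E)."""
        tokens = np.asarray(tokens, dtype=np.float64)
        if tokens.ndim == 2:
            tokens = tokens[None]
        B, T, d = tokens.shape
        if T != self.spec.context or d != self.spec.token_dim:
            raise ValidationError(
                f"tokens shaped {T}x{d}, spec expects "
                f"{self.spec.context}x{self.spec.token_dim}"
            )
        if mask is not None:
            mask = np.asarray(mask, dtype=np.float64)
            if mask.ndim == 1:
                mask = mask[None]
        self._mask = mask if self.spec.mask_padding else None
        if self._mask is not None:
            tokens = tokens * self._mask[:, :, None]
        x = self.dense_in.forward(tokens) + self.pe
        for blk in self.blocks:
            x = blk.forward(x, self._mask, train, rng)
        x = self.ln_out.forward(x)
        if self._mask is not None:
            x = x * self._mask[:, :, None]
        return x.reshape(B, -1)

    def forward(self, tokens: np.ndarray, mask: np.ndarray | None = None,
                task: str | None = None, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for a batch of embedded windows through one head."""
        task = self._resolve_task(task)
        flat = self.trunk_forward(tokens, mask, train, rng)
        self._active_task = task
        return self.heads[task].forward(flat, train, rng)

    def backward(self, g: np.ndarray) -> None:
        """Backprop from d(loss)/d(logits); grads land on trunk + active head."""
        gflat = self.heads[self._active_task].backward(g)
        B = gflat.shape[0]
        gx = gflat.reshape(B, self.spec.context, self.spec.embed_width)
        if self._mask is not None:
            gx = gx * self._mask[:, :, None]
        gx = self.ln_out.backward(gx)
        for blk in reversed(self.blocks):
            gx = blk.backward(gx)
        if self._mask is not None:
            gx = gx * self._mask[:, :, None]
        self.dense_in.backward(gx)

    def score(self, tokens: np.ndarray, mask: np.ndarray | None = None,
              task: str | None = None) -> np.ndarray:
        """Evaluation-mode probabilities (deterministic)."""
        return nn.sigmoid(self.forward(tokens, mask, task, train=False))

    # -- parameter access ---------------------------------------------------

    def trunk_params(self) -> list[nn.Param]:
        out = self.dense_in.params()
        for blk in self.blocks:
            out += blk.params()
        return out + self.ln_out.params()

    def head_params(self, task: str | None = None) -> list[nn.Param]:
        return self.heads[self._resolve_task(task)].params()

    def params(self) -> list[nn.Param]:
        out = self.trunk_params()
        for t in sorted(self.heads):
            out += self.heads[t].params()
        return out

    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = self.dense_in.state("trunk.dense_in")
        for i, blk in enumerate(self.blocks):
            out.update(blk.state(f"trunk.block{i}"))
        out.update(self.ln_out.state("trunk.ln_out"))
        for t in sorted(self.heads):
            out.update(self.heads[t].state(f"head.{t}"))
        return out

    def load_state_dict(self, arrays: dict[str, np.ndarray]) -> None:
        nn.load_layer_state(self.dense_in, "trunk.dense_in", arrays)
        for i, blk in enumerate(self.blocks):
            nn.load_layer_state(blk, f"trunk.block{i}", arrays)
        nn.load_layer_state(self.ln_out, "trunk.ln_out", arrays)
        for t in sorted(self.heads):
            nn.load_layer_state(self.heads[t], f"head.{t}", arrays)


# ---------------------------------------------------------------------------
# Prediction helpers
# ---------------------------------------------------------------------------

def _window_batch(window: EmbeddedWindow) -> tuple[np.ndarray, np.ndarray]:
    return window.tokens[None], window.mask[None]


def predict_single(model: TransformerModel | MLPModel,
                   x: EmbeddedWindow | np.ndarray,
                   task: str = "methylation") -> Prediction:
    """Score one input through a single-task model."""
    if isinstance(model, MLPModel):
        score = float(model.score(np.asarray(x))[0])
    else:
        tokens, mask = _window_batch(x)
        score = float(model.score(tokens, mask)[0])
    return Prediction(score=score, task=task)


def predict_multitask(model: TransformerModel, window: EmbeddedWindow,
                      task: str) -> Prediction:
    """Score one window through the head of the requested task only."""
    tokens, mask = _window_batch(window)
    score = float(model.score(tokens, mask, task=task)[0])
    return Prediction(score=score, task=task)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: TransformerModel | MLPModel, path: str | Path) -> None:
    """Single-file archive: structured spec plus parameter arrays."""
    meta: dict = {"seed": 0}
    if isinstance(model, MLPModel):
        meta["kind"] = "mlp"
        meta["spec"] = asdict(model.spec)
    else:
        meta["kind"] = "transformer"
        meta["spec"] = asdict(model.spec)
        meta["heads"] = (
            None if model.head_spec is None
            else {t: list(w) for t, w in model.head_spec.heads.items()}
        )
    arrays = model.state_dict()
    with open(path, "wb") as f:
        np.savez(f, __meta__=np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> TransformerModel | MLPModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["kind"] == "mlp":
        spec_d = meta["spec"]
        spec_d["hidden_widths"] = tuple(spec_d["hidden_widths"])
        model: TransformerModel | MLPModel = MLPModel(MLPSpec(**spec_d))
    else:
        spec_d = meta["spec"]
        spec_d["head_hidden_widths"] = tuple(spec_d["head_hidden_widths"])
        spec = TransformerSpec(**spec_d)
        heads = meta.get("heads")
        head_spec = (
            None if heads is None
            else MultitaskHeadSpec({t: tuple(w) for t, w in heads.items()})
        )
        model = TransformerModel(spec, head_spec)
    model.load_state_dict(arrays)
    return model
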