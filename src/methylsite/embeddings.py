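"""Per-residue embedding matrices: file-backed, windowing, and synthesis.

Real protein-language-model inference happens out of process: any embedder
can populate the HDF5 layout documented here (one group per accession with a
dataset ``emb`` of shape L×d and a file-level attribute ``model``). The
synthetic provider emulates class-conditional embeddings with a planted,
partially task-shared signal so every training and evaluation stage runs
without downloads.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import h5py
import numpy as np

from .records import PTM_TASKS, ProteinRecord, ValidationError, WindowRecord


@dataclass
class ResidueEmbeddingMatrix:
    """One L×d embedding matrix, one row per residue of the protein."""

    accession: str
    matrix: np.ndarray

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class EmbeddedWindow:
    """A context-window slice of a protein embedding with its pad mask.

    ``tokens`` is window_size×d; rows where ``mask`` is 0 are all-zero pads
    (the site was too close to a terminus).
    """

    tokens: np.ndarray
    mask: np.ndarray
    label: int | None = None
    task: str | None = None


def embed_window(
    embeddings: ResidueEmbeddingMatrix,
    position: int,
    window_size: int = 31,
    label: int | None = None,
    task: str | None = None,
) -> EmbeddedWindow:
    """Slice the window_size rows centered on ``position`` (1-based).

    Out-of-range rows are zero-filled and flagged in the mask, mirroring the
    zero-vector padding applied to sites near a protein terminus.
    """
    L, d = embeddings.matrix.shape
    if not 1 <= position <= L:
        raise ValidationError(
            f"{embeddings.accession}:{position}: position outside matrix of "
            f"length {L}"
        )
    half = window_size // 2
    tokens = np.zeros((window_size, d))
    mask = np.zeros(window_size)
    lo = position - 1 - half
    for w in range(window_size):
        src = lo + w
        if 0 <= src < L:
            tokens[w] = embeddings.matrix[src]
            mask[w] = 1.0
    return EmbeddedWindow(tokens=tokens, mask=mask, label=label, task=task)


def pool_site_embedding(
    embeddings: ResidueEmbeddingMatrix | Sequence[ResidueEmbeddingMatrix],
    position: int,
) -> np.ndarray:
    """Return the site residue's embedding row (the MLP input).

    Passing a sequence of matrices concatenates their rows, yielding the
    combined representation across several embedders.
    """
    if isinstance(embeddings, ResidueEmbeddingMatrix):
        embeddings = [embeddings]
    parts = []
    for emb in embeddings:
        L = emb.matrix.shape[0]
        if not 1 <= position <= L:
            raise ValidationError(
                f"{emb.accession}:{position}: position outside matrix of "
                f"length {L}"
            )
        parts.append(emb.matrix[position - 1])
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# HDF5 store
# ---------------------------------------------------------------------------

def write_embedding_store(
    matrices: Iterable[ResidueEmbeddingMatrix],
    path: str | Path,
    model: str = "synthetic",
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["model"] = model
        for m in matrices:
            g = f.create_group(m.accession)
            g.create_dataset("emb", data=m.matrix)


def read_embedding_store(
    path: str | Path, accessions: Iterable[str] | None = None
) -> dict[str, ResidueEmbeddingMatrix]:
    out = {}
    with h5py.File(path, "r") as f:
        keys = list(accessions) if accessions is not None else list(f.keys())
        for acc in keys:
            out[acc] = ResidueEmbeddingMatrix(acc, f[acc]["emb"][...])
    return out


class EmbeddingProvider(Protocol):
    """Anything that can hand the model an embedding matrix for a protein."""

    def embed(self, protein: ProteinRecord) -> ResidueEmbeddingMatrix: ...


class StoreEmbeddingProvider:
    """Provider over a precomputed HDF5 store (lookup by accession only)."""

    def __init__(self, path: str | Path):
        self._path = str(path)

    def embed(self, protein: ProteinRecord) -> ResidueEmbeddingMatrix:
        with h5py.File(self._path, "r") as f:
            if protein.accession not in f:
                raise KeyError(protein.accession)
            return ResidueEmbeddingMatrix(
                protein.accession, f[protein.accession]["emb"][...]
            )


# ---------------------------------------------------------------------------
# Synthetic embeddings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticEmbeddingConfig:
    """Parameters of the planted-signal embedding generator.

    The base embedding of each residue is isotropic Gaussian noise (sd
    ``noise_sd``) plus a residue-identity component of the same scale, making
    rows a deterministic function of (accession, position, residue, seed).
    Rows at labeled positive sites additionally receive
    ``shared_effect``·u + ``task_effect``·v_t, where u is a direction common
    to all four tasks and v_t a task-private direction; the five directions
    are unit-norm and mutually orthogonal.
    """

    d: int = 32
    shared_effect: float = 4.0
    task_effect: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValidationError("embedding dimension must be >= 2")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.shared_effect < 0 or self.task_effect < 0:
            raise ValidationError("effect sizes must be non-negative")

    def directions(self) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Orthonormal shared direction u and task directions v_t."""
        if self.d < 1 + len(PTM_TASKS):
            raise ValidationError(
                f"d={self.d} too small for {1 + len(PTM_TASKS)} orthogonal "
                f"directions"
            )
        rng = np.random.default_rng([self.seed, 0xD1])
        q, _ = np.linalg.qr(rng.normal(size=(self.d, 1 + len(PTM_TASKS))))
        u = q[:, 0]
        v = {t: q[:, 1 + i] for i, t in enumerate(PTM_TASKS)}
        return u, v


def _acc_key(accession: str) -> int:
    return zlib.crc32(accession.encode("utf-8"))


class SyntheticEmbeddingProvider:
    """Content-deterministic synthetic embedder.

    Row i of a protein is positional noise seeded by (seed, accession, i)
    plus a residue-identity vector, so re-embedding a mutant protein changes
    exactly the mutated row. Labeled positive sites receive the planted
    class signal on top.
    """

    def __init__(
        self,
        config: SyntheticEmbeddingConfig,
        labels: Sequence[WindowRecord] = (),
    ):
        self.config = config
        self._u, self._v = config.directions()
        rng = np.random.default_rng([config.seed, 0xE5])
        self._residue_table = {
            aa: rng.normal(0.0, config.noise_sd, config.d)
            for aa in "ACDEFGHIKLMNPQRSTVWYX-"
        }
        self._positives: dict[tuple[str, int], set[str]] = {}
        for r in labels:
            if r.label == 1:
                self._positives.setdefault(r.key, set()).add(r.task)

    def embed(self, protein: ProteinRecord) -> ResidueEmbeddingMatrix:
        cfg = self.config
        L = len(protein.sequence)
        rng = np.random.default_rng([cfg.seed, _acc_key(protein.accession)])
        mat = rng.normal(0.0, cfg.noise_sd, (L, cfg.d))
        for i, aa in enumerate(protein.sequence):
            try:
                mat[i] += self._residue_table[aa]
            except KeyError:
                raise ValidationError(
                    f"{protein.accession}:{i + 1}: unknown residue {aa!r}"
                ) from None
        for (acc, pos), tasks in self._positives.items():
            if acc == protein.accession and pos <= L:
                signal = cfg.shared_effect * self._u
                for t in tasks:
                    signal = signal + cfg.task_effect * self._v[t]
                mat[pos - 1] += signal
        return ResidueEmbeddingMatrix(protein.accession, mat)


def generate_synthetic_embeddings(
    proteins: Sequence[ProteinRecord],
    labels: Sequence[WindowRecord],
    config: SyntheticEmbeddingConfig,
) -> list[ResidueEmbeddingMatrix]:
    """Materialize synthetic embedding matrices for a collection of proteins.

    Every labeled site must resolve against ``proteins``.
    """
    by_acc = {p.accession: p for p in proteins}
    for r in labels:
        prot = by_acc.get(r.accession)
        if prot is None or r.position > len(prot.sequence):
            raise ValidationError(
                f"label {r.accession}:{r.position} does not resolve against "
                f"the protein collection"
            )
    provider = SyntheticEmbeddingProvider(config, labels)
    return [provider.embed(p) for p in proteins]
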