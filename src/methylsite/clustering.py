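"""Window redundancy reduction and train/validation/test partitioning.

Greedy incremental clustering at a fixed identity threshold over the
pre-aligned 31-mers (all windows share the center lysine, so identity is
ungapped column-wise agreement), followed by one-representative-per-cluster
selection that favours positives, and a label-stratified holdout split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import ValidationError, WindowRecord


def pairwise_identity(a: str, b: str) -> float:
    """Column-wise identity between two equal-length windows.

    Pad positions match only pad positions, and pad-pad agreements count
    toward the numerator (the windows are aligned on their center residue).
    """
    if len(a) != len(b):
        raise ValidationError(
            f"windows differ in length: {len(a)} vs {len(b)}"
        )
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / len(a)


@dataclass
class Cluster:
    """A representative-linked cluster of windows."""

    representative: WindowRecord
    members: list[WindowRecord]


def _iteration_order(records: Sequence[WindowRecord]) -> list[WindowRecord]:
    # Positives first so they found clusters (supports the positive-favouring
    # representative rule); within each class lexicographic for determinism.
    return sorted(records, key=lambda r: (-r.label, r.accession, r.position))


def greedy_cluster(
    records: Sequence[WindowRecord], threshold: float = 0.70, seed: int = 0
) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Records are visited in a deterministic order (positives first, then by
    accession/position); each joins the first existing cluster whose
    representative is at least ``threshold`` identical, else founds a new one.
    The result is a partition of the input. ``seed`` is accepted for interface
    symmetry; the procedure itself is deterministic.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    if not records:
        return []
    lengths = {len(r.window) for r in records}
    if len(lengths) > 1:
        raise ValidationError(f"mixed window lengths: {sorted(lengths)}")

    # Encode windows as byte matrices so membership scans vectorize.
    ordered = _iteration_order(records)
    n, w = len(ordered), lengths.pop()
    mat = np.frombuffer(
        "".join(r.window for r in ordered).encode("ascii"), dtype=np.uint8
    ).reshape(n, w)

    clusters: list[Cluster] = []
    rep_rows: list[np.ndarray] = []
    rep_mat = np.empty((0, w), dtype=np.uint8)
    for i, rec in enumerate(ordered):
        if rep_rows:
            ident = (rep_mat == mat[i]).mean(axis=1)
            hits = np.nonzero(ident >= threshold)[0]
            if hits.size:
                clusters[hits[0]].members.append(rec)
                continue
        clusters.append(Cluster(representative=rec, members=[rec]))
        rep_rows.append(mat[i])
        rep_mat = np.vstack(rep_rows)
    return clusters


def select_representatives(
    clusters: Sequence[Cluster], seed: int = 0
) -> list[WindowRecord]:
    """Draw one record per cluster, uniformly among positives when any exist,
    else uniformly among all members. Reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    out: list[WindowRecord] = []
    for c in clusters:
        positives = [m for m in c.members if m.label == 1]
        pool = positives if positives else c.members
        out.append(pool[int(rng.integers(len(pool)))])
    return out


@dataclass(frozen=True)
class SplitAssignment:
    record: WindowRecord
    partition: str  # train | validation | test


def partition_holdout(
    records: Sequence[WindowRecord],
    test_fraction: float = 0.2,
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> list[SplitAssignment]:
    """Label-stratified random split.

    Test receives ``test_fraction`` of each class; validation receives
    ``validation_fraction`` of each class's remainder; the rest trains.
    Counts round to the nearest integer, so they deviate from the exact
    proportion by at most one per class.
    """
    if not (0.0 < test_fraction < 1.0 and 0.0 < validation_fraction < 1.0):
        raise ValidationError("fractions must lie in (0, 1)")
    if test_fraction + validation_fraction >= 1.0:
        raise ValidationError("test + validation fractions must be < 1")
    rng = np.random.default_rng(seed)
    assignments: dict[tuple[str, int, str], str] = {}
    for label in (0, 1):
        cls = [r for r in records if r.label == label]
        if not cls:
            continue
        cls = sorted(cls, key=lambda r: (r.accession, r.position))
        if len(cls) < 3:
            raise ValidationError(
                f"class {label} has {len(cls)} records, too few for 3 partitions"
            )
        perm = rng.permutation(len(cls))
        n_test = int(round(test_fraction * len(cls)))
        remainder = len(cls) - n_test
        n_val = int(round(validation_fraction * remainder))
        for rank, idx in enumerate(perm):
            if rank < n_test:
                part = "test"
            elif rank < n_test + n_val:
                part = "validation"
            else:
                part = "train"
            r = cls[idx]
            assignments[(r.accession, r.position, r.task)] = part
    return [
        SplitAssignment(record=r, partition=assignments[(r.accession, r.position, r.task)])
        for r in records
    ]
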