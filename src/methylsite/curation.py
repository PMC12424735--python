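"""Curation of labeled lysine-site datasets.

Positives are lysines annotated with the target PTM. Negatives follow the
high-confidence rule: a lysine in a protein carrying at least one target-PTM
site, with no annotation for any of the four lysine PTMs, and predicted to be
buried (RSA < threshold). All other lysines are of unknown status and are
discarded rather than labeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .records import (
    PTM_TASKS,
    CurationConfig,
    ProteinRecord,
    PTMAnnotation,
    RSARecord,
    ValidationError,
    WindowRecord,
)


def extract_window(
    protein: ProteinRecord, position: int, config: CurationConfig | None = None
) -> str:
    """Extract the window_size-mer centered on the lysine at ``position``.

    Flanks extending past either terminus are filled with the pad symbol, so
    the site residue always sits at the exact middle of the window.
    """
    config = config or CurationConfig()
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise ValidationError(
            f"{protein.accession}:{position}: position outside sequence of "
            f"length {len(seq)}"
        )
    if seq[position - 1] != "K":
        raise ValidationError(
            f"{protein.accession}:{position}: residue is {seq[position - 1]!r}, "
            f"expected K"
        )
    half = config.window_size // 2
    lo = position - 1 - half  # 0-based, may be negative
    hi = position - 1 + half  # inclusive
    left_pad = max(0, -lo)
    right_pad = max(0, hi - (len(seq) - 1))
    core = seq[max(lo, 0) : min(hi, len(seq) - 1) + 1]
    return config.pad_symbol * left_pad + core + config.pad_symbol * right_pad


@dataclass
class CurationResult:
    """Labeled windows plus the tally of candidates skipped for missing RSA."""

    records: list[WindowRecord]
    skipped_missing_rsa: int = 0


def label_sites(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[PTMAnnotation],
    rsa: Sequence[RSARecord],
    target_ptm: str,
    config: CurationConfig | None = None,
) -> CurationResult:
    """Build the labeled window set for one PTM task.

    Only proteins with at least one target-PTM site contribute. A candidate
    negative missing its RSA value is skipped and counted, never silently
    dropped. Output order is deterministic: by accession, then position.
    """
    config = config or CurationConfig()
    if target_ptm not in PTM_TASKS:
        raise ValidationError(f"unknown target PTM {target_ptm!r}")
    by_acc = {p.accession: p for p in proteins}

    # Validate annotations against sequences and index them per site.
    site_ptms: dict[tuple[str, int], set[str]] = {}
    for a in annotations:
        prot = by_acc.get(a.accession)
        if prot is None:
            raise ValidationError(
                f"annotation {a.accession}:{a.position} has no matching protein"
            )
        if a.position > len(prot.sequence):
            raise ValidationError(
                f"{a.accession}:{a.position}: beyond sequence length "
                f"{len(prot.sequence)}"
            )
        if prot.sequence[a.position - 1] != "K":
            raise ValidationError(
                f"{a.accession}:{a.position}: annotated residue is "
                f"{prot.sequence[a.position - 1]!r}, not K"
            )
        site_ptms.setdefault((a.accession, a.position), set()).add(a.ptm)

    rsa_map = {(r.accession, r.position): r.rsa for r in rsa}

    target_proteins = sorted(
        {acc for (acc, _pos), ptms in site_ptms.items() if target_ptm in ptms}
    )

    out: list[WindowRecord] = []
    skipped = 0
    for acc in target_proteins:
        prot = by_acc[acc]
        for idx, residue in enumerate(prot.sequence):
            if residue != "K":
                continue
            pos = idx + 1
            ptms = site_ptms.get((acc, pos), set())
            if target_ptm in ptms:
                label = 1
            elif ptms:
                continue  # modified by another PTM: unknown for this task
            else:
                r = rsa_map.get((acc, pos))
                if r is None:
                    skipped += 1
                    continue
                if r >= config.rsa_burial_threshold:
                    continue  # exposed, status unknown
                label = 0
            out.append(
                WindowRecord(
                    accession=acc,
                    position=pos,
                    window=extract_window(prot, pos, config),
                    label=label,
                    task=target_ptm,
                )
            )
    return CurationResult(records=out, skipped_missing_rsa=skipped)


@dataclass(frozen=True)
class CooccurrenceSummary:
    """Per-PTM site counts and multi-PTM overlap statistics."""

    per_ptm: Mapping[str, int]
    sites_with_multiple_ptms: int
    target_ptm: str
    target_total: int
    target_overlapping: int
    overlap_percent: float | None  # to 1 decimal, None when undefined

    def __str__(self) -> str:
        pct = "n/a" if self.overlap_percent is None else f"{self.overlap_percent}%"
        return (
            f"{self.target_ptm}: {self.target_overlapping}/{self.target_total} "
            f"sites carry >=1 other PTM ({pct})"
        )


def count_ptm_cooccurrence(
    annotations: Iterable[PTMAnnotation], target_ptm: str = "methylation"
) -> CooccurrenceSummary:
    """Summarize PTM co-occurrence over unique (accession, position) sites."""
    site_ptms: dict[tuple[str, int], set[str]] = {}
    for a in annotations:
        site_ptms.setdefault((a.accession, a.position), set()).add(a.ptm)

    per_ptm = {t: 0 for t in PTM_TASKS}
    multi = 0
    target_total = 0
    target_overlap = 0
    for ptms in site_ptms.values():
        for t in ptms:
            per_ptm[t] += 1
        if len(ptms) >= 2:
            multi += 1
        if target_ptm in ptms:
            target_total += 1
            if len(ptms) >= 2:
                target_overlap += 1

    pct = (
        round(100.0 * target_overlap / target_total, 1) if target_total else None
    )
    return CooccurrenceSummary(
        per_ptm=per_ptm,
        sites_with_multiple_ptms=multi,
        target_ptm=target_ptm,
        target_total=target_total,
        target_overlapping=target_overlap,
        overlap_percent=pct,
    )
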