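"""Core domain records and tabular/FASTA I/O.

Positions are 1-based everywhere (PhosphoSitePlus convention); conversion to
0-based array indices happens only at array boundaries inside operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

#: The four lysine PTM prediction tasks, in canonical order. The order also
#: fixes the mapping of per-head hyperparameters onto tasks.
PTM_TASKS = ("methylation", "ubiquitination", "acetylation", "sumoylation")

#: Amino-acid alphabet: the 20 standard residues plus X for unknown.
RESIDUE_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: Pad symbol used in window strings; distinct from X (unknown residue).
PAD = "-"


class ValidationError(ValueError):
    """Raised when an input record violates a structural precondition."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by accession."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")


@dataclass(frozen=True)
class PTMAnnotation:
    """One experimentally catalogued lysine modification."""

    accession: str
    position: int  # 1-based
    ptm: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"{self.accession}:{self.position}: position must be >= 1"
            )
        if self.ptm not in PTM_TASKS:
            raise ValidationError(
                f"{self.accession}:{self.position}: unknown PTM {self.ptm!r}"
            )


@dataclass(frozen=True)
class RSARecord:
    """Relative solvent accessibility of one residue, in [0, 1]."""

    accession: str
    position: int
    rsa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rsa <= 1.0:
            raise ValidationError(
                f"{self.accession}:{self.position}: rsa {self.rsa} outside [0, 1]"
            )


@dataclass(frozen=True)
class WindowRecord:
    """A lysine-centered sequence window with label and task tag.

    ``window`` has odd length with the site lysine exactly in the middle;
    flanks that fall off the protein are filled with the pad symbol.
    """

    accession: str
    position: int  # 1-based index of the center lysine in the protein
    window: str
    label: int  # 1 = modified for `task`, 0 = high-confidence negative
    task: str

    def __post_init__(self) -> None:
        n = len(self.window)
        if n % 2 != 1:
            raise ValidationError(f"window length {n} must be odd")
        center = self.window[n // 2]
        if center != "K":
            raise ValidationError(
                f"{self.accession}:{self.position}: window center is "
                f"{center!r}, expected K"
            )
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.accession, self.position)


@dataclass(frozen=True)
class CurationConfig:
    """Knobs of the dataset-curation stage.

    window_size
        Odd context length centered on the lysine (default 31).
    rsa_burial_threshold
        Residues with RSA strictly below this are considered buried and thus
        eligible as high-confidence negatives (default 0.2).
    """

    window_size: int = 31
    rsa_burial_threshold: float = 0.2
    pad_symbol: str = PAD

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 != 1:
            raise ValidationError(
                f"window_size must be odd and >= 3, got {self.window_size}"
            )
        if not 0.0 < self.rsa_burial_threshold < 1.0:
            raise ValidationError(
                f"rsa_burial_threshold must lie in (0, 1), got "
                f"{self.rsa_burial_threshold}"
            )
        if len(self.pad_symbol) != 1:
            raise ValidationError("pad_symbol must be a single character")


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA proteome; accession = first whitespace token after '>'."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValidationError(f"duplicate accession in FASTA: {acc}")
        seen.add(acc)
        records.append(ProteinRecord(accession=acc, sequence=str(rec.seq).upper()))
    return records


def read_ptm_table(path: str | Path) -> list[PTMAnnotation]:
    """Read a TSV with columns accession, position, ptm."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    return [
        PTMAnnotation(str(r.accession), int(r.position), str(r.ptm))
        for r in df.itertuples(index=False)
    ]


def read_rsa_table(path: str | Path) -> list[RSARecord]:
    """Read a TSV with columns accession, position, rsa."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    return [
        RSARecord(str(r.accession), int(r.position), float(r.rsa))
        for r in df.itertuples(index=False)
    ]


def windows_to_frame(records: Iterable[WindowRecord]) -> pd.DataFrame:
    rows = [
        (r.accession, r.position, r.window, r.label, r.task) for r in records
    ]
    return pd.DataFrame(
        rows, columns=["accession", "position", "window", "label", "task"]
    )


def frame_to_windows(df: pd.DataFrame) -> list[WindowRecord]:
    return [
        WindowRecord(
            str(r.accession), int(r.position), str(r.window), int(r.label),
            str(r.task),
        )
        for r in df.itertuples(index=False)
    ]


def write_windows(records: Sequence[WindowRecord], path: str | Path) -> None:
    windows_to_frame(records).to_csv(path, sep="\t", index=False)


def read_windows(path: str | Path) -> list[WindowRecord]:
    return frame_to_windows(pd.read_csv(path, sep="\t", dtype={"accession": str}))
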