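"""In-silico tryptic digestion and PRM-MS isolation-list generation.

Trypsin cleaves C-terminal to K or R unless the next residue is proline;
digestion here uses zero missed cleavages, so the peptides tile the protein
exactly. Precursor and b/y fragment m/z values are computed from standard
monoisotopic residue masses, with each methyl group adding one CH2
(14.01565 Da) on the site lysine, across the null/mono/di/tri methylation
states and the +2/+3/+4 charge states of a targeted acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import ProteinRecord, ValidationError

#: Standard monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.0105646
PROTON = 1.0072765
METHYL = 14.0156500  # CH2 per methyl group


@dataclass(frozen=True)
class TrypticPeptide:
    """One zero-missed-cleavage tryptic peptide in protein coordinates.

    ``site_offset`` is the 1-based position of the target lysine within the
    peptide, when the peptide carries one.
    """

    accession: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    sequence: str
    site_offset: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrecursorEntry:
    """One isolation-list row."""

    peptide: TrypticPeptide
    methyl_state: int  # 0 = null .. 3 = tri
    charge: int
    mz: float


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" or "y"
    index: int
    charge: int
    mz: float


def digest(protein: ProteinRecord) -> list[TrypticPeptide]:
    """Cleave C-terminal to every K/R not followed by P; peptides tile the
    protein exactly."""
    seq = protein.sequence
    peptides: list[TrypticPeptide] = []
    start = 0
    for i, aa in enumerate(seq):
        at_end = i == len(seq) - 1
        cleave = aa in "KR" and (at_end or seq[i + 1] != "P")
        if cleave or at_end:
            peptides.append(TrypticPeptide(
                accession=protein.accession,
                start=start + 1,
                end=i + 1,
                sequence=seq[start:i + 1],
            ))
            start = i + 1
    return peptides


def site_peptide(protein: ProteinRecord, position: int) -> TrypticPeptide:
    """The unique tryptic peptide containing the lysine at ``position``.

    When the site lysine is itself a cleavage site, the peptide terminates
    at it.
    """
    if not 1 <= position <= len(protein.sequence):
        raise ValidationError(
            f"{protein.accession}:{position}: position outside sequence"
        )
    if protein.sequence[position - 1] != "K":
        raise ValidationError(
            f"{protein.accession}:{position}: residue is "
            f"{protein.sequence[position - 1]!r}, expected K"
        )
    for pep in digest(protein):
        if pep.start <= position <= pep.end:
            return TrypticPeptide(
                accession=pep.accession, start=pep.start, end=pep.end,
                sequence=pep.sequence, site_offset=position - pep.start + 1,
            )
    raise AssertionError("digestion must tile the protein")  # pragma: no cover


def _residue_mass_sum(sequence: str, accession: str = "?") -> float:
    total = 0.0
    for aa in sequence:
        try:
            total += MONOISOTOPIC_MASS[aa]
        except KeyError:
            raise ValidationError(
                f"{accession}: unknown residue symbol {aa!r}"
            ) from None
    return total


def peptide_neutral_mass(peptide: TrypticPeptide, methyl_state: int) -> float:
    """Monoisotopic neutral mass with ``methyl_state`` methyl groups."""
    if not 0 <= methyl_state <= 3:
        raise ValidationError(f"methyl_state {methyl_state} outside 0..3")
    return (_residue_mass_sum(peptide.sequence, peptide.accession)
            + WATER + methyl_state * METHYL)


def precursor_mz(peptide: TrypticPeptide, methyl_state: int,
                 charge: int) -> float:
    """m/z of the [M + charge·H]^charge+ precursor."""
    if charge < 1:
        raise ValidationError(f"charge must be >= 1, got {charge}")
    M = peptide_neutral_mass(peptide, methyl_state)
    return (M + charge * PROTON) / charge


def fragment_mz(peptide: TrypticPeptide, methyl_state: int, series: str,
                index: int, charge: int = 1) -> float:
    """m/z of the b_index or y_index fragment ion.

    The methyl mass is assigned to the site lysine, so it is carried only by
    fragments that contain that residue.
    """
    n = len(peptide.sequence)
    if series not in ("b", "y"):
        raise ValidationError(f"series must be 'b' or 'y', got {series!r}")
    if not 1 <= index < n:
        raise ValidationError(
            f"fragment index {index} outside 1..{n - 1} for peptide of "
            f"length {n}"
        )
    if charge < 1:
        raise ValidationError(f"charge must be >= 1, got {charge}")
    if methyl_state and peptide.site_offset is None:
        raise ValidationError(
            "methylated fragments require a peptide with a site_offset"
        )
    if series == "b":
        frag = peptide.sequence[:index]
        contains_site = (peptide.site_offset is not None
                         and peptide.site_offset <= index)
        neutral = _residue_mass_sum(frag, peptide.accession)
    else:
        frag = peptide.sequence[n - index:]
        contains_site = (peptide.site_offset is not None
                         and peptide.site_offset > n - index)
        neutral = _residue_mass_sum(frag, peptide.accession) + WATER
    if contains_site:
        neutral += methyl_state * METHYL
    return (neutral + charge * PROTON) / charge


@dataclass
class IsolationList:
    entries: list[PrecursorEntry]
    errors: list[str]
    n_duplicate_sites: int = 0


def build_isolation_list(
    sites: Sequence[tuple[str, int]],
    proteins: Sequence[ProteinRecord],
    charges: Iterable[int] = (2, 3, 4),
    methyl_states: Iterable[int] = (0, 1, 2, 3),
) -> IsolationList:
    """One precursor entry per (site, methyl state, charge).

    Unique sites × states × charges rows, sorted by accession, position,
    state, charge. Duplicate input sites are deduplicated with a tally;
    unresolvable sites become error records excluded from the count.
    """
    by_acc = {p.accession: p for p in proteins}
    charges = sorted(set(charges))
    states = sorted(set(methyl_states))
    seen: set[tuple[str, int]] = set()
    n_dup = 0
    entries: list[PrecursorEntry] = []
    errors: list[str] = []
    for acc, pos in sites:
        if (acc, pos) in seen:
            n_dup += 1
            continue
        seen.add((acc, pos))
        prot = by_acc.get(acc)
        if prot is None:
            errors.append(f"{acc}:{pos}: unknown accession")
            continue
        try:
            pep = site_peptide(prot, pos)
            for state in states:
                for z in charges:
                    entries.append(PrecursorEntry(
                        peptide=pep, methyl_state=state, charge=z,
                        mz=precursor_mz(pep, state, z),
                    ))
        except ValidationError as exc:
            errors.append(str(exc))
    entries.sort(key=lambda e: (e.peptide.accession, e.peptide.start
                                + (e.peptide.site_offset or 1) - 1,
                                e.methyl_state, e.charge))
    return IsolationList(entries=entries, errors=errors,
                         n_duplicate_sites=n_dup)


@dataclass(frozen=True)
class ValidationTally:
    """Outcome arithmetic of a PRM-MS validation campaign.

    precision_worst treats every inconclusive site as a negative;
    precision_conclusive discards sites with no detectable transitions.
    Both are percentages to one decimal.
    """

    n_assayed: int
    n_methylated: int
    n_unmethylated_only: int
    n_inconclusive: int
    precision_worst: float
    precision_conclusive: float | None


def tally_validation(outcomes: Sequence[str]) -> ValidationTally:
    """Tally per-site outcomes in {methylated, unmethylated_only,
    inconclusive}."""
    if not outcomes:
        raise ValidationError("outcomes must be nonempty")
    allowed = {"methylated", "unmethylated_only", "inconclusive"}
    bad = set(outcomes) - allowed
    if bad:
        raise ValidationError(f"unknown outcomes: {sorted(bad)}")
    n_me = sum(1 for o in outcomes if o == "methylated")
    n_un = sum(1 for o in outcomes if o == "unmethylated_only")
    n_in = sum(1 for o in outcomes if o == "inconclusive")
    n = len(outcomes)
    conclusive = n_me + n_un
    return ValidationTally(
        n_assayed=n,
        n_methylated=n_me,
        n_unmethylated_only=n_un,
        n_inconclusive=n_in,
        precision_worst=round(100.0 * n_me / n, 1),
        precision_conclusive=(
            round(100.0 * n_me / conclusive, 1) if conclusive else None
        ),
    )


def isolation_list_rows(lst: IsolationList) -> list[dict]:
    """Plain-dict rows for CSV export (mz to 6 decimals)."""
    return [
        {
            "accession": e.peptide.accession,
            "site_position": e.peptide.start + (e.peptide.site_offset or 1) - 1,
            "peptide": e.peptide.sequence,
            "methyl_state": e.methyl_state,
            "charge": e.charge,
            "mz": round(e.mz, 6),
        }
        for e in lst.entries
    ]
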