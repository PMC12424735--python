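"""Proteome-scale scanning, methylome extrapolation, matched candidate
sampling for wet-lab validation, and mutation delta-score analysis."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingProvider, embed_window
from .models import TransformerModel
from .records import ProteinRecord, PTMAnnotation, RSARecord, ValidationError


@dataclass
class ProteomeScanResult:
    """Scores of every lysine in a proteome plus the threshold summary."""

    records: list[tuple[str, int, float]]  # (accession, position, score)
    threshold: float
    n_predicted: int
    n_proteins_hit: int
    skipped_accessions: list[str] = field(default_factory=list)


def _score_sites(model: TransformerModel, matrix, positions,
                 task: str = "methylation", batch_size: int = 256) -> np.ndarray:
    spec = model.spec
    windows = [embed_window(matrix, p, spec.context) for p in positions]
    tokens = np.stack([w.tokens for w in windows])
    masks = np.stack([w.mask for w in windows])
    head = task if model.head_spec is not None else None
    return np.concatenate([
        model.score(tokens[i:i + batch_size], masks[i:i + batch_size], task=head)
        for i in range(0, len(positions), batch_size)
    ])


def scan_proteome(
    proteins: Sequence[ProteinRecord],
    provider: EmbeddingProvider,
    model: TransformerModel,
    threshold: float,
    task: str = "methylation",
) -> ProteomeScanResult:
    """Score every lysine of every protein; deterministic given a checkpoint.

    Proteins whose embeddings the provider cannot supply are skipped and
    tallied, not fatal.
    """
    records: list[tuple[str, int, float]] = []
    skipped: list[str] = []
    hit_proteins: set[str] = set()
    n_pred = 0
    for prot in proteins:
        positions = [i + 1 for i, aa in enumerate(prot.sequence) if aa == "K"]
        if not positions:
            continue
        try:
            matrix = provider.embed(prot)
        except KeyError:
            skipped.append(prot.accession)
            continue
        scores = _score_sites(model, matrix, positions, task)
        for pos, sc in zip(positions, scores):
            records.append((prot.accession, pos, float(sc)))
            if sc >= threshold:
                n_pred += 1
                hit_proteins.add(prot.accession)
    return ProteomeScanResult(
        records=records,
        threshold=threshold,
        n_predicted=n_pred,
        n_proteins_hit=len(hit_proteins),
        skipped_accessions=skipped,
    )


def estimate_methylome_size(n_predicted: int, precision: float,
                            recall: float) -> int:
    """Extrapolated total: round(n_predicted × precision / recall).

    Of the predicted sites, precision·n are expected true; dividing by the
    recall at the same operating point extrapolates to all true sites.
    """
    if not 0.0 < precision <= 1.0:
        raise ValidationError(f"precision {precision} outside (0, 1]")
    if not 0.0 < recall <= 1.0:
        raise ValidationError(f"recall {recall} outside (0, 1]")
    return int(round(n_predicted * precision / recall))


@dataclass
class CandidateSet:
    """Two score-matched validation candidate pools.

    set1: exposed lysines with a known other PTM; set2: exposed lysines
    with no known modification. Both exclude known methylation sites and
    clear the conservative score threshold.
    """

    set1: list[tuple[str, int, float]]
    set2: list[tuple[str, int, float]]
    per_set_n: int
    cdf_distance: float


def _max_cdf_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample maximum CDF distance (Kolmogorov–Smirnov statistic)."""
    grid = np.union1d(a, b)
    ca = np.searchsorted(np.sort(a), grid, side="right") / len(a)
    cb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
    return float(np.max(np.abs(ca - cb)))


def sample_matched_candidates(
    scored_sites: Sequence[tuple[str, int, float]],
    annotations: Sequence[PTMAnnotation],
    rsa: Sequence[RSARecord],
    threshold: float,
    per_set_n: int = 50,
    score_bin_width: float = 0.05,
    rsa_exposed_threshold: float = 0.2,
    seed: int = 0,
) -> CandidateSet:
    """Sample score-matched candidates from the two eligibility pools.

    Eligibility: score ≥ threshold, RSA ≥ the exposure threshold, and not a
    known methylation site. Draws are stratified over score bins of width
    ``score_bin_width`` on [threshold, 1], allocating matched per-bin counts
    to both sets (largest-remainder rounding, capped at each bin's joint
    availability; the shortfall of an undersupplied bin spills into bins
    with spare capacity). The maximum CDF distance between the two samples'
    scores is reported as a matching diagnostic.
    """
    site_ptms: dict[tuple[str, int], set[str]] = {}
    for a in annotations:
        site_ptms.setdefault((a.accession, a.position), set()).add(a.ptm)
    rsa_map = {(r.accession, r.position): r.rsa for r in rsa}

    pool1: list[tuple[str, int, float]] = []
    pool2: list[tuple[str, int, float]] = []
    for acc, pos, score in scored_sites:
        if score < threshold:
            continue
        r = rsa_map.get((acc, pos))
        if r is None or r < rsa_exposed_threshold:
            continue
        ptms = site_ptms.get((acc, pos), set())
        if "methylation" in ptms:
            continue
        (pool1 if ptms else pool2).append((acc, pos, score))

    if min(len(pool1), len(pool2)) < per_set_n:
        raise ValidationError(
            f"insufficient eligible sites: pools of {len(pool1)} and "
            f"{len(pool2)} for per_set_n={per_set_n}"
        )

    edges = np.arange(threshold, 1.0 + score_bin_width, score_bin_width)
    n_bins = len(edges) - 1

    def bin_of(score: float) -> int:
        return min(int((score - threshold) / score_bin_width), n_bins - 1)

    rng = np.random.default_rng(seed)
    by_bin1: dict[int, list] = {b: [] for b in range(n_bins)}
    by_bin2: dict[int, list] = {b: [] for b in range(n_bins)}
    for site in pool1:
        by_bin1[bin_of(site[2])].append(site)
    for site in pool2:
        by_bin2[bin_of(site[2])].append(site)

    avail = np.array(
        [min(len(by_bin1[b]), len(by_bin2[b])) for b in range(n_bins)],
        dtype=float,
    )
    if avail.sum() < per_set_n:
        raise ValidationError(
            "score bins cannot jointly supply matched samples; widen "
            "score_bin_width or lower per_set_n"
        )
    # largest-remainder allocation proportional to joint availability
    ideal = per_set_n * avail / avail.sum()
    alloc = np.floor(ideal).astype(int)
    remainder = ideal - alloc
    short = per_set_n - alloc.sum()
    for b in np.argsort(-remainder):
        if short == 0:
            break
        if alloc[b] < avail[b]:
            alloc[b] += 1
            short -= 1
    # spill any residue into bins with spare joint capacity
    while short > 0:
        spare = np.nonzero(alloc < avail)[0]
        alloc[spare[0]] += 1
        short -= 1

    def draw(pool_by_bin: dict[int, list]) -> list:
        out = []
        for b in range(n_bins):
            members = pool_by_bin[b]
            take = alloc[b]
            idx = rng.choice(len(members), size=take, replace=False)
            out.extend(members[i] for i in idx)
        return out

    set1 = draw(by_bin1)
    set2 = draw(by_bin2)
    dist = _max_cdf_distance(
        np.array([s[2] for s in set1]), np.array([s[2] for s in set2])
    )
    return CandidateSet(set1=set1, set2=set2, per_set_n=per_set_n,
                        cdf_distance=dist)


@dataclass(frozen=True)
class MutationImpact:
    """Effect of one missense mutation on one nearby lysine's score."""

    accession: str
    mutation_position: int
    ref: str
    alt: str
    lysine_position: int
    wild_score: float
    mutant_score: float
    lost: bool

    @property
    def delta(self) -> float:
        return self.wild_score - self.mutant_score


@dataclass
class MutationScanReport:
    impacts: list[MutationImpact]
    errors: list[str]


def mutation_delta_scores(
    mutations: Sequence[tuple[str, int, str, str]],
    proteins: Sequence[ProteinRecord],
    provider: EmbeddingProvider,
    model: TransformerModel,
    threshold: float,
    min_delta: float = 0.02,
    relative: bool = False,
) -> MutationScanReport:
    """Wild-vs-mutant methylation scores for lysines near each mutation.

    Only lysines whose context window overlaps the mutated position are
    rescored (the model is window-limited). An impact is emitted when the
    score decrease reaches ``min_delta`` (absolute by default; fractional
    change when ``relative``); ``lost`` flags crossings of the operating
    threshold. A reference-residue mismatch produces an error record and
    processing continues.
    """
    by_acc = {p.accession: p for p in proteins}
    half = model.spec.context // 2
    impacts: list[MutationImpact] = []
    errors: list[str] = []
    for acc, mpos, ref, alt in mutations:
        prot = by_acc.get(acc)
        if prot is None:
            errors.append(f"{acc}:{mpos}{ref}>{alt}: unknown accession")
            continue
        if not 1 <= mpos <= len(prot.sequence):
            errors.append(f"{acc}:{mpos}{ref}>{alt}: position out of range")
            continue
        if prot.sequence[mpos - 1] != ref:
            errors.append(
                f"{acc}:{mpos}{ref}>{alt}: sequence has "
                f"{prot.sequence[mpos - 1]!r} at {mpos}"
            )
            continue
        mutant_seq = prot.sequence[: mpos - 1] + alt + prot.sequence[mpos:]
        mutant = ProteinRecord(acc, mutant_seq)
        lysines = [
            i + 1 for i, aa in enumerate(prot.sequence)
            if aa == "K" and abs(i + 1 - mpos) <= half and mutant_seq[i] == "K"
        ]
        if not lysines:
            continue
        wild_scores = _score_sites(model, provider.embed(prot), lysines)
        mut_scores = _score_sites(model, provider.embed(mutant), lysines)
        for kpos, ws, ms in zip(lysines, wild_scores, mut_scores):
            delta = ws - ms
            effective = delta / ws if relative and ws > 0 else delta
            if effective >= min_delta:
                impacts.append(MutationImpact(
                    accession=acc, mutation_position=mpos, ref=ref, alt=alt,
                    lysine_position=kpos, wild_score=float(ws),
                    mutant_score=float(ms),
                    lost=bool(ws >= threshold > ms),
                ))
    return MutationScanReport(impacts=impacts, errors=errors)
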