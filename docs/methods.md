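# Methods

This note records the models and procedures implemented in `methylsite`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic benchmark does and does not demonstrate.

## Dataset curation

A binary lysine-methylation dataset cannot use "not annotated" as a
negative label: absence of annotation mostly reflects absence of
measurement. The curation rule therefore requires three conditions of a
negative: (i) it lies in a protein with at least one annotated site for the
target PTM (so the protein has been studied at all), (ii) it carries no
annotation for *any* of the four lysine PTMs considered (methylation,
acetylation, ubiquitination, sumoylation — including the target PTM
itself), and (iii) it is predicted buried, RSA < 0.2, where the structural
context makes modification unlikely. Lysines failing these are *unknown*
and discarded, never labeled. The RSA comparison is strict (<), so raising
the threshold weakly increases the negative pool and the count is monotone
in the threshold.

Coordinates are 1-based throughout (the convention of PTM databases);
conversion to 0-based indices happens only inside array operations.
Annotations pointing at non-lysine residues abort with a named error
rather than being skipped — a silent skip would hide coordinate or isoform
mismatches between the FASTA and the annotation table. Candidate negatives
with no RSA value are skipped but tallied on the result. Each FASTA entry
is treated as an independent protein; no isoform collapsing is attempted.
The same workflow, run once per PTM, yields the four task datasets; the
burial filter applies to negatives only.

Windows are 31 residues centered on the site lysine, padded with `-` when
the protein terminus intrudes; `-` is distinct from `X`, which is kept as
an (unknown) residue.

## Redundancy clustering and splitting

Near-identical windows inflate apparent accuracy through train/test
leakage. Windows are clustered greedily: visit records in a deterministic
order (positives first, then by accession and position), join the first
cluster whose *representative* is ≥ 70% identical, else found a new
cluster. Identity is ungapped column-wise agreement over the 31 positions —
the windows are pre-aligned on the center lysine, so no alignment is
needed; a pad column matches only a pad column and pad–pad agreement counts.
Only the member↔representative relation is guaranteed (the usual greedy
incremental-clustering contract); members of different clusters may still
be similar to each other. Positives-first ordering maximizes the chance
that a mixed cluster is founded by (and represented by) a positive,
supporting the positive-favouring representative draw: uniform among a
cluster's positives if any, else uniform among members.

The holdout split is label-stratified: the test set takes 20% of each
class, validation 20% of each class's remainder (the validation fraction is
inferred from the published split arithmetic of the full-scale dataset:
604/3,019 ≈ 0.20), rounding to the nearest integer so counts deviate from
exact proportions by at most one per class. Clustering and splitting run
per task; only the methylation task receives validation/test splits.

## Embeddings

Models consume per-residue embedding matrices (L×d, one row per residue)
through a provider interface; a file-backed provider reads an HDF5 store
(one group per accession, dataset `emb`, file attribute `model`) that any
protein language model can populate out of process. Windowing copies the 31
rows around a site, zero-fills rows beyond the termini, and records a
binary mask; the zero-vector pad generalizes the 1,024-dimensional
zero-pad of full-scale embeddings to arbitrary d. The MLP input is the site
residue's row (mean-pooling is available but not the default — "embedding
of the lysine site" is read as the residue row); concatenating rows from
several stores yields a combined representation.

### Synthetic generator

The synthetic provider makes every stage runnable and testable offline.
The base embedding of residue i of a protein is Gaussian noise (sd
`noise_sd`, default 1.0) seeded by (seed, accession, position) plus a
residue-identity vector of the same scale, so embeddings are a
deterministic function of sequence content: re-embedding a mutant protein
changes exactly the mutated row, and mutation effects on window scores are
strictly local. Positive sites additionally receive
`shared_effect`·u + `task_effect`·v_t, with u and the four v_t orthonormal:
u is the signal common to all tasks (the transferable part), v_t each
task's private part. Defaults d = 32, shared_effect = 4, task_effect = 2
put the positive class ~4.5 noise-sd away from the negatives, mostly along
the shared direction — a strong planted signal, separable nearly perfectly
by an ideal observer, so that failures to learn indicate model or training
defects rather than an impossible problem.

What the generator does *not* emulate: positional correlation within real
windows, sequence-motif structure, embedding anisotropy, label noise, and
the long-tailed protein length distribution. Passing the synthetic
benchmarks therefore demonstrates that the architecture, losses, batching
and optimization behave as specified — not that any particular accuracy
will be reached on real proteomes.

## Models

The window transformer maps each token through a dense "embedding" layer
(width E), adds the canonical sinusoidal positional encoding (added after
the dense layer, so the encoding lives in model width E), and applies
pre-norm encoder blocks: x + Attn(LN(x)) then x + FFN(LN(x)), with 4
attention heads by default and a GELU feed-forward of width 4E; a final
layer norm, a flatten concatenating the 31 token vectors, and a ReLU dense
head ending in a sigmoid. Pre-norm was chosen over post-norm for
optimization stability at the learning rates used here; the feed-forward
shape follows the canonical encoder recipe. The multitask variant owns
four heads over the shared trunk and evaluates only the head matching the
queried task.

Pad positions are masked out of attention (as keys), and pad token rows
are zeroed at the input and again before the flatten. Zero-padding alone
does not make scores independent of pad content once biases and layer
norms act; with masking plus zeroing, invariance to pad-row content is
exact and is asserted in the tests. A flag disables masking for strict
zero-pad-only behaviour.

Each spec carries a closed-form parameter count that is asserted against
the instantiated model, catching silent architecture drift. The shipped
full-scale configuration (2 blocks, E = 1,600, heads 1,797/1,803/338/493
mapped to methylation/ubiquitination/acetylation/sumoylation in that order,
dropout 0.15, 1,024-D tokens) is provided for reference; every test and
benchmark uses a reduced spec. The head-width-to-task mapping follows the
canonical task order; the source material lists the widths without naming
tasks.

All layers are NumPy (float64) with hand-written backward passes, verified
against central finite differences and an independently coded naive
forward pass. Evaluation-mode inference is deterministic.

## Training

Minibatches are task-homogeneous: each epoch shuffles every task's
instances, chunks them into batches (128 by default for transformers, 64
for MLPs), and shuffles the batch order globally, which interleaves tasks
in proportion to dataset sizes while every instance appears exactly once.
The loss of a batch is γ·L_CE for methylation, L_CE otherwise
(γ default 20, candidates {1, 13.5, 20} — 13.5 approximating the
methylation-to-other-PTM instance ratio); gradients flow only into the
shared trunk and the batch's head, and the Adam state is lazy per
parameter, so the other heads are bitwise untouched — the partial
parameter sharing contract, asserted in the tests together with the exact
linearity of gradients in γ.

Early stopping monitors methylation-only validation BCE (a flag widens the
monitor to all tasks); the best-validation-loss epoch's parameters are
restored, and both that loss and the corresponding validation AUPRC are
recorded, keeping the within-run selection criterion (loss) distinct from
the across-run criterion (AUPRC). Patience defaults to 10 epochs with a
100-epoch cap at full scale; the source material does not state a patience,
and 10 is standard practice. Scores are clamped at 1e-12 before
logarithms; non-finite losses abort with a diagnostic. Hyperparameter
search is plain random sampling (learning rate log-uniform) with the best
trial chosen by validation AUPRC; 50 trials by default.

## Evaluation

Curves are computed over all distinct score thresholds with tied scores
entering or leaving the predicted-positive set together. AUPRC is
step-wise average precision, Σ(R_k − R_{k−1})·P_k — trapezoidal
interpolation in PR space overestimates and is not used; AUROC is the
trapezoid over (FPR, TPR), equal to the normalized Mann–Whitney statistic.
Both are tested to 1e-12 against exhaustive threshold enumeration and
cross-checked against scikit-learn.

Prevalence-corrected precision handles the mismatch between the test-set
imbalance (1:6.5) and an assumed deployment imbalance (1:36): holding the
class-conditional score distributions fixed, scaling the negative class by
w = r_target/r_test scales false positives by w, giving
PCPr = TP/(TP + w·FP) while recall is unchanged. This is the standard
re-weighting correction; resampling the test set would estimate the same
quantity with extra variance. PCPr ≤ precision whenever w ≥ 1, with
equality iff FP = 0 or w = 1. The operating threshold for a target PCPr is
the lowest threshold meeting it, which maximizes recall subject to the
precision constraint.

## Discovery

The proteome scan scores every lysine of every protein (missing embeddings
are tallied, not fatal) and is deterministic given a checkpoint. The
methylome extrapolation is round(n_predicted × precision / recall):
precision converts predictions to expected true positives, recall converts
those to the total. For validation campaigns, candidates are drawn from two
pools — exposed lysines (RSA ≥ 0.2) above the conservative score threshold
that are not known methylation sites, with ("Set 1") or without ("Set 2")
another PTM annotation — stratified over 0.05-wide score bins with matched
per-bin counts (largest-remainder allocation; bins that cannot supply their
share spill into bins with joint capacity), and the maximum CDF distance
between the two samples' scores is reported as the matching diagnostic.
Mutation analysis rescoring is window-limited: only lysines whose 31-mer
overlaps the mutated position are re-evaluated; the score decrease is
absolute by default (0.02) with a relative-change flag, and a `lost` flag
marks crossings of the operating threshold.

## PRM-MS

Digestion cleaves C-terminal to K/R unless followed by proline, with zero
missed cleavages, so peptides tile the protein exactly and each site maps
to a unique peptide; when the site lysine is itself a cleavage site the
peptide ends at it. This matches the observed behaviour of the validated
example peptides and makes the isolation list exactly
|sites|×|states|×|charges| rows. Methylated lysine is known to hinder
trypsin; a missed-cleavages flag enumerates the alternative peptides
without changing the default count semantics. Masses use the standard
monoisotopic residue table with water 18.0105646 Da, proton 1.0072765 Da,
and 14.01565 Da per methyl group assigned to the site lysine; cysteine is
carried unmodified (no fixed alkylation) by default. Fragment ions are b/y
only, charge 1 by default; the methyl mass is carried only by fragments
containing the site residue, and b_i + y_{n−i} reconstruct the precursor
neutral mass plus two protons — both asserted property-wise. All mass
arithmetic is verified against an independent peptide-mass calculator to
1e-4 Th.

## The synthetic benchmark

The transfer study (`methylsite.study`) generates 2,000 sites per task at
the 1:6.5 test imbalance, embeds them with the planted-signal generator,
and holds the methylation *training* subset to 450 instances — about 1:13
against the 6,000 auxiliary-task instances, mirroring the
methylation-to-other-PTM instance ratio of the full-scale dataset — with
750 validation and 800 test sites. The reduced model (32-D tokens, E = 32,
1 block, 2 heads, one 32-wide head layer, dropout 0.05) trains with Adam
at 2e-3, γ = 20, batch 128. The multitask schedule is patience 2 / max 10
epochs; the single-task baseline, whose epochs are ~13× cheaper, gets
patience 3 / max 20 so both reach their early-stopping plateau and the
comparison is not confounded by step counts. Under these conditions the
single-task model is data-limited while the multitask model learns the
shared signal direction from the auxiliary tasks; the test suite requires
mean multitask validation AUPRC > 0.9 over ten seeds and mean multitask ≥
mean single-task — the directional claim that auxiliary PTM knowledge
transfers, at desk scale. Problem sizes were chosen so the full benchmark
runs in minutes on one CPU.

## Known limitations

- The NumPy models are CPU-bound and float64; the full-scale configuration
  (~10⁸ parameters) is provided as a spec but is not practical to train
  here.
- Greedy clustering reproduces the contract, not the exact cluster
  boundaries, of word-filter-accelerated tools.
- The synthetic generator's independence assumptions (see above) make it a
  correctness harness, not a realism benchmark.
- RSA values are consumed, never predicted; real protein-language-model
  embeddings are consumed from files, never computed in-process.
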