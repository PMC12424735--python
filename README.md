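# methylsite

A toolkit for predicting lysine methylation sites in proteins and for
planning their wet-lab validation by targeted mass spectrometry.

Lysine methylation regulates far more than histones, and several lysine
methyltransferases are cancer drivers, but only a few thousand human
methyllysines are catalogued. Because unmodified lysines vastly outnumber
methylated ones and experimentally validated negatives do not exist,
building a trustworthy predictor requires careful dataset curation,
a model that can borrow signal from better-annotated lysine modifications
(acetylation, ubiquitination, sumoylation), and an evaluation that corrects
for the difference between test-set and proteome-wide class imbalance.
`methylsite` implements that entire pipeline as a library with a thin CLI.

## What it does

- **Dataset curation** — positives are annotated methylation sites;
  negatives are lysines in methylation-bearing proteins with *no* annotation
  for any of the four lysine PTMs and predicted buried (relative solvent
  accessibility < 0.2). All other lysines are treated as unknown, not
  negative.
- **Redundancy reduction and splitting** — greedy incremental clustering of
  the 31-residue, lysine-centered windows at 70% ungapped identity; one
  representative per cluster (positives favoured); label-stratified
  train/validation/test splits.
- **Embeddings** — per-residue embedding matrices from an HDF5 store
  populated by any protein language model, or from a built-in synthetic
  generator that plants a class signal partially shared across the four PTM
  tasks, so the full pipeline runs with no downloads.
- **Models** — an MLP over the site residue's embedding row, and a window
  transformer: per-token dense layer, sinusoidal positional encoding,
  pre-norm self-attention blocks (4 heads by default), a flatten over the 31
  positions, and either one classification head or four task-specific heads
  over a shared trunk. Implemented in NumPy with hand-verified backprop.
- **Multitask training** — task-homogeneous minibatches; the loss
  L = γ·L_CE,me + L_CE,ub + L_CE,ac + L_CE,su with the per-batch gating that
  makes exactly one term active, so only the shared trunk and the batch's
  head receive updates (partial parameter sharing). Adam, early stopping on
  validation loss, randomized hyperparameter search selecting on validation
  AUPRC.
- **Evaluation** — PR/ROC curves and areas verified against brute-force
  threshold enumeration, precision at fixed recall, and prevalence-corrected
  precision PCPr = TP/(TP + w·FP) with w the ratio of the deployment
  imbalance (e.g. 1:36) to the test imbalance (e.g. 1:6.5).
- **Discovery** — proteome-wide lysine scanning, methylome-size
  extrapolation (predicted × precision / recall), score-matched candidate
  sampling for validation, and mutation delta-score analysis of missense
  mutations near lysines.
- **PRM-MS support** — in-silico tryptic digestion (K/R, proline rule, zero
  missed cleavages), precursor m/z across null/mono/di/tri methylation and
  +2/+3/+4 charge states, b/y fragment masses, isolation-list CSV export,
  and validation-outcome tallies.

## Worked example

```
$ python examples/isolation_list_and_tally.py
site K14 -> tryptic peptide NPDDPQAQEK (residues 5-14, site at offset 10)
  null-methyl, +2: precursor m/z 571.2596
  mono-methyl, +2: precursor m/z 578.2675
    di-methyl, +2: precursor m/z 585.2753
   tri-methyl, +2: precursor m/z 592.2831
each methyl group adds 14.01565 Da (CH2), i.e. +7.0078 Th at +2.
y1 (unmodified K) m/z 147.1128; y5 of the mono-methyl form 617.3253 ...
100 sites x 4 methyl states x 3 charges = 1200 isolation-list rows
campaign of 100 sites: worst-case precision 68.0% (inconclusive counted
negative), conclusive-only precision 91.9%
```

The four precursor rows are what a targeted (PRM) acquisition monitors for
one site: the same tryptic peptide at each methylation state, each methyl
group shifting the +2 precursor by 14.01565/2 Th. The tally lines show the
two precision bounds a validation campaign yields: counting every
undetected peptide as a false positive (worst case) or discarding them
(conclusive-only).

Other examples: `curate_and_split.py` (dataset construction),
`evaluate_with_prevalence_correction.py` (metrics and operating-threshold
selection), `multitask_transfer_benchmark.py` (multitask vs single-task
training on synthetic embeddings), `proteome_scan_and_mutations.py`
(scanning and mutation impacts). A `methylsite` console command exposes the
same steps as subcommands (`curate`, `cluster`, `split`, `embed-synthetic`,
`train`, `evaluate`, `scan`, `isolate`, `tally`).

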