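"""Curate a labeled lysine-methylation dataset from a toy proteome, then
redundancy-cluster it and carve out train/validation/test splits.

Positives are annotated methylation sites; negatives are buried lysines
(RSA < 0.2) with no annotation for any of the four lysine PTMs, drawn only
from proteins that carry at least one methylation site.
"""

import numpy as np

from methylsite.clustering import (
    greedy_cluster,
    partition_holdout,
    select_representatives,
)
from methylsite.curation import label_sites
from methylsite.records import ProteinRecord, PTMAnnotation, RSARecord

rng = np.random.default_rng(0)
aas = list("ACDEFGHILMNPQRSTVWY")

proteins, annotations, rsa = [], [], []
for i in range(40):
    seq = list(rng.choice(aas, 120))
    k_positions = rng.choice(120, size=12, replace=False) + 1
    for p in k_positions:
        seq[p - 1] = "K"
    acc = f"TOY{i:03d}"
    proteins.append(ProteinRecord(acc, "".join(seq)))
    for p in sorted(k_positions):
        r = rng.random()
        if r < 0.25:
            ptm = rng.choice(["methylation", "acetylation", "ubiquitination",
                              "sumoylation"], p=[0.4, 0.2, 0.3, 0.1])
            annotations.append(PTMAnnotation(acc, int(p), str(ptm)))
        rsa.append(RSARecord(acc, int(p), float(rng.random())))

result = label_sites(proteins, annotations, rsa, "methylation")
n_pos = sum(r.label for r in result.records)
n_neg = len(result.records) - n_pos
print(f"curated {len(result.records)} windows: {n_pos} methylation positives, "
      f"{n_neg} high-confidence negatives "
      f"({result.skipped_missing_rsa} candidates lacked RSA)")

clusters = greedy_cluster(result.records, threshold=0.70, seed=0)
reps = select_representatives(clusters, seed=0)
print(f"redundancy reduction at 70% identity: {len(result.records)} windows "
      f"-> {len(clusters)} clusters (one representative each, positives "
      f"favoured)")

parts = partition_holdout(reps, test_fraction=0.2, validation_fraction=0.2,
                          seed=0)
counts = {}
for a in parts:
    counts.setdefault(a.partition, [0, 0])[a.record.label] += 1
for part in ("train", "validation", "test"):
    neg, pos = counts.get(part, [0, 0])
    print(f"  {part:<11s} {pos} pos / {neg} neg")
print("each split holds the same positive:negative balance to within one "
      "site per class (label-stratified sampling).")
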