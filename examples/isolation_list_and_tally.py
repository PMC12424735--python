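"""Build a PRM-MS isolation list for predicted methylation sites and tally
a validation campaign.

For each target lysine the zero-missed-cleavage tryptic peptide is derived,
and one precursor row is emitted per methylation state (null/mono/di/tri)
and charge state (+2/+3/+4): 12 rows per site.
"""

import numpy as np

from methylsite.prm import (
    build_isolation_list,
    fragment_mz,
    precursor_mz,
    site_peptide,
    tally_validation,
)
from methylsite.records import ProteinRecord

# a site whose tryptic peptide ends at the target lysine
prot = ProteinRecord("EXAMPLE", "MAVR" + "NPDDPQAQEK" + "LVSTW")
pep = site_peptide(prot, 14)
print(f"site K14 -> tryptic peptide {pep.sequence} "
      f"(residues {pep.start}-{pep.end}, site at offset {pep.site_offset})")
for state, name in enumerate(["null", "mono", "di", "tri"]):
    mz = precursor_mz(pep, state, 2)
    print(f"  {name:>4s}-methyl, +2: precursor m/z {mz:.4f}")
print("each methyl group adds 14.01565 Da (CH2), i.e. +7.0078 Th at +2.")

y1 = fragment_mz(pep, 0, "y", 1)
y5 = fragment_mz(pep, 1, "y", 5)
print(f"y1 (unmodified K) m/z {y1:.4f}; y5 of the mono-methyl form "
      f"{y5:.4f} (contains the site, so it carries the methyl mass)")

# a 100-site isolation list
rng = np.random.default_rng(3)
aas = list("ACDEFGHILMNPQRSTVWY")
proteins, sites = [], []
for i in range(100):
    seq = "".join(rng.choice(aas, 22)) + "K" + "".join(rng.choice(aas, 9))
    proteins.append(ProteinRecord(f"S{i:03d}", seq))
    sites.append((f"S{i:03d}", 23))
lst = build_isolation_list(sites, proteins)
print(f"{len(sites)} sites x 4 methyl states x 3 charges = "
      f"{len(lst.entries)} isolation-list rows")

t = tally_validation(["methylated"] * 68 + ["unmethylated_only"] * 6
                     + ["inconclusive"] * 26)
print(f"campaign of {t.n_assayed} sites: worst-case precision "
      f"{t.precision_worst}% (inconclusive counted negative), "
      f"conclusive-only precision {t.precision_conclusive}%")
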