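"""Comparative assays: rotation-aware ANI, clade clustering, identity
profile, and the diagnostic in-silico PCR.

Simulates a small panel of phage genomes, clusters them at the >95% ANI
clade threshold, profiles per-column identity of a toy alignment, and
reproduces the integration diagnostics: a short empty-site product versus a
product enlarged by exactly the prophage length.
"""

import numpy as np

from goku.compare import (
    PrimerPair,
    ani_matrix,
    cluster_clades,
    identity_profile,
    insilico_pcr,
)
from goku.core_io import revcomp, rotate
from goku.simulate import SimConfig, make_host, make_phage, plant_integration

# --- ANI and clades: two rotated/mutated copies of one phage + an outlier
phage, _ = make_phage(SimConfig(seed=5))
rng = np.random.default_rng(5)
seq = list(phage.seq)
for p in rng.choice(len(seq), size=len(seq) // 50, replace=False):  # 2% subs
    seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
from goku.core_io import SequenceRecord

twin = SequenceRecord("twin", "".join(seq), "circular")
outlier, _ = make_phage(SimConfig(seed=99))
outlier = SequenceRecord("outlier", outlier.seq, "circular")
panel = [phage, rotate(twin, 1200), outlier]
m = ani_matrix(panel)
for i, a in enumerate(m.ids):
    print("ANI", a, [f"{v:6.1f}" for v in m.values[i]])
print("clades:", cluster_clades(m, threshold=95.0))

# --- identity profile of a toy alignment
prof = identity_profile(["ACGTACGTAC", "ACGTACGTAC", "ACCTACGAAC"])
print("per-column identity:", [f"{v:.2f}" for v in prof.columns])

# --- in-silico PCR: empty site vs lysogen
cfg = SimConfig(seed=6, host_len=30_000)
rng = np.random.default_rng(6)
host, truth = make_host(cfg, rng)
ph, pt = make_phage(cfg, rng)
truth.merge(pt)
lysogen, truth = plant_integration(host, ph, truth)
site = truth.host_dif[host.id].location
assay = PrimerPair(
    "dif_site",
    host.seq[site.start - 110 : site.start - 90],
    revcomp(host.seq[site.end + 90 : site.end + 110]),
    max_product=20_000,
)
(empty,) = insilico_pcr(host, assay)
(integrated,) = insilico_pcr(lysogen, assay)
print(f"empty-site product: {empty[1]} bp; lysogen product: {integrated[1]} bp; "
      f"difference = phage length ({len(ph)} bp): "
      f"{integrated[1] - empty[1] == len(ph)}")
# The short product marks an unoccupied dif site; integration enlarges the
# amplicon by exactly the prophage length.
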