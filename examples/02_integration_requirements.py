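"""The XerC/XerD integration requirement model.

Attempts integration under the ten strain/phage/plasmid conditions of the
lysogeny assay: recombinase deletions, induced/uninduced plasmid
complementation, and phage dif-arm deletion constructs. Integration demands
both recombinases and an intact phage-like dif; only the wild type and the
induced-xerC complementation succeed.
"""

import numpy as np

from goku.miner import HostState, integrate
from goku.simulate import SimConfig, delete_dif_arm, make_host, make_phage

cfg = SimConfig(seed=42, host_len=30_000)
rng = np.random.default_rng(cfg.seed)
host, _ = make_host(cfg, rng)
phage, ptruth = make_phage(cfg, rng)
constructs = {w: delete_dif_arm(phage, ptruth, w) for w in ("C", "D", "CD")}
intact = (phage, ptruth.phage_dif[phage.id])

conditions = [
    ("wild type host, wild type phage", HostState.from_genotype(), intact),
    ("xerC deleted", HostState.from_genotype(xerC_deleted=True), intact),
    ("xerC deleted + induced xerC plasmid",
     HostState.from_genotype(xerC_deleted=True, plasmid="xerC", induced=True), intact),
    ("xerC deleted + uninduced xerC plasmid",
     HostState.from_genotype(xerC_deleted=True, plasmid="xerC"), intact),
    ("xerD deleted", HostState.from_genotype(xerD_deleted=True), intact),
    ("xerD deleted + induced xerD plasmid",
     HostState.from_genotype(xerD_deleted=True, plasmid="xerD", induced=True), intact),
    ("xerD deleted + uninduced xerD plasmid",
     HostState.from_genotype(xerD_deleted=True, plasmid="xerD"), intact),
    ("phage dif lacking XerC arm", HostState.from_genotype(), constructs["C"]),
    ("phage dif lacking XerD arm", HostState.from_genotype(), constructs["D"]),
    ("phage with no dif at all", HostState.from_genotype(), constructs["CD"]),
]

for name, state, (ph, site) in conditions:
    out = integrate(host, ph, state, phage_dif=site)
    verdict = "integrates" if out.ok else f"refused ({out.refusal_reason})"
    print(f"{name:42s} -> {verdict}")
# Matches the observed lysogeny pattern: every deletion or uninduced
# condition yields 0% lysogens; induced xerD complementation is modelled as
# non-restoring, mirroring the measured outcome.
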