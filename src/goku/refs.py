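"""Synthetic reference proteins for the six-gene gokushovirus complement.

These are deterministic, randomly generated stand-ins (labelled synthetic)
for the real VP1..VP8 reference proteins, which are external database
records. They serve two coupled purposes: the simulator back-translates them
into gene sequences, and the miner/annotator use them as homology-search
queries, so self-consistency — not biological realism — is what matters.

Gene order on the phage circle: VP4 (replication initiation), VP5 (ssDNA
switch), VP3 (scaffold), VP1 (major capsid), VP2 (minor capsid), VP8
(DNA binding).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Protein lengths (aa, incl. the initial M) per role; the summed nucleotide
#: footprint (3*aa + 3 per gene) leaves 624-1269 bp of intergenic space within
#: the 4047-4692 bp genome-length envelope the generator samples from.
ROLE_AA_LEN = {
    "VP4": 170,
    "VP5": 90,
    "VP3": 180,
    "VP1": 460,
    "VP2": 190,
    "VP8": 45,
}

GENE_ORDER = ("VP4", "VP5", "VP3", "VP1", "VP2", "VP8")

_REF_SEED = 74520


@lru_cache(maxsize=1)
def reference_proteins() -> dict[str, str]:
    """Deterministic synthetic reference protein per role (starts with M)."""
    rng = np.random.default_rng(_REF_SEED)
    out: dict[str, str] = {}
    for role in GENE_ORDER:
        n = ROLE_AA_LEN[role]
        body = "".join(rng.choice(list(AMINO_ACIDS), size=n - 1))
        out[role] = "M" + body
    return out


def reference_list() -> list[tuple[str, str]]:
    return list(reference_proteins().items())


def vp1_query() -> str:
    """The capsid-search query protein (synthetic VP1 reference)."""
    return reference_proteins()["VP1"]
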