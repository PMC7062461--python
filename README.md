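# goku

Discovery, excision and integration modelling of **dif-flanked gokushovirus
prophages** in bacterial genomes.

Gokushoviruses (*Microviridae: Gokushovirinae*) are small circular ssDNA
phages, ubiquitous in metagenomes but long thought to be strictly lytic.
A group of enterobacterial gokushoviruses instead lysogenizes its hosts
*without an integrase*: the phage carries a 28-bp *dif*-like motif and
hijacks the host's XerC/XerD chromosome-dimer resolution machinery,
integrating immediately downstream of the chromosomal *dif* site. The
integrated prophage is therefore bracketed by two *dif* motifs — a highly
conserved **bacterial-type** site upstream (≤1 mismatch from the canonical
*E. coli* *dif*) and a divergent **phage-type** site downstream (conserved
XerC-binding arm, variable spacer/XerD arm).

This package implements the full computational workflow around that
biology, exercised end-to-end on synthetic data with a ground-truth oracle:

- **`goku.core_io`** — sequence/interval model, the *dif* grammar
  (11-bp XerC arm + 6-bp spacer + 11-bp XerD arm), circular-sequence
  utilities, FASTA/GFF3/BED/TSV I/O.
- **`goku.simulate`** — generator for host chromosomes, phage genomes
  (4047–4692 bp, gene order VP4 VP5 VP3 VP1 VP2 VP8), planted integrations,
  and MAG sets with decoy motifs; every planted feature is recorded in a
  `GroundTruth` object.
- **`goku.annotate`** — greedy longest-ORF gene caller (minimum gene length
  110 bp, maximum overlap 50 bp), translated role assignment against
  reference proteins, and the coding-context classifier.
- **`goku.miner`** — the discovery engine: six-frame seeded capsid (VP1)
  homology search, detection of the attachment-site direct repeat (identical
  17-mers within 5-kb flanks, with a PWM fallback for diverged phage difs),
  *dif* classification, excision of the circular replicative form, and the
  XerC/XerD integration requirement model.
- **`goku.difscan`** — position-weight-matrix *dif*-motif search with
  analytic null calibration, iterative retraining, and the filtering rules:
  coding-region hits removed (VP4 N-terminus excepted), sub-threshold hits
  rescued when ≥15 bp identical to a confirmed motif in a non-coding region.
- **`goku.compare`** — rotation-aware ANI by global alignment,
  single-linkage >95 %-ANI clade clustering, per-column alignment identity
  profiles, and in-silico PCR for the integration diagnostics.

## Worked example

`examples/01_simulate_and_mine.py` simulates a lysogen and rediscovers the
prophage:

```
host 50000 bp + phage 4205 bp -> lysogen 54205 bp
prophage called at 25237-29442 (4205 bp); truth: 25237-29442
upstream dif:   bacterial_like (1 mismatches vs canonical)
downstream dif: phage_like (XerC arm 0 mm, spacer+XerD 3 mm)
gene order on excised genome: VP4 VP5 VP3 VP1 VP2 VP8
excised genome identical to input phage (rotation-normalized): True
restored host identical to input host: True
```

The called region runs from the first base after the bacterial *dif*
through the last base of the phage *dif*, so excision yields the circular
replicative-form genome (carrying the phage *dif* once) and leaves the
chromosomal *dif* intact — the geometry that makes the lysogeny cycle
reversible. The other examples cover the ten-condition integration
requirement table (`02`), the iterative *dif* scan with its filters (`03`),
and ANI/clades/identity-profile/PCR diagnostics (`04`).

A thin CLI mirrors the library: `goku simulate`, `goku annotate`,
`goku mine`, `goku integrate`, `goku scan-dif`, `goku ani`, `goku clades`,
`goku profile`, `goku pcr`, `goku io validate`.

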