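# kinmeth

Single-molecule detection and long-read phasing of bacterial DNA
methylation from SMRT sequencing kinetics.

## The problem

SMRT sequencing records, alongside every base call, the inter-pulse
duration (IPD) — the waiting time before the polymerase incorporates the
next nucleotide.  IPDs are systematically elevated when the template base
is modified, which makes N6-methyladenine (6mA) and N4-methylcytosine
(4mC), the two dominant marks of bacterial methylomes, directly detectable
from sequencing kinetics.  The standard analysis aggregates IPDs across
all molecules covering a genomic position, which detects methylated
*positions* but is blind to *heterogeneity*: subpopulations of cells with
a phase-variable methyltransferase (MTase) switched off, stochastic
per-site methylation by a processivity-limited enzyme, or the transient
hemi-methylation behind a replication fork all disappear into the
population average.

`kinmeth` implements the single-molecule alternative for microbiologists
and epigenomics groups working with bacterial SMRT data.  Because each
sequencing molecule is one DNA fragment from one cell, molecule-resolved
kinetic scores turn a methylome experiment into a single-cell-resolution
epigenetic assay.

## The statistics

Let `log IPD` values be per-read normalized (log-transform, subtract the
read mean) and let a whole-genome-amplified (WGA) sample — amplification
erases all methylation — provide the kinetic null.  With native molecule
*m*, strand *s* and genomic position *p*:

* **Agg_SN** (aggregate, single nucleotide — the classical score):
  `Agg_SN(s, p) = mean_all-molecules(log IPD_native) − mean(log IPD_WGA)`
* **SM_SN** (single molecule, single nucleotide):
  `SM_SN(m, s, p) = mean_subreads(log IPD_native at m, s, p) − mean(log IPD_WGA at s, p)`.
  Its precision is set by cov_SM, the number of subread passes the
  molecule contributes — short-insert libraries (~250 bp under an 8–12 kb
  polymerase read) give cov_SM of 10–20.
* **SM_P** (single molecule, pooled): for a long contiguous read,
  `SM_P(m, s) = mean(log IPD_native over all motif sites on m, s) −
  mean_sites(WGA per-site means)`.  One number per molecule that phases
  MTase activity along single DNA fragments.

For 6mA, methylated sites sit near SM_SN ≈ +2 natural-log units and
unmethylated sites near 0, so the genome-wide SM_SN distribution of a
motif is a two-component Gaussian mixture; an EM fit reads off the
methylated fraction with no ad-hoc threshold.  Molecule-level calls are
made against empirical FDR curves computed from a matched negative
control (the WGA sample, or IPD values shuffled across molecules).

The package also ships a seeded synthetic-kinetics generator
(`kinmeth.synthetic`) that emulates molecule/subread structure, sequence
context bias shared between native and WGA twins, alignment errors and
configurable methylation regimes — so every claim above is testable end
to end without any sequencing data.

## Worked example

Simulate a 120-molecule short-insert sample in which the MTase methylates
each GATC site with probability 0.6 (intracellular stochastic
methylation), then score and estimate the methylated fraction:

```sh
$ cat sim.yaml
seed: 7
reference_length: 20000
n_molecules: 120
read_length: 12000
regime: stochastic
p_site: 0.6
motif: {iupac: GATC, modified_index: 1, name: GATC}

$ kinmeth simulate --config sim.yaml --out-dir fx
$ kinmeth smsn --native fx/native.tsv --wga fx/wga.tsv \
      --ref fx/reference.fasta --motif GATC:1 --out smsn.tsv
133 SM_SN scores -> smsn.tsv
$ head -4 smsn.tsv
molecule_id     strand  ref_pos cov_sm  score
mol000001       0       10197   15      -0.29357847
mol000001       1       10198   14      1.2927137
mol000007       0       16598   15      0.300398407
$ kinmeth mixture --scores smsn.tsv --out mixture.json
methylated fraction 0.592 (components 0.022/1.955) -> mixture.json
```

Each score row is one molecule's kinetic evidence at one strand of one
GATC site: `mol000001` was unmethylated at position 10197 on the forward
strand (score ≈ 0) but methylated on the reverse strand at 10198
(score ≈ 1.3–2) — single-molecule, strand-resolved detection.  The EM fit
finds the two components at 0.02 and 1.96 (sd ≈ 0.5 each) and estimates
the methylated fraction at 59.2%, recovering the injected 60% without any
score threshold.

For phasing, `kinmeth smp` computes per-long-read SM_P scores (with an
optional IPD-shuffled control via `--shuffle-seed`), and `kinmeth fdr`
turns a score table plus a control table into an empirical FDR curve for
calling methylated or non-methylated molecules.  `kinmeth roc` tabulates
sensitivity/specificity over cov_SM bins.  Aligned kinetics are read from
the plain-text TSV dialect written by `simulate`, or from an aligned BAM
with a per-base IPD tag (`kinmeth.io.read_pacbio_bam`).

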