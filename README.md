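# cistrio

Combinatorial cistrome integration for regulatory genomics: tools for
asking how a nuclear receptor's genome-wide binding is shaped by the
pioneer factors and cofactors that share its sites. The motivating
setting is estrogen receptor α (ERα) in ER-positive breast cancer, where
FOXA1, GATA3 and the orphan nuclear receptor NR2F2 pre-occupy accessible
chromatin and jointly cover the bulk of ERα binding sites — but every
stage is generic over BED peak sets, tag tracks and expression/survival
tables.

The package is aimed at computational biologists who already have called
peaks (MACS-style BED/narrowPeak) and aligned-tag positions and want the
integrative layer on top:

* **Cofactor screen** — rank candidate cistromes against an anchor
  cistrome by the *overlap coefficient*. Two denominator conventions are
  in circulation, so both are always reported: overlap count divided by
  the anchor peak count, and the fraction of merged-union peaks touched
  by both cistromes.
* **Binned signal quantification** — each site is extended ±2 kb from
  its center and split into 40 bins of 100 bp; per-bin tag counts are
  scaled by 10⁷ / (total mapped reads), i.e. reads per 10 million mapped
  reads per 100-bp bin, so tracks of different depth are comparable.
* **Co-binding S-codes** — each anchor site gets a binary membership
  string over an ordered factor list (with order GATA3, NR2F2, FOXA1,
  `S110` means bound by GATA3 and NR2F2 but not FOXA1), plus coverage
  fractions by cardinality and an NMF (multiplicative updates, Frobenius
  loss) of the site × factor signal matrix.
* **Super-enhancer screen** — ROSE-style stitch-and-rank: constituents
  within 12.5 kb are stitched (optionally excluding promoter-proximal
  peaks), regions are scored by summed activity-mark signal, rank and
  signal are scaled to [0, 1], and the cutoff sits where a slope-1 line
  is tangent to the signal-vs-rank curve; regions above it are
  super-enhancers, each assigned its nearest TSS.
* **Knockdown perturbation** — per-site log₂ fold change between control
  and knockdown libraries, classified weaker / unchanged / stronger at a
  symmetric 1.5-fold threshold, plus condition-level peak loss (Venn
  counts of self-merged peak sets).
* **Expression-code survival** — patients coded high/low per gene
  relative to the cohort mean (E-codes), Kaplan–Meier curves per code
  group and log-rank comparison (lifelines-backed), with undersized
  groups flagged for exclusion.
* **Synthetic data** — a generator that plants all of the above
  structure (combinatorial co-occurrence, cardinality-graded enrichment,
  heavy-tailed activity intensity, cofactor-dependent knockdown
  attenuation, code-shifted hazards) and returns its ground truth, so
  every stage is testable by parameter recovery without external data.

## Worked example

The `demo` subcommand runs the whole pipeline on synthetic data:

```bash
cistrio demo --seed 7 --sites 2000 --out demo_out/
```

```
cistrio demo pipeline summary
seed: 7
latent sites: 2000
[simulate]
anchor peaks: 2000
GATA3 peaks: 1407
NR2F2 peaks: 1177
FOXA1 peaks: 780
[screen]
GATA3: overlap=1407 coeff_anchor=0.7035 coeff_merged=0.7035
NR2F2: overlap=1177 coeff_anchor=0.5885 coeff_merged=0.5885
FOXA1: overlap=780 coeff_anchor=0.39 coeff_merged=0.39
[combos]
bound by 0 factor(s): 0.1585
bound by 1 factor(s): 0.2495
bound by 2 factor(s): 0.3435
bound by 3 factor(s): 0.2485
covered (>=1 factor): 0.8415
nmf reconstruction error: 9744.93
[density]
central anchor density S000: 80.6364
central anchor density S001: 151.811
central anchor density S010: 152.325
central anchor density S011: 296.28
central anchor density S100: 155.473
central anchor density S101: 297.007
central anchor density S110: 291.963
central anchor density S111: 581.032
[superenhancer]
stitched regions: 408
super-enhancers: 29
unique genes: 28
[perturb]
weaker: 0.5915
unchanged: 0.3905
stronger: 0.018
peaks lost fraction: 0.655
[survive]
e-code groups tested: 8
log-rank statistic: 38.3767
log-rank p: 2.56929e-06
```

Reading it: the generator planted a co-occurrence design in which the
three factors cover 85% of anchor sites (recovered: 0.8415 at this small
n), with 25% of sites bound by all three; central anchor density is
graded by how many factors co-bind a site (S111 ≈ 581 vs ≈ 150 for
single-factor classes, in reads per 10 M mapped per 100 bp); 29 of 408
stitched regions carry the planted heavy tail of activity signal and are
called super-enhancers; the knockdown attenuates anchor binding at
cofactor-bound sites, classifying 59% of sites weaker; and the planted
hazard structure across E-code groups gives a log-rank p of 2.6 × 10⁻⁶.
Every table behind these numbers (per-site codes, rank curve, KM curves,
…) is written next to `summary.txt`.

Individual stages are available as `cistrio {simulate, screen, combos,
density, se, perturb, survive}` on your own BED/TSV inputs; run any
subcommand with `--help`.

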