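# sevmir

Analysis of the tumor-cell **miRNA secretome**: which miRNAs does a cancer
cell sort into its small extracellular vesicles (sEVs), what sequence
signals and RNA-binding proteins drive that sorting, which cell types do
the secreted miRNAs plausibly target, and does the secretory signature
carry clinical information?

The package implements the full computational chain as a tested, reusable
pipeline, driven by a synthetic-data generator with known planted ground
truth, so that every screen can be validated end to end without any
download. Real inputs (a count matrix from a miRNA-seq experiment, mature
sequences, interaction tables, a clinical cohort) plug into the same file
contracts.

## What it computes

Starting from a miRNA × sample count matrix of paired cell and sEV
samples:

1. **Differential abundance** — median-of-ratios size factors s_j
   (refined by one trim pass against composition bias),
   method-of-moments NB dispersion α̂_g (variance μ + αμ²), and a
   per-miRNA Wald test of log(μ_sEV/μ_cell). miRNAs with
   p_adj < 0.05 and log₂FC > 0 are classified *secretory*, with
   log₂FC < 0 *retained* (an optional strict profile requires
   |log₂FC| > 1).
2. **Motif screen** — every k-mer over {A,C,G,U}, k = 4..7, defines a gene
   set (miRNAs whose mature sequence contains it; sets with < 6 members
   dropped). Each set is scored on the log₂FC-ranked list with the
   weighted Kolmogorov–Smirnov running-sum enrichment score ES,
   normalized to an NES against size-matched random sets and BH-adjusted.
   Positive-NES motifs are candidate sEV-sorting signals, negative-NES
   motifs retention signals.
3. **RBP screen** — per RBP, a 2×2 table of interactions with secretory vs
   background miRNAs; Pearson χ² = n(ad−bc)²/(r₁r₂c₁c₂), BH adjustment,
   ranking by observed/expected ratio, top-10 report.
4. **Target-cell screen** — pooled target mRNAs of the secretory miRNAs
   tested against cell-type marker sets with the one-sided hypergeometric
   tail P[X ≥ k], X ~ Hypergeom(N, K, n); per-type bipartite subnetwork
   export. The same operation accepts any pathway GMT.
5. **Clinical signature** — per-patient score = mean of z-scored
   log₂(x+1) signature expressions; Welch t / ANOVA + Tukey contrasts
   across nodal and tumor stages including the *occult metastasis*
   subgroup (clinically N0, pathologically node-positive); Kaplan–Meier +
   log-rank survival with the lowest-p cutpoint, reported together with
   the full cutpoint scan and an optional permutation-adjusted p, because
   a minimized p is selection-biased.

## Worked example

Run the numbered analysis scripts in order (they share `results/run/`):

```bash
python analysis/01_simulate.py
python analysis/02_differential_abundance.py
python analysis/03_motif_screen.py
```

Output of the first three steps (seed 1, the default study: 500 miRNAs,
20% carrying the planted GCGC motif with a +2 log₂ sEV shift, 2 cell
lines × 2 compartments × 3 replicates):

```
planted carriers : 100 / 500 miRNAs
...
tested 500/500 miRNAs
secretory: 108, retained: 13 (screen profile)
carrier mean log2FC estimate: 1.833 (planted 2.0)
carriers recovered at p_adj<0.05: 98.0%
...
planted GCGC: rank 1/256 among 4-mers, NES 2.22, FDR 0.032
```

Reading: the differential test recovers 98% of the planted secretory
miRNAs with an effect-size estimate close to the planted +2.0, and the
motif screen ranks the planted GCGC sorting motif first among all 256
4-mers with FDR 0.03; the 5-mers directly below it (AGCGC, GCGCU, ...)
are its superstrings, which inherit the signal. Scripts 04–06 continue
with the RBP, target-cell and clinical stages.

The same pipeline is available as a CLI:

```bash
sevmir run-all --seed 1 --workdir results/run
sevmir diff --workdir results/run        # re-run one stage
```

## Layout

```
src/sevmir/          library: io_formats, synthetic_data, differential,
                     motifs, rbp, targets, clinical, pipeline, cli
analysis/            numbered narrative drivers over the library
tests/               pytest suite incl. brute-force oracle cross-checks
scripts/acceptance.py
docs/methods.md      models, parameters, numerical choices, limitations
```
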