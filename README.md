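# canemap

Integrated genetic linkage maps from **single-dose dominant markers** in an
outcrossed F1 population, with the retrotransposon-marker distribution
analyses used in sugarcane genetics: Poisson goodness-of-fit clustering
tests, adjacent-marker cluster calling, and anchored-fragment copy-number
estimation.

## The problem

Sugarcane (*Saccharum* spp. hybrids) is a highly polyploid, aneuploid crop
(~100–130 chromosomes).  Codominant genotype calling is impossible at most
loci, so maps are built from **dominant presence/absence markers** (AFLP,
EST-SSR alleles scored dominantly, retrotransposon-anchored fragments)
carried in a single dose.  Under faithful bivalent pairing, a single-dose
marker behaves like a diploid testcross locus:

* **D1** — band heterozygous in parent 1 only (*A0000000 × 00000000*),
  segregating **1:1** in the F1;
* **D2** — heterozygous in parent 2 only, also 1:1;
* **C**  — simplex in both parents (*A0000000 × A0000000*), segregating
  **3:1**.

D1 and D2 markers carry information about different meioses; only the
biparental **C loci can bridge** the two parental marker sets into a single
integrated map.  `canemap` implements the full pipeline for this design:

1. **Segregation analysis** — cross-type classification, Pearson χ² against
   1:1 / 3:1, Bonferroni filtering of distorted loci
   (α per test = α/number of tested loci).
2. **Two-point analysis** — for every informative pair, joint
   maximum-likelihood estimation of the recombination fraction
   r̂ ∈ [0, ½] and the **linkage phase** (coupling/repulsion per parent),
   with LOD = log₁₀ L(r̂) − log₁₀ L(½).
3. **Grouping** — co-segregation groups (CGs) as connected components of
   the linkage graph at LOD ≥ 6 and r̂ ≤ 0.35.
4. **Multipoint ordering** — a 4-state hidden Markov chain over the pair of
   parental transmissions, interval recombination fractions fitted by
   Baum–Welch EM; order search by exhaustive comparison (≤ 6 markers),
   frame-plus-insertion for larger groups, and sliding-window *ripple*
   polishing; per-marker linkage-phase re-checks; distances by the
   **Kosambi** function d = 25 ln((1+2r)/(1−2r)) cM.
5. **Homo(eo)logy groups** — CGs sharing ≥ 2 EST-SSR loci form an HG core
   (one shared locus attaches a putative member); Roman-numeral naming,
   within-HG ordering by cM length, `U` groups for the rest.
6. **Retrotransposon analyses** — 10 cM-bin Poisson goodness-of-fit test
   for clustered marker distribution (χ² with df = c − 1 − 1, optional
   bootstrap-calibrated p-values), adjacent-marker clusters at gaps
   < 5 cM, and element copy number as total anchored fragments divided by
   the number of enzyme/primer combinations.

Because no genotype matrix for the motivating cross is publicly available,
the package ships a first-class **synthetic population generator** whose
defaults reproduce the study conditions (188 F1 individuals, 730 single-dose
markers over three marker systems in the published proportions, ~4843 cM of
genome, six planted retrotransposon clusters) with stored ground truth for
every downstream stage.

## Worked example

```bash
cat > cfg.yaml <<'YAML'
n_individuals: 188
n_chromosomes: 4
chromosome_length_cm: 60.0
n_homolog_groups: 2
marker_counts:
  AFLP: {D1: 10, D2: 10, C: 8}
  EST_SSR: {D1: 3, D2: 3, C: 2}
  RT: {D1: 2, D2: 2, C: 1}
te_clusters: {sizes: [2], spacing_cm: 5.0}
YAML
canemap simulate --seed 7 --config cfg.yaml --out markers.tsv
canemap run --markers markers.tsv --outdir out/
```

prints

```
wrote 41 markers x 188 individuals to markers.tsv
map: 41 linked markers in 4 CGs, 195.06 cM (density 4.76 cM/marker)
```

i.e. all 41 undistorted single-dose markers were linked, the four simulated
chromosomes were recovered as four CGs totalling 195.06 cM, and the mean
inter-marker spacing is 4.76 cM.  `out/map.tsv` lists every marker with its
group and cumulative Kosambi position — note D1, D2 and C markers
interleaved on one integrated group:

```
HG  CG   marker        position_cM  system   cross_type
I   I-1  C-ESTC01344   0.00         EST_SSR  C
I   I-1  C-E34M50597   3.94         AFLP     C
I   I-1  D2-E35M49558  6.62         AFLP     D2
I   I-1  D2-E39M57425  9.80         AFLP     D2
I   I-1  C-ESTA01477   11.81        EST_SSR  C
...
```

`out/hgs.tsv` shows two CGs assembled into homeology group I through the
shared EST-SSR loci ESTA01 and ESTC01, and `out/te_clusters.tsv` reports
the planted retrotransposon cluster recovered with a 6.47 cM span.  The
copy-number estimator works straight from fragment counts:

```
$ canemap copynum --total 357 --combinations 6
357/6 = 59.50 (~60 copies)
```

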