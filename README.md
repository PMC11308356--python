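# equidiv

Genomic diversity, runs of homozygosity (ROH), inbreeding and effective
population size (Ne) for SNP-array data from closed horse populations —
with a gene-dropping simulator that provides exact ground truth, so every
stage of the pipeline can be validated without any external download.

The package is aimed at researchers monitoring genetic diversity in
managed breeds (the motivating system is a pair of native pony/horse
breeds genotyped on a 670K array): it answers how much heterozygosity a
population retains, how much of each genome lies in autozygous segments,
which genomic regions are shared as homozygous by most of a population
(candidate selection signatures), and how the effective population size
has moved over recent generations.

## What it computes

* **Heterozygosity** — per-sample observed H_O = n_het / n_nonmissing and
  cohort expected H_E = mean over SNPs of 2p(1−p) (optionally small-sample
  corrected), plus the method-of-moments inbreeding estimate
  F̂ = (O_hom − E_hom)/(n − E_hom).
* **ROH detection** — sliding-window calling on unphased genotypes: a
  10-SNP window with zero heterozygous/missing tolerance scans each
  chromosome; a SNP is "in run" when more than 5% of the windows covering
  it are homozygous; maximal flagged stretches are split at inter-SNP gaps
  > 100 kb and kept if they have ≥ 10 SNPs, span ≥ 100 kb (or 500 kb in
  the sensitivity setting) at ≥ 0.05 SNP/kb, with ≤ 1 heterozygous and
  ≤ 1 missing call. The detector is verified against an exhaustive
  interval-enumeration oracle.
* **Genomic inbreeding** — F_ROH = Σ run lengths / L_auto per sample, at
  genome, chromosome and length-class resolution (classes (0.1,1], (1,2],
  (2,4], (4,8], (8,∞) Mb), with L_auto taken from the SNP-covered map span
  or pinned to a constant.
* **ROH islands** — per-SNP incidence (share of animals whose ROH covers
  the SNP) and maximal stretches with incidence strictly above 70%,
  exported as TSV and BED; island overlap across populations.
* **LD-based Ne** — composite (unphased) r² for intra-chromosomal SNP
  pairs 0.05–40 Mb apart, binned by distance, sample-size adjusted by
  1/(βn), mapped to recombination fractions c by a pluggable modifier
  (linear, Haldane, Kosambi, Sved & Feldman), and inverted as
  Ne(c) = (1/(4c)) (1/E[r²_adj] − α) at time depth t = 1/(2c) generations.
* **Pedigree analysis** — generation equivalents (completeness), Wright's
  F_PED via the tabular kinship recursion (validated against path
  counting), and Ne from the mean rate of increase in coancestry
  Δc_jk = 1 − (1 − c_jk)^(1/((ge_j+ge_k)/2)), Ne = 1/(2 mean Δc).
* **Simulation** — founder haplotypes dropped through arbitrary pedigrees
  with Poisson recombination and exact identity-by-descent tracking, and
  constant-size Wright–Fisher populations; both emit PLINK files plus a
  machine-readable truth set.

Genotypes are read and written in the PLINK text (`.ped/.map`) and binary
(`.bed/.bim/.fam`) formats; intervals in BED.

## Worked example

The `analysis/` directory holds the numbered study scripts; they simulate
two breeds (a 60-founder population with a moderate close-mating share and
a 24-founder bottlenecked one), then run the full analysis:

```bash
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_qc_heterozygosity.py
python analysis/03_roh_inbreeding.py
python analysis/04_roh_islands.py
python analysis/05_ne_trajectory.py --seed 1
python analysis/06_pedigree_analysis.py
```

prints, among other lines:

```
breed_a: H_O = 0.372 (range 0.278-0.382), H_E = 0.369
breed_b: H_O = 0.370 (range 0.182-0.392), H_E = 0.369
breed_a: 792 ROH at >= 100 kb; mean F_ROH = 0.018 (range 0.000-0.243); r(F_ROH, truth) = 0.999
breed_b: 1699 ROH at >= 100 kb; mean F_ROH = 0.043 (range 0.002-0.507); r(F_ROH, truth) = 1.000
breed_a: 2 islands above 70% incidence on chromosomes 3,7 (peak incidence 0.90)
breed_b: 2 islands above 70% incidence on chromosomes 5,7 (peak incidence 0.89)
shared islands: 1 overlapping pairs on chromosomes 7; largest overlap 295,859 bp
large_pop: true Ne = 150; recent estimate 123 at t ~ 0.9 generations
bottleneck_pop: true Ne = 50; recent estimate 43 at t ~ 0.9 generations
F_ROH ~ F_PED: r = 0.74 (p = 2.45e-22)
```

Reading these: both simulated breeds retain similar heterozygosity, but
the bottlenecked breed carries more than twice the genomic inbreeding,
and per-sample F_ROH tracks the simulator's true autozygous fraction
almost perfectly. Island calling recovers exactly the three engineered
swept regions (private on chromosomes 3 and 5, shared on chromosome 7,
where the 300 kb engineered overlap is measured as 295,859 bp — the
nearest SNP-bounded interval). The LD trajectory recovers the census
sizes of the two constant-size populations within ~20% at the most recent
time point.

The same stages are available as a CLI (`equidiv qc|het|roh|froh|islands|
ne|pedigree|coverage-check|simulate|run-all`) for use on real PLINK
filesets; `equidiv run-all --config run.yaml` executes the whole pipeline
from one config and writes a hash-stamped manifest.

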