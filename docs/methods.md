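# Methods

This note records the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and
does not emulate, and the design decisions taken where more than one
reasonable construction existed.

## Genotype representation and I/O

Genotypes are stored as allele-b dosage codes {0, 1, 2} with −1 for a
missing call, in a samples × markers `int8` matrix alongside a marker map
(chromosome label, id, 1-based physical position, allele labels) and a
sample registry. Allele orientation is deliberately not resolved: every
statistic in the package depends only on het/hom status or on allele
frequency, both invariant under a 0↔2 relabelling.

Internal coordinates are 1-based inclusive; BED export converts interval
[s, e] to the 0-based half-open (s−1, e). Both PLINK dialects are
supported bit-exactly (binary: SNP-major v1, magic `6c 1b 01`, two bits
per call, 00/01/10/11 = hom-a/missing/het/hom-b packed low-bits-first).
At load, markers are sorted by (chromosome, position) with chromosome
order taken from the declared autosome list (default "1".."31", the horse
autosomes); non-autosomal labels are dropped with a logged count and
duplicate (chromosome, position) pairs keep the first occurrence.

## Quality control

Two profiles reflect the different sensitivities of the downstream
stages: the ROH profile filters only on call rate (SNP missingness
> 0.10, then sample missingness > 0.10), because pruning low-MAF markers
would delete exactly the monomorphic stretches that ROH are made of; the
diversity profile adds MAF ≥ 0.05 for heterozygosity and LD work. The
declared order (SNP call rate → sample call rate → MAF, each recomputed
on the current matrix) is swept to a fixed point: removing a sample can
push a marker's missing rate over threshold, and the contract is that the
returned matrix satisfies every threshold simultaneously, which also
makes the operation idempotent. Two sweeps suffice in practice; the
report accumulates per-stage removal counts.

PCA for outlier screening mean-imputes missing calls per marker, scales
each marker by (x − 2p)/√(2p(1−p)) (monomorphic markers excluded), and
takes the top singular vectors of the centred matrix, with the sign fixed
so the largest-magnitude coordinate is positive.

## Heterozygosity

H_O is a per-sample ratio over non-missing calls. Cohort H_E is averaged
over markers (the quantity is per-locus by definition; an alternative
per-individual average would weight markers by each sample's missingness
pattern). The default applies the small-sample factor 2n/(2n−1) to each
marker's 2p(1−p), matching the expected-homozygosity convention of the
standard array-QC tools; a toggle disables it. Monomorphic markers
contribute 0 and stay in the mean. The method-of-moments inbreeding
estimate per sample uses the same expected-homozygosity convention.

## ROH detection

Sliding-window semantics, in three separable operations so each can be
tested against an oracle:

1. every block of `window_size` consecutive SNPs (stride 1) is homozygous
   iff it contains ≤ `window_max_het` heterozygous and ≤ `window_max_miss`
   missing calls (defaults 10/0/0);
2. each SNP's in-run proportion is homozygous-covering-windows divided by
   covering windows; near chromosome ends the denominator is the true
   covering count (no padding). The flag threshold is strict
   (proportion > 0.05 by default; the proportion parameter is exposed
   because published analyses rarely print it);
3. maximal flagged stretches are split at inter-SNP gaps > `max_gap_bp`
   (100 kb) and each candidate survives iff it has ≥ `min_snp` (10) SNPs,
   spans ≥ `min_length_bp` (100 kb; 500 kb as the sensitivity setting),
   has ≥ `min_density_snp_per_kb` (0.05) and carries ≤ 1 heterozygous and
   ≤ 1 missing call.

Run coordinates are SNP positions (first/last SNP of the stretch) and run
length is end − start, so a run's length equals the distance its SNPs
span. With a window-level heterozygote tolerance of zero the run-level
allowance of one heterozygote is in practice vacuous — a heterozygous SNP
is covered only by non-homozygous windows, gets proportion 0 and is never
flagged — but the run-level caps are enforced as post-filters anyway so
that permissive window settings cannot smuggle extra heterozygotes into
reported runs. Candidates are maximal by construction and never merged
across gaps.

The detector is validated two ways: an exhaustive oracle enumerates every
SNP interval of small instances and applies the flag/gap/filter
definition directly (exact set equality on 1,000+ random instances, plus
a derandomised property test varying the window tolerance and threshold),
and gene-dropping simulations (below) provide base-pair recall against
known autozygous segments.

`coverage_validation` answers "could these settings call a run here at
all?" without genotypes: marker stretches are split at over-limit gaps
and stretches passing the min-SNP/length/density constraints contribute
their span; the statistic is covered span / L_auto. On 670K-like maps the
settings leave essentially the whole SNP-covered genome detectable, which
is the justification for interpreting F_ROH as a genome fraction.

## F_ROH, length classes, islands

F_ROH divides each sample's summed run length by L_auto; L_auto defaults
to the map's summed per-chromosome span (last − first SNP) and can be
pinned (e.g. 2281 Mb for the 670K equine map) for comparability across
studies. Per-class values use the same denominator, so classes sum
exactly to the total; per-chromosome values use that chromosome's span.
Length classes are left-open/right-closed: (0.1,1], (1,2], (2,4], (4,8],
(8,∞) Mb — a 1.0 Mb run is "short", a 1.000001 Mb run is not.

Island incidence at a SNP is the share of *all* samples (not only ROH
carriers) with a run covering the position; runs of one sample are
disjoint, so a difference-array sweep counts carriers exactly. Islands
are maximal stretches with incidence strictly above the threshold
(default 0.70 — "shared by more than 70%"), bounded by the first/last SNP
of the stretch; raising the threshold provably yields islands nested
inside the lower-threshold ones. Cross-population comparison intersects
island intervals (the populations are first restricted to their shared
marker set); joint incidence across pooled populations is deliberately
not computed, since the two cohorts' sizes would weight it arbitrarily.

## LD-based Ne

For unphased data, LD between two markers is the composite r²: the
squared Pearson correlation of dosage codes over samples with both calls
present (pairwise-complete; pairs with fewer than two joint observations
or a monomorphic member are skipped). Pairs are intra-chromosomal within
[0.05, 40] Mb, binned into 30 equal-width distance bins (the bin scheme
is configurable; equal width is the simplest scheme that leaves the
recent end well populated), and adjusted as r²_adj = r² − 1/(βn) with
β = 1 and n the pair's joint sample count — the null expectation of a
squared correlation over n observations.

Each bin's mean distance maps to a recombination fraction c through a
pluggable modifier, all of which agree to first order as d → 0:

* linear: c = d (d in Morgans at 1.24 × 10⁻⁸ per bp by default);
* Haldane: c = (1 − e^(−2d))/2;
* Kosambi: c = tanh(2d)/2;
* Sved & Feldman (default): the Haldane fraction corrected to the
  effective recombination of the two-locus drift approximation,
  c* = c(2 − c)/(2(1 − c)²), i.e. the value that makes 1/(4Nc*) equal the
  (1 − c)²/(2Nc(2 − c)) drift LD. c* exceeds ½ for loosely linked loci,
  where the plain 1/(4Nc) inversion understates recombination and would
  otherwise inflate Ne — this was confirmed directly against the
  Wright–Fisher simulator, whose measured inter-chromosome composite r²
  (0.0134 at n = 100, N = 100) matches a drift term of this family plus
  the 1/n sampling term, not 1/(1 + 4Nc) + 1/n.

The trajectory point for a bin is Ne = (1/(4c)) (1/mean r²_adj − α) at
t = 1/(2c) generations ago, α = 2.2 by default (the constant absorbing
mutation; at the recent end, where 4Nc ≫ α, its value is immaterial).
Bins with non-positive adjusted LD, and bins whose Ne comes out negative
(1/r²_adj < α), are excluded with a log message rather than clamped.
Points are reported newest (largest c) to oldest. There is no sampling
inside the estimator, so the trajectory is deterministic given the
matrix.

Validation: on constant-size Wright–Fisher populations (census 100, 200
generations, 100 sampled, 20 chromosomes × 1,000 SNPs at 100 kb spacing)
the most recent trajectory point lands within ±35% of the census size in
10 of 10 seeds (estimates 78–97), with a mild downward bias expected from
inverting an approximate drift formula at loose linkage.

## Pedigree analysis

Unknown parents are founders; acyclicity is verified and a topological
order fixed at construction. Generation equivalents follow the
slot-counting recursion ge_i = Σ_parents ½(1 + ge_parent) (a fully known
g-generation pedigree gives ge = g). Inbreeding is Wright's F via the
tabular kinship recursion — kinship(x, x) = (1 + F_x)/2, kinship(x, y)
with x later in the order = mean over x's parents of kinship(parent, y) —
computed lazily pair-by-pair with memoisation instead of a dense
relationship matrix, so memory stays bounded by the pairs actually
requested. The recursion is validated to 1 × 10⁻¹² against an independent
path-counting implementation (node-disjoint ancestor paths,
Σ (½)^(l₁+l₂+1)(1 + F_A)).

Coancestry-rate Ne over a reference cohort uses per-pair rates
Δc_jk = 1 − (1 − c_jk)^(1/((ge_j + ge_k)/2)) and Ne = 1/(2 mean Δc), over
all pairs within the cohort (the cohort rule is a parameter; all pairs in
the sampled birth cohort is the default). A mutually unrelated cohort has
zero mean rate and Ne = ∞, reported as infinity rather than an error. On
simulated closed populations (census 20, 10 generations) the estimate
tracks the census within ~30%.

## Synthetic data

The generator produces array-like genotypes whose ground truth is known
exactly, for two regimes:

* **Gene dropping.** Founder haplotypes are drawn site-wise from a
  configurable frequency law and labelled per founder copy; every
  transmitted gamete is a recombinant mosaic of the parent's two
  haplotypes. True autozygous segments are the maximal marker runs where
  an individual's two founder labels coincide.
* **Wright–Fisher.** Discrete non-overlapping generations, two parents
  drawn uniformly with replacement per offspring, recombination as above,
  no mutation; the census size is the true Ne.

Crossovers follow a Poisson process (no interference). Restricted to the
marker loci this is equivalent to independent switches between adjacent
markers with the Haldane probability (1 − e^(−2dr))/2, which is how
gametes are generated — exact in distribution at the markers and fully
vectorisable. Consequently truth segments are recorded at marker
resolution (first to last coinciding marker), the same resolution at
which ROH can be observed; segment ends between markers are not
represented, which biases recorded truth lengths short by about one
marker spacing per end (≈ 3.4 kb at the default density) — negligible at
the ≥ 100 kb scales analysed.

Defaults emulate a desk-scale slice of a 670K-array dataset: 10
chromosomes × 17 Mb × 5,000 markers (≈ 0.29 SNP/kb, the array's
density), founder minor-allele frequencies uniform on [0.05, 0.5] (an
ascertainment-biased common-variant spectrum, giving H_E ≈ 0.35–0.37,
in the range typical of array data on outbred cohorts), recombination
1.24 × 10⁻⁸ per bp matching the Ne analysis assumption, and optional
missingness/genotyping error injected *after* the truth is recorded
(an error flips a genotype to a uniformly chosen different code).
`plant_sweep` additionally engineers a selection signature — a chosen
fraction of samples made homozygous across an interval — as the known
truth for island calling.

What the generator does not emulate, and hence what passing tests do not
show about real data: genotyping error that is clustered or
allele-biased, array ascertainment beyond the MAF spectrum, population
structure within a cohort, mutation (irrelevant over tens of
generations), crossover interference, overlapping generations and
unequal sex ratios, and deep population history — the gene-dropped
cohorts carry only the inbreeding their 4–5 recorded generations create,
so their F_ROH levels sit well below those of breeds with centuries of
closed breeding, and the validation checks compare against the
simulator's own truth rather than against any published cohort's values.

## Validation problem sizes

The recovery checks (in `equidiv.validation`, exercised by
`tests/test_acceptance.py` and recomputed by `scripts/acceptance.py`) use:
1,000 random ≤ 50-SNP instances for the ROH oracle; a 100-sample
gene-dropped cohort on the default 10 × 17 Mb genome for F_ROH recovery
(Pearson r vs truth ≈ 1.0, base-pair recall of ≥ 1 Mb truth segments
100%, < 0.2% of detected bp outside ≥ 100 kb truth segments); 10
Wright–Fisher replicates for Ne; a 100-individual random pedigree with a
30% full-sib mating share for pedigree exactness; 50 random incidence
tracks for island nesting; and a 500-sample Hardy–Weinberg cohort for
H_O/H_E consistency. These sizes were chosen so every check measures its
statistic with comfortable margin while the whole harness stays a
few-minute desk-scale run.

## Known limitations

* ROH calling is window-based only; HMM or genotype-likelihood callers
  are out of scope, as are consecutive-runs (window-free) modes.
* No HWE or LD pruning is implemented anywhere — deliberately for the ROH
  profile, and out of scope elsewhere.
* The Ne estimator reports no confidence intervals and relies on an
  equilibrium drift approximation; its time attribution t = 1/(2c) is the
  usual coarse mapping and the recent-most points (t < 2 generations)
  should be read qualitatively.
* Pedigree analysis does not model unknown-parent groups; unknowns are
  founders with F = 0.
* VCF input, genome-build liftover and sex chromosomes are not supported.
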