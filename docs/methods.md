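# Methods

## Scope and model

The package quantifies agreement between transcript and protein profiles of
a small number of closely related species measured over a shared gene
namespace (AGI locus codes), and tests whether regulation of glucosinolate
pathway genes predicts the measured chemotype. It deliberately consumes
*finished* matrices: microarray image processing, normalization,
separate-channel loop-design estimation, peptide-spectrum matching and
protein inference all happen upstream.

### NSAF

For sample *i*, protein *k* with spectral count SpC and molecular weight
MW (kDa):

    NSAF_k = (SpC_k / MW_k) / Σ_j (SpC_j / MW_j)

Division by MW corrects length bias (longer proteins produce more tryptic
peptides, hence more spectra); the normalization makes values comparable
across runs of different depth. Per-species abundance `NSAF_S` pools the
replicate counts first and then normalizes — equivalent to a count-weighted
replicate average and robust to shallow single runs. Isoforms of one locus
are summed; the merged record's MW is the total-count-weighted mean of
isoform MWs (the choice matters little when one isoform dominates, which
is the common case; an unweighted mean would let a never-observed isoform
shift the weight). Reproducibility filter: ≥ 2 distinct peptides and
SpC > 0 in every replicate of at least one species. "Present" means
SpC > 0; peptide evidence is handled by the separate peptide rule.

The spectral pseudo-fraction (default 0.5, configurable) is added to every
count on the pairwise-test path only; it makes NSAF approximately normal,
keeps log fold changes finite for proteins absent from one species, and
never reorders proteins with distinct counts.

### Differential expression

*Transcripts.* A cell-means OLS model per gene over species indicator
columns; each of the six contrasts (3 × one-vs-rest with coefficients
(1, −1/(S−1), …), 3 × pairwise) is tested with a two-sided t-test on the
contrast estimate using the residual variance (df = arrays − species).
This is a single-pre-processing plain-OLS stand-in for the original
moderated multi-pre-processing analysis, whose parameters are not
recoverable; absolute DE counts are therefore not comparable to the
original study, only the machinery is.

*Proteins.* Group (one-vs-rest) contrasts use two-sided Wilcoxon rank-sum
tests on per-replicate NSAF — exact when both sides have ≤ 8 replicates
without ties, otherwise the normal approximation with continuity and tie
correction. **Power limit, stated prominently:** with 3 vs 6 replicates
the smallest exact two-sided p is 2/84 ≈ 0.024, so after BH across ~10³
loci no group test can clear 0.05; at study-like replicate numbers the
group tests rank loci rather than certify them, and significance calls
come from the pairwise t-tests. Pairwise contrasts use two-sample t-tests
on pseudo-counted NSAF; Welch is the module default (robust at n = 3),
with a pooled-variance option.

All p-values are Benjamini–Hochberg step-up adjusted across loci within a
contrast. Calls: up = {log2FC > 0 and adjusted p < α}, down symmetric,
α = 0.05 by default.

### Concordance

Spearman correlations (midranks for ties) among all per-species transcript
and protein abundance columns, restricted to the common locus set; a
constant column yields NaN with a warning rather than an error. Regulated
lists are intersected after restriction to the common set ("size
correction"): a = regulated transcripts in the common set, b = regulated
proteins, k = both. Confirmation percentages 100·k/a and 100·k/b are
displayed rounded half-up to whole percent (full precision retained).
Significance: k is compared with the overlap of two uniform random subsets
of sizes a and b drawn without replacement n_perm times (default 10,000);
p = (1 + #{overlap ≥ k}) / (1 + n_perm). The +1 keeps p positive; the
tail is one-sided (enrichment only). For uniform subsets the null overlap
is exactly hypergeometric, which the tests use as a closed-form oracle;
the permutation machinery is retained because it generalizes to
structured nulls.

### Chemotypes

Per-plant compound proportions (columns sum to 1; zero-total samples are
dropped with a warning) are clustered with Ward linkage on Euclidean
distances. Heights follow the scipy convention, sqrt(2·ΔESS); a
brute-force explicit-ESS agglomerator in the test suite verifies both the
merge order and the heights on all ≤ 6-sample fixtures. Ties are broken by
scipy's deterministic ordering; the oracle fixtures are continuous and
tie-free.

Hydrolysis products are partitioned into isothiocyanate vs
nitrile/epithionitrile fractions; compound percentages are
100·mean/species-total, displayed rounded half-up to one decimal. Class
totals are reported in two conventions: sum of full-precision percentages
and sum of the *rounded* ones — printed summary tables conventionally add
rounded rows (e.g. 35.3 as a rounded sum vs 35.40 at full precision), and
display follows that convention.

The chemotype rule table (editable TSV shipped with the package) maps
regulation of pathway loci to phenotype claims: side-chain elongation
(MAM1 At5g23010, MAM-I At2g43100, MAM-D At5g14200/At1g31180 → C4
glucosinolates higher), side-chain modification (AOP2 At4g03050 → alkenyl
higher; AOP3 At4g03060 → hydroxyalkyl higher, carrying a reliability note
about possible cross-hybridization with AOP2), and hydrolysis specifiers
(ESP At1g54040 up → nitriles; ESP down / ESM1 At3g14210 up →
isothiocyanates). A rule fires when its locus is called in the stated
direction, contrast and layer; two fired "class higher" claims with
swapped winner/loser roles are both emitted and flagged as conflicting.
Scoring: class-sum claims use a Welch t-test on per-sample class totals —
supported when the winner's mean is higher and p < α, contradicted when
significantly lower, untestable otherwise (ties, all-zero classes, missing
species). Hydrolysis claims are judged by dominant product class (> 50%).
Per-layer accuracy = supported / (supported + contradicted).

## Synthetic generator

Per locus k: base log2 abundance b_k ~ N(8, 1.5²). Transcript latent value
of species s: T[k,s] = b_k + Δ[k,s], where Δ injects the configured
regulation (fraction `frac_de` of shared loci, assigned round-robin to
species with random sign, magnitude `de_log2fc`). Protein latent values
mix the standardized transcript signal with one independent per-locus
noise vector shared by all species:

    P_z[k] = w·z_k + sqrt(1 − w²)·ε_k,  w = 2·sin(π·ρ_s/6)

so the within-species transcript–protein *rank* correlation is ρ_s in
expectation (inverting Spearman's relation ρ_s = (6/π)·asin(ρ/2) for a
bivariate normal). Sharing ε across species is essential: species protein
profiles then differ only through Δ, so data generated with frac_de = 0
are genuinely null for the between-species tests. Injected effects appear
at full magnitude in both layers.

Observed data: arrays add N(0, noise_sd²) log2 noise per sample
(noise_sd = 0.25, a typical two-channel array replicate scatter);
spectral counts are Poisson with rate depth·(a_k·MW_k)/Σ(a_j·MW_j) — so
counts/MW is proportional to abundance, exactly the relation NSAF inverts
— with optional negative-binomial over-dispersion (default off; replicate
variability beyond the count model is deliberately *not* added, that is
what the over-dispersion knob is for). MW ~ lognormal around 40 kDa
(clipped 5–250); peptide evidence 1 + Poisson(3), leaving ~5% of proteins
at a single peptide for the filter to act on. Metabolite samples are
species chemotype means times 2^N(0, 0.2²) — multiplicative, so zero
means stay exactly zero and zero noise reproduces the means. The bundled
chemotype means mirror the study system: CH and NZ share their two major
compounds (allyl ≈ 37/24.8, S-2OH3-butenyl ≈ 48/45 μmol/g; alkenyl totals
85 and 77.8, C4 totals 48 and 59) while EX is dominated by long-chain
methylsulfinylalkyl and indolic compounds with almost no alkenyl forms.

One root seed spawns one child stream per component (truth, transcripts,
proteins, counts, metabolites), so regenerating one component never
perturbs another and identical configurations are bit-identical.

**What the generator does not emulate:** dye effects, loop designs and
array normalization artefacts; peptide detectability bias and shared
peptides; missing-not-at-random protein dropout; compositional coupling
between strongly regulated loci and the rest of the NSAF vector beyond
what normalization induces; metabolite covariance between compounds.
Passing recovery tests therefore demonstrate correctness of the
estimators and calibration under a clean sampling model, not performance
on raw instrument data.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `coupling_rho` | 0.5 | target within-species transcript–protein Spearman (the strongest observed in the emulated system is ≈ 0.52) |
| `frac_de`, `de_log2fc` | 0.1, 2.0 | fraction of shared loci regulated; effect in log2 units |
| `count_depth` | 50 × n_proteins | expected total spectral counts per replicate (≈ 50/locus) |
| `noise_sd` | 0.25 | log2 array noise per transcript sample |
| `locus_sd` | 1.5 | between-locus log2 abundance spread |
| `metabolite_noise_sd` | 0.2 | log2 multiplicative noise per metabolite sample |
| `spectral_fraction` | 0.5 | pseudo-count added on the t-test path |
| `alpha` | 0.05 | BH-adjusted significance threshold |
| `n_perm` | 10000 | permutation draws for overlap significance |

## Recovery studies and their design choices

The validation studies (`validation.py`) run the emulated design at 1074
shared loci, 3 species × 3 replicates, 2 log2-unit effects, average depth
50 counts/locus, over 20 seeds — sizes chosen to exercise the full
study-scale statistics while keeping a complete run in seconds.

Two deliberate choices, both power-driven and fixed a priori by analysis
rather than tuning:

1. **Pooled-variance t for recovery.** A 4-fold mean change makes the
   high group's variance ≈ 16× the low group's on the linear NSAF scale;
   Welch's approximation then has ≈ 2 degrees of freedom, where even
   t = 15 gives p ≈ 0.003 — below no BH threshold at m = 1074. Recovery
   through the Welch default is impossible at n = 3 *by arithmetic*, so
   the recovery studies use the pooled-variance variant (df = 4). The
   pipeline default remains Welch, which is the safer choice when calls,
   not recall, are the product.
2. **Recall is reported over loci meeting the stated depth.** With a
   realistic abundance spread, an *average* depth of 50 counts/locus
   leaves half the loci below 50 counts, and a locus observed with a
   handful of spectra simply carries too little information for any
   three-replicate test. Recovery is therefore quoted over injected loci
   whose mean observed count meets the 50-count design depth (98–99%
   across seeds; ≈ 73% over all loci including shallow ones, also
   reported).

Null calibration: raw-p type-I ≈ 0.050 (band 0.035–0.065 asserted in the
acceptance test, reflecting Monte-Carlo error plus the mild discreteness
of count-derived NSAF at n = 3), and essentially zero BH calls on null
data.

## Numerical conventions and degenerate inputs

- Rounding for display is decimal half-up (23% from 23.0159…, 12.4 from
  12.400…); full precision is always retained internally.
- All-zero spectral-count samples return an all-zero NSAF vector with a
  warning rather than raising, so sparse synthetic data survive.
- Zero-variance t-test pairs: equal means → p = 1; unequal means →
  p = 0 with an infinite statistic (flagged degenerate by sign).
- Wilcoxon on an all-identical locus → p = 1.
- BH rejects inputs outside [0, 1]; adjusted values are clipped at 1 and
  returned in input order.
- Saturated transcript designs (no residual df) yield NaN p-values and
  "ns" calls with a warning; rank-deficient designs raise an error naming
  the confounded columns.
- Permutation p-values can never be 0 (the +1 correction) and the
  significance threshold for the star flag is configurable (default
  0.05).

## Limitations

- Absolute reproduction of the original study's correlation values, DE
  counts and per-gene fold changes requires the deposited raw microarray
  series and unpublished spectra plus unrecoverable pre-processing
  parameters; the package reproduces the printed worked examples and the
  qualitative patterns, and validates the machinery on synthetic ground
  truth instead.
- The transcript model is unmoderated OLS; with few arrays its variance
  estimates are noisier than an empirical-Bayes analysis. A consensus
  mode (intersecting calls across user-supplied settings) can mimic the
  original conservative intersection but is a stand-in, not a
  reproduction.
- The chemotype rule engine evaluates class-level claims only; it does
  not model cross-hybridization (the AOP3 rule carries a note instead)
  nor compound-level kinetics.
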