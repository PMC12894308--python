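# Methods

## Scope and model of the data

The package analyzes genus-level compositional count data: each sample is a
multinomial draw constrained by its library size, so only relative
abundances carry information. All correlation-based inference therefore
operates on TMM-normalized relative abundances, and the synthetic generator
produces counts the same way (softmax composition → multinomial), so the
test suite exercises the pipeline on data with the same compositional
closure the real analysis sees.

## Synthetic communities

Each planted module m has a per-sample latent factor
f(m, j) ~ N(shift[treatment(j), m], 1). Taxon i in module m has
log-abundance x(i, j) = μᵢ + √r·f(m, j) + ε, ε ~ N(0, √(1−r)), which makes
the latent pairwise correlation of same-module taxa exactly r while keeping
every taxon's total log-variance at 1. Background (module-0) taxa are
mutually independent — the negative control for edge calling. Counts are
one multinomial draw of `library_size` reads from softmax(x(·, j)); the N₂O
rate is baseline + Σₘ effectₘ·f(m, j) + N(0, σ).

Presets:

- **paper_mimic** — 3 treatments (RF, VE4, VE7) × 3 replicates; 120
  bacterial genera (3 modules of 18/15/12), 80 fungal genera (4 modules of
  15/12/10/8), latent correlation 0.8, library sizes 29 000 / 34 900 reads
  (the study-scale sequencing depth per sample). Baseline 0.5
  nmol N g⁻¹ h⁻¹ with shift/effect magnitudes chosen so expected
  treatment-mean N₂O differences are a few tenths of a unit, ordered
  RF < VE7 < VE4. One bacterial module contributes negatively and one
  positively to the rate; one fungal module negatively.
- **power** — 30 samples (3 × 10), 60 genera per kingdom (modules 12/10/8
  plus 30 background), latent correlation 0.9, no treatment shifts (so
  recovery statistics are not confounded by treatment structure), module
  effects −0.25/+0.25/0, noise sd 0.1. Three replicates per group is far
  too few for stable recovery assertions; the power preset is what the
  recovery and calibration tests run on.

What the generator does **not** emulate: sequencing error, taxonomic
mis-assignment, zero-inflation beyond multinomial sampling, phylogenetic
signal in abundances, and environmental covariates that causally drive both
community and N₂O (covariates carry treatment signal only). Passing tests
show the chain recovers planted co-occurrence structure and effect signs
from compositional counts; they do not certify performance on real
communities with stronger overdispersion.

The generator exposes `expected_relative_abundance` (ratio of expected
log-normal weights, exp(μᵢ + ½)/Σ exp(μₖ + ½)); the Monte-Carlo test
verifies a 2%-abundance taxon against it to ±0.005.

## Preprocessing

- Low-abundance filter: keep taxa with mean relative abundance ≥ 1e-4 AND
  presence in ≥ 2 samples (both configurable, both logged). The filter is
  idempotent.
- TMM: reference sample = library whose 75th-percentile count fraction is
  closest to the mean of that quantity, ties broken by lowest column index
  (determinism). M-values are computed on count fractions over taxa nonzero
  in both libraries, trimmed 30% from each M tail and 5% from each A tail
  (the canonical published trims), averaged with inverse-asymptotic-variance
  (binomial) weights; factors are rescaled to geometric mean 1. Effective
  library size = raw × factor feeds the relative abundances used for
  correlation.
- Z-scores use the sample sd (ddof = 1). Zero-variance rows become
  all-zeros with a flag rather than erroring: degenerate taxa must not abort
  the pipeline and zeros contribute nothing to module means.

## Network inference

Spearman ρ uses mid-ranks for ties; two-sided p from the t approximation
t = ρ√((n−2)/(1−ρ²)) with df = n−2, with p = 0 pinned when |ρ| = 1 (within
1e-12). Against exhaustive rank-permutation enumeration the approximation's
worst two-sided error is 0.077 at n = 5, 0.048 at n = 6, 0.027 at n = 7;
the suite asserts a 0.10 bound. No multiple-testing correction is applied
by default (a BH-FDR flag would change the edge set; the default mirrors
the common thresholded-correlation practice), and the thresholds
(|ρ| > 0.7, p < 0.05) are recorded in the graph's provenance. The absolute
value is thresholded because negative edges are ecologically first-class.

Per-treatment and per-sample networks are induced subgraphs of the single
all-sample network on the taxa present there (count > 0), not re-estimated:
correlation at n = 3 per treatment is degenerate.

## Topology, modules, keystones

- "Vertices" counts non-isolated nodes (degree ≥ 1); isolated taxa carry no
  interaction information (configurable to all nodes).
- Mean clustering averages local clustering 2Tᵢ/(kᵢ(kᵢ−1)) over nodes with
  kᵢ ≥ 2 only, avoiding arbitrary 0-imputation in sparse subnetworks.
- Betweenness centralization is Freeman's: Σᵢ(B_max − Bᵢ) /
  [(V−1)·(V−1)(V−2)/2] with raw betweenness (each unordered pair counted
  once) on the non-isolated node set; the five-node star scores exactly 1.
- Modules: seeded Louvain on the unsigned, unweighted skeleton, relabeled
  1, 2, … by descending size (ties by smallest member). Q is
  Newman–Girvan modularity. Signed modularity is out of scope.
- Zi = (κᵢ − mean κ)/sd κ within the node's module, population sd, Zi = 0
  when sd = 0; keystone iff Zi ≥ 2.5 (the canonical within-module hub
  cutoff; a 1e-12 tolerance absorbs float rounding at the threshold).
  Among-module connectivity (Pi) is deliberately not computed.

## Stability

Robustness at removal fraction f = proportion of remaining nodes that keep
≥ 1 surviving edge after removing ⌊f·V⌋ uniformly random nodes; 100
repetitions per fraction by default, compared between treatments with a
Welch two-sided t-test on the repetition values at f = 0.5. This is one
standard co-occurrence-toolkit robustness; natural connectivity is a
possible alternative and would need its own calibration.

Cohesion: connectedness⁺ᵢ = mean positive off-diagonal ρ in row i (0 if
none), connectedness⁻ᵢ analogous; cohesion±ⱼ = Σᵢ pᵢⱼ·connectedness±ᵢ with
p the relative abundance. The same Spearman matrix as network inference is
used for internal consistency. An optional taxa-shuffle null correction
(each taxon's abundances permuted across samples, ρ recomputed) subtracts
the null-mean connectedness; sign constraints (⁺ ≥ 0 ≥ ⁻) are guaranteed
only in the uncorrected mode.

## Ecological statistics

Shannon in nats; Simpson as Gini–Simpson 1−Σp²; Pielou H/ln S and Heip
(e^H−1)/(S−1) flagged 0 for S = 1; Good's coverage 1−F₁/N with F₁ the
count-1 taxa. Faith's PD includes the path to the root (matching common
amplicon toolchains). Levins B = 1/Σqⱼ² over a treatment's samples; the
community value is the unweighted taxon mean (abundance weighting is a
documented alternative). ANOSIM uses mid-ranks and an add-one permutation
p; the default dissimilarity is Bray–Curtis on TMM-scaled relative
abundances. ANOVA is one-way; LSD p-values use the pooled MSE and its df;
compact letters come from maximal cliques of the
not-significantly-different graph ordered by descending mean. The N₂O rate
from an incubation series is the OLS slope of total (gas + dissolved,
Bunsen-converted: conc × (v_gas + β·v_liq)/v_liq) concentration against
time; β is a required input, never hard-coded. Module regressions take N₂O
as response and per-module mean z-score as predictor (r² and p are
direction-invariant).

## Driver attribution

PC1 composites are computed from the correlation matrix of the z-scored
block; the eigenvector sign is fixed by non-negative correlation of the
scores with the mean standardized variable (falling back to a positive
first loading when that mean is constant). The regression forest is
authored in-package (numba): bootstrap per tree, mtry = max(1, ⌊p/3⌋),
variance-reduction splits, nodes with ≤ 5 samples become leaves.
Importance = total decrease in node sum-of-squares per predictor, averaged
over trees; a conformance test checks the ranking against an off-the-shelf
forest. Model R² = 1 − MSE_OOB/var(y); at n = 9 this is an honest but
pessimistic (occasionally negative) estimate — small-sample OOB error is
noisy, which is why headline explanatory-power figures from in-model fits
at n = 9 should not be expected here. Permutation significance permutes the
response (add-one rule, so p > 0 always), refitting the forest per
permutation with derived seeds.

## Orchestration and determinism

One global seed spawns per-stage seeds via `numpy.random.SeedSequence`, so
identical config + seed yields byte-identical JSON reports (floats
serialized at full precision, keys sorted, NaN → null, ∞ → "inf"
sentinel). Modules smaller than 3 members are treated as background
singletons and excluded from module regressions and driver predictors. All
edge-calling thresholds and stage seeds are recorded in the report.

## Problem sizes in the test and acceptance runs

Recovery claims use 50 seeded power-preset runs (30 samples, 60 genera);
calibration claims use 500 null simulations each (ANOSIM: 12 samples, 199
permutations; permutation importance: 16 samples, 2 predictors, 99
permutations, 15 trees — calibration of a permutation test does not depend
on forest size, so a small forest is used). The topology oracle covers 200
random graphs of ≤ 30 nodes; the robustness oracle enumerates all removal
subsets of a 10-node graph. These sizes were chosen as the smallest at
which the Monte-Carlo tolerances quoted in the tests are meaningful.

## Known limitations

- The Spearman-threshold network has no compositional null model; spurious
  correlation induced by closure is mitigated only by TMM scaling and the
  high |ρ| cutoff (SparCC/SPIEC-EASI-style approaches are out of scope).
- Per-treatment topology comparisons rest on induced subgraphs of a single
  global network, an interpretation forced by n = 3 per treatment.
- Louvain cluster counts are algorithm- and resolution-dependent; module
  *identity* (membership, regressions) is the supported output, not the
  number of clusters.
- The permutation importance test is exchangeability-based: valid under
  independence of response and predictors, but conservative when
  predictors are strongly collinear composites.
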