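# Methods

This note documents the models and procedures implemented in `cryograd`,
the parameter defaults and why they were chosen, the synthetic study
conditions used for validation, and the numerical decisions a maintainer
would want written down.

## Pipeline model

The package analyses an elevational soil survey in five stages, each a
module with a typed surface:

1. **community_prep** — filtering and dissimilarity. Filters apply in a
   fixed order (non-target taxonomy → ASV total reads → sample total
   reads) and report counts removed at each step, so reprocessing a
   deposited table is auditable. Richness is the number of distinct ASVs
   in a single seeded subsample without replacement (multivariate
   hypergeometric) at 2,000 reads; samples below the depth are scored at
   full depth and flagged rather than resampled with replacement or
   dropped — the least-surprising policy for tables where a few samples
   sit between the inclusion cutoff (1,000 reads) and the rarefaction
   depth. Bray-Curtis uses the standard Σ|x−y| / Σ(x+y) form.

2. **gradient_stats** — the shared statistical engines. Spearman is
   Pearson on mid-ranks. The Mantel test is one-sided ("greater"), the
   standard alternative for distance association; its null permutes rows
   and columns of the second matrix jointly. BIOENV is genuinely
   exhaustive (all 2^k − 1 subsets up to `max_subset`) and returns the
   full subset table, not just the argmax; ties break toward the smaller
   subset, then lexicographically (parsimony). Mann-Whitney switches from
   exact enumeration to the tie- and continuity-corrected normal
   approximation at n + m > 20 or in the presence of ties. Z-scores use
   the sample standard deviation (n − 1); zero-variance features
   standardize to 0 with a warning rather than NaN.

3. **cooccurrence** — network and modules. Correlations are computed on
   relative abundances (Spearman is invariant to per-ASV monotone maps
   but not to per-sample normalization; proportions are the convention
   for deposited tables). The edge rule is strict (ρ > 0.75, positive
   only). Module detection maximizes weighted Newman–Girvan modularity:
   networks of at most 9 nodes are solved exactly by enumerating all
   partitions (Bell(9) = 21,147 — cheap, and the greedy heuristic
   provably cannot reach some optima on such graphs: we found 6-node
   instances whose optimum requires a coordinated 3-node rearrangement
   that no single- or pair-move path with positive gain can reach);
   larger networks use igraph's multilevel Louvain with 20 seeded
   vertex-permuted restarts, each followed by a hill-climb refinement
   over single-node and adjacent-pair moves with incremental modularity
   deltas. Communities of one node are dropped from the partition and
   counted, since a lone ASV carries no co-occurrence information.

4. **niche_inference** — random-forest preference models. The response is
   the module's 0/1 presence ("any member ASV has reads"), fitted with a
   *regression* forest: presence is binary, but the acceptance rules are
   expressed in percent variance explained and MSE, and a regression
   forest on a 0/1 response (a Brier-score view) is the only reading
   consistent with both. The forest is an explicit bagging loop over
   sklearn regression trees because the importance needed — per-tree
   out-of-bag permutation importance, %IncMSE = 100 · mean over trees of
   (MSE_perm − MSE)/MSE — has R-randomForest semantics that sklearn's
   ensemble API does not expose. Importance p-values refit the whole
   forest under B response permutations (default B = 100; the acceptance
   script and recovery tests use B = 50, which bounds attainable p at
   1/51 ≈ 0.02 < 0.05) and count exceedances with the +1 correction.
   Models are accepted only when variance explained > 10 % (strict) and
   the top variable has %IncMSE ≥ 5 at p < 0.05. The three-way
   high/low/mid classification of accepted modules is operationalized
   as: ρₑ = Spearman(mean member Z, elevation); E* = mean elevation of
   the highest-mean bin among 10 equal-count elevation bins; high iff
   ρₑ > 0.3 and E* above the 800 m split, low iff ρₑ < −0.3 and E* below
   it, mid otherwise. The constants (0.3, 10 bins, 800 m) sit in
   configuration; they are the simplest rule that separates monotone
   from unimodal gradient responses.

5. **functional_profiles / trace_gas** — differential gene analysis. KO
   rarefaction draws in sorted-KO order so results are invariant to
   column order. Single-copy normalization divides each sample by the
   median abundance of its universal single-copy genes — a deliberate
   simplification of learned per-gene correction schemes that preserves
   the quantity downstream steps need (abundance per genome equivalent)
   and is exactly scale-invariant per sample. Fold changes are oriented
   fc = log₂((μ_low + ε)/(μ_high + ε)) so that fc < −1 literally means
   "at least twice as abundant at high elevation"; ε is half the smallest
   positive table value (scale-aware, keeps zero means finite), and all
   classification boundaries are strict. Hit filtering reads its
   thresholds inclusively (≥ 80 % coverage, ≤ 10⁻¹⁰ E-value, ≥ 50/60 %
   identity): "threshold" wording in common workflows means the boundary
   value passes. One best hit per read (bitscore, then E-value, then
   input order) before counting, since reads-per-gene counting implies a
   single assignment per read.

## Configuration

All thresholds live in `PipelineConfig` (defaults in parentheses, all
strict-positive): ASV minimum total reads (10), sample minimum reads
(1,000), prevalence minimum (10 samples), richness rarefaction depth
(2,000 reads), network edge threshold ρ (0.75), forest size (100 trees),
mtry (3), importance permutations (100), variance-explained minimum
(10 %), %IncMSE minimum (5), importance α (0.05), elevation split (800 m
ASL; a sample exactly at the split goes to "high" with a warning),
log₂FC cutoff (1), pathway minimum genes (5), hit coverage minimum
(80 %), [NiFe]-Hyd / other identity minima (50 % / 60 %), E-value maximum
(10⁻¹⁰), KO rarefaction depth (5,203,694 annotated reads). Metadata
concentrations are log₁₀(c + δ) transformed before analysis with δ = half
the variable's smallest positive value; elevation is never transformed;
missing values stay missing (the BIOENV caller restricts to complete

cases).

## Synthetic study conditions

The generator emulates a ~100–200-sample survey spanning 100–2,200 m ASL.
Each geochemical variable is linear in elevation plus Gaussian noise,
orthogonalized in-sample so the realized Pearson r matches its target
(default 0.7; NH₃, SiO₂ and chloride 0.2, mirroring the weakly-coupled
variables of such gradients), clipped at zero from a location four SDs
above it. The community is multinomial: member ASV j of module m has
latent abundance scale_j · exp(effect·(g(v) − 1)) · exp(noise) with g a
logistic or Gaussian niche-suitability curve on the standardized driver,
so `effect_size` is the log dynamic range between the niche optimum and
hostile samples; background ASVs are gradient-independent, sparse
(occupancy uniform on 0.05–0.6) and lognormal, with member scales drawn
from the same lognormal so that at effect 0 members are statistically
indistinguishable from background. Depths are lognormal (median 30,000
reads).

Two planted regimes are used. The *module-recovery* regime (default
modules; effect 8, noise 0.2, 60 samples, 500 background ASVs) plants
five modules with mutually distinguishable profiles — up, down, and
mid-peak on elevation plus two driven by the weakly-coupled variables —
because two same-direction responses to the same driver are
rank-identical and will (correctly) merge at ρ > 0.75. The
*niche-attribution* regime plants five elevation-driven modules (two up,
two down, one mid) at effect 12 and noise 0.1: at that amplitude
specialists are effectively absent off-niche, so module presence varies
along the gradient instead of saturating (the "any member present" rule
integrates over ten members, which at effect 8 keeps presence near
0.5–1.0 and starves the forest of signal). KO tables plant a 40-gene
4-fold high-elevation-enriched set, 60 low-elevation-only genes (the
functional-richness contrast), and 10 constant single-copy genes. Hit
tables plant probe records on both sides of — and exactly at — every QC
threshold, plus Poisson survivor counts 5× enriched in high-elevation
samples for the six uptake-hydrogenase genes.

What passing recovery tests shows — and does not. The conditions are
favorable by construction: noise is modest, niche responses are smooth
and non-interacting, counts are multinomial without overdispersion, and
taxa are phylogenetically unstructured. Recovery under these conditions
validates the *correctness of the machinery* (thresholds, orientations,
seeds, acceptance rules), not the power of the method on real tables,
where compositional coupling, spatial autocorrelation and unmeasured
drivers all bite. The null checks (effect 0, driver-free communities,
fold 1) bound the false-positive side under the same idealizations.

## Problem sizes for tests and the acceptance script

Stochastic recovery batches run at 60 samples × 550–800 ASVs with 8–20
seeds per claim (20 for module recovery, 8 signal + 8 null for niche
attribution, 10 for functional recovery, 5 for the trace-gas screen, 10
for Mantel/BIOENV power), with forest permutation count B = 50. These
sizes keep each claim's sampling error well inside its margin (e.g. a
1.0 observed attribution rate over 40 planted modules against a 0.8
gate) at a few CPU-minutes total.

## Known limitations

- The exact-partition branch is O(Bell(n)) and capped at 9 nodes; between
  10 nodes and a few dozen the heuristic is very reliable but carries no
  optimality certificate.
- Permutation p-values from B refits are granular (multiples of
  1/(B+1)); raise `n_importance_perm` for sharper values.
- Single-copy normalization assumes the chosen genes are genuinely
  single-copy and well-measured; it does not learn per-gene corrections.
- BIOENV is exhaustive and therefore exponential in the variable count;
  it is intended for the ten-variable setting (1,023 subsets), not for
  dozens of variables.
- The generator does not simulate sequence-level error, chimeras,
  phylogenetic structure, or negative associations; networks built from
  its output contain positive edges only.
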