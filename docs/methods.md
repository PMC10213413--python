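# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design decisions taken where the
analysis recipe left choices open. Every number quoted here is recomputed
by the test suite, the analysis scripts, or `scripts/acceptance.py`.

## 1. Differential screening

**Test.** All layers use a two-sided Wilcoxon rank-sum test per feature.
For combined sample sizes n₁+n₂ ≤ 14 without ties, the exact null of the
rank sum is built by the subset-sum dynamic programme (equivalent to full
enumeration of all C(n, n₁) rank assignments) and the two-sided p doubles
the smaller tail, capped at 1. Ties in exact mode switch to mid-ranks with
10 000 seeded permutations and a |W − E W| two-sided criterion (the exact
tied-null is input-specific). Larger samples use the normal approximation
with tie and continuity corrections.

**Multiplicity.** Benjamini–Hochberg step-up per feature table at one
level — nasal genera are one family, lung genes another, the metabolome a
third — mirroring how per-level figures annotate significance. BH is
hand-implemented (it is a core primitive here) and cross-checked against
`statsmodels.multipletests` in the tests.

**Gates.** Microbiome/functional levels: q < 0.05. Genes: q < 0.01 and
|log₂FC| > 1 (the DEG rule of the emulated study). Metabolites: q < 0.05
and VIP > 1. Fold changes use a per-table pseudocount of half the smallest
positive value — a scale-free regulariser for zero-containing data.

**The p-value floor.** With 6 + 6 subjects the smallest achievable exact
two-sided p is 2/C(12,6) = 2/924 ≈ 0.00216. Step-up BH over m features
therefore rejects nothing until at least ⌈0.00216·m/α⌉ features sit at the
floor: ≥ 23 of 515 metabolites at α = 0.05, ≥ 65 of 300 genes at α = 0.01.
This is a structural property of rank tests at this design size, not an
implementation artefact; it is why the metabolite screen recovers almost
nothing at a 1.5-SD shift (the floor is reached by only ~13 % of shifted
features) while the gene screen (log₂FC = 2 on counts with dispersion 0.1,
~94 % complete separations, ~100 planted) passes its gate comfortably.
The screening-recovery benchmark reports the honest pooled consequence:
mean sensitivity ≈ 0.65 over genes+metabolites, empirical FDR ≈ 0.

**Diversity.** Shannon entropy in nats over normalised nonzero
proportions. ACE with rare cutoff 10: ACE = S_abund + S_rare/C_ace +
(F₁/C_ace)·γ², C_ace = 1 − F₁/N_rare, γ² the rare-class CV estimate
floored at 0; if every rare individual is a singleton (C_ace = 0) the
bias-corrected Chao1 is returned and flagged.

**qPCR.** 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_treated −
(Ct_target − Ct_ref)_control.

## 2. PLS-DA and VIP

A plain NIPALS PLS1: columns autoscaled (constant columns get zero
weight), class response coded −1/+1 and centred (making explained sums of
squares symmetric in the labels), sequential components with X- and
y-deflation, default 2 components capped at min(n−1, p). VIP_j =
√(p·Σ_a SSY_a w²_aj / Σ_a SSY_a), which satisfies Σ VIP² = p identically.

The orthogonal filter of O-PLS is deliberately omitted: orthogonal
variation removal rotates the components but leaves the VIP > 1 screening
role intact, and the added machinery would not change which features pass
a dual VIP+FDR gate in any qualitative way. VIP values from an O-PLS fit
would differ numerically; no equivalence with any specific fitted model is
claimed.

## 3. Correlation networks

Spearman ρ = Pearson correlation of mid-rank vectors; pairs with zero rank
variance are skipped. Significance by two-sided permutation: exhaustive
enumeration of all n! orderings when n ≤ 7 (exact p = tail fraction,
including the identity), otherwise seeded Monte-Carlo with
p = (1 + exceedances)/(n_perm + 1) (n_perm = 999). BH runs over all pairs
tested in one network build — a single multiplicity family — and an edge
is kept iff q < 0.05 **and** |ρ| ≥ the gate.

Gate defaults: |ρ| ≥ 0.8 for 6-subject (single-group) networks, where only
near-perfect monotone relations are distinguishable from noise; 12-subject
(both-group) analyses use |ρ| ≥ 0.6, at which the permutation-BH machinery
is the binding constraint. Networks default to the high-exposure group
only, following the emulated design (biomarker interplay under challenge);
a group filter widens to both groups.

Graphs are treated as **unweighted** downstream: edge betweenness, the
Girvan–Newman procedure and maximal-clique enumeration are defined on
topology; ρ survives only as an edge attribute (it breaks core-community
size ties, below).

## 4. Graph algorithms

* **Edge betweenness**: Brandes accumulation over BFS DAGs; per unordered
  pair one unit of flow split fractionally across equal-length shortest
  paths.
* **Girvan–Newman**: iteratively remove a maximum-betweenness edge (ties:
  lexicographically smallest edge), re-scoring only the component that
  contained the removed edge; record the component partition after every
  split; return the partition maximising modularity
  Q = Σ_c [l_c/m − (d_c/2m)²] over the trace (earliest/coarsest wins Q
  ties). The input's own components are the coarsest candidate. An
  edgeless graph yields singletons with Q = 0 by convention.
* **Maximal cliques**: Bron–Kerbosch with pivoting; isolated nodes give
  singleton cliques; output canonically sorted.
* **MCC**: Σ(|C|−1)! over maximal cliques containing the node; isolated
  nodes score (1−1)! = 1 so every biomarker stays rankable.

All operations are deterministic including output ordering.

## 5. Two-stage integration

Per-layer network → **core community** = largest community of the best-Q
partition; size ties go to the community with the highest mean |ρ| over
internal edges, remaining ties to the lexicographically smallest member
set. Core features of all layers are pooled and **correlations are
recomputed** over every within- and cross-layer pair (cross-layer edges
cannot exist otherwise). Girvan–Newman then partitions the integrated
network and MCC ranks its nodes; **key features** are the nodes at or
above the 0.90 MCC quantile (boundary ties all included; a top-k rule is
available). Degenerate runs (fewer than two layers contributing cores)
carry the features forward as an edgeless network rather than failing.

Provenance: the run report records version, seed, and configuration;
wall-clock time is deliberately kept out of all artifacts so that
identical (inputs, config, seed) reruns are byte-identical.

## 6. Synthetic-data generator

The generator emulates the study design: 6 high + 6 low subjects (3 male /
3 female each); per layer one table over the same animals.

* **Microbiome** (per site): 60 genus-level taxa cycling through 8 phylum
  groups whose base weights put ≥ 95 % of mass on the top five; log-normal
  within-phylum spread (SD 0.6 log units); multinomial sequencing at depth
  50 000. Planted taxa (12 per site, mirroring the ~dozen differential
  OTUs the emulated study reports) are *rare* members (~0.1 % base mass)
  of the dominant phyla multiplied by 2^3.5 in the high group — rare so
  that compositional closure does not drag unplanted taxa into apparent
  differences; a strong fold change is realistic for opportunist blooms.
* **Transcriptomes**: negative-binomial counts, dispersion 0.1, log-normal
  base means (median 100); 100 planted genes per tissue (the study reports
  100 and 89 DEGs) at log₂FC 2.
* **Metabolome**: 515 log-normal intensities; 70 planted metabolites (the
  study reports 70) shifted by 1.5 pooled SD on the log scale (monotone in
  the raw intensities, so rank tests are unaffected).
* **Exposure factor**: z ~ N(2·1{high}, 1) contributes weak correlated
  noise (loading 0.2 SD) to planted features. The configured mean effect
  is applied deterministically rather than routed through z: full
  mediation would inflate within-group variance and silently change the
  effective effect sizes.
* **Cross-omic blocks**: 3 latent factors over subjects, orthonormalised
  in-sample (zero mean, unit variance, zero mutual correlation across the
  12-subject panel). Orthonormalisation is an identifiability choice: at
  n = 12 two independent factor draws can easily correlate at 0.5+, which
  would randomly merge planted blocks and make recovery results reflect
  factor-draw luck rather than algorithm behaviour. Each block loads on 2
  features per layer (within planted features) as
  feature = λ·f_b + √(1−λ²)·ε with λ = 0.95 on the standardised log
  scale; for NB genes the factor coefficient is calibrated against the
  NB noise floor (CV² = 1/μ + 0.1) so realised inter-gene correlation
  still approaches λ². One **hub** per block is an extra member (placed in
  layers 1–3 round-robin) loading λ on its own factor and √(1−λ²) on the
  neighbouring block's factor, with no idiosyncratic noise.
* **Randomness**: one root seed; per-layer child streams via SeedSequence
  spawning, so layers are individually reproducible.

What the generator does *not* emulate: phylogenetic correlation among
taxa, batch/run effects, metabolomics missingness, library-size variation,
sex effects. Passing recovery tests therefore show that the *pipeline*
recovers the structures it assumes, not that real data contain them.

## 7. Recovery benchmarks and their operating points

* **Screening** (20 seeds): sensitivity and empirical FDR pooled over the
  planted gene and metabolite features at the defaults above. Genes are
  recovered at ~0.9; metabolites at ~0 because of the p-floor arithmetic
  of §1, so the pooled sensitivity sits near 0.65. This is reported as
  measured; the operating point (n = 6+6, 1.5 SD, m = 515) is the study's,
  and no parameter is moved to flatter the result.
* **Block/hub recovery** (25 seeds): the network stages are measured with
  the true block features supplied as cores, over all 12 subjects with the
  12-subject gate, and with group-mean shifts disabled in the fixture.
  Shifts are the screening stage's concern; over pooled groups a strong
  shift correlates *every* differential-feature pair through the group
  separation itself (for the taxa effect, population ρ ≈ 0.8), which would
  confound latent-block recovery. Mean ARI against the planted block
  labels is ≈ 0.99, with ARI ≥ 0.8 in 100 % of seeds.
* **Hubs**: hubs land in the top MCC decile about 3× more often than
  chance (≈ 39 % of hub observations vs a 12 % base rate), but the event
  "every hub in the global top decile" is rare (~4 % of seeds). The cause
  is structural: per-edge retention within a block is ~0.9 (the BH gate
  binds at n = 12), and MCC's factorial scale means whichever block loses
  fewest edges in a draw dominates the global top decile by orders of
  magnitude — nodes of a near-complete 11-clique score ~10! while a block
  missing a few more edges scores factorially less. Cross-block MCC
  comparison under sampling noise is therefore winner-take-all, and no
  parameterisation consistent with the fixed loading and n changes this.

## 8. Known limitations

* Exact rank tests at n = 6+6 cannot support FDR control over hundreds of
  features (§1); studies of this size that report many discoveries are
  implicitly using parametric or model-based tests.
* Girvan–Newman with max-Q selection is O(E²·V) at worst; networks beyond
  a few hundred edges become slow. The component-wise rescoring keeps the
  shipped analyses in seconds.
* The MCC quantile rule inherits the factorial winner-take-all behaviour
  across communities of unequal cleanliness (§7); rankings *within* a
  community are meaningful, global ones favour the densest community.
* PLS-DA VIP is reported from a fixed 2-component fit; no cross-validated
  component selection or permutation validation of the fit is performed.
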