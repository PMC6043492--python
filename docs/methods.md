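# Methods

## Network model and distances

The interactome is an undirected simple graph over opaque gene-identifier
strings. Self-loops and duplicate edges are dropped at load time with
counts reported — the standard convention for protein-interaction edge
lists. By default every proximity computation runs on the largest connected
component (genes outside it are dropped with a report; a flag disables
this): restricting to one component keeps every shortest-path length
finite, and disconnected interactome fragments are tiny in practice.
When two components tie for largest, the one containing the
lexicographically smallest node id wins, so the choice is deterministic.

All distances are unweighted hop counts. Four set-to-set measures are
implemented; *S* is the disease module, *T* the target set, `d(s,t)` the
shortest-path length:

- **closest** (the primary statistic): `mean_t min_s d(s,t)`.
- **shortest**: `mean_t mean_s d(s,t)`.
- **kernel**: `mean_t [ -ln( mean_s exp(-(d(s,t)+1)) ) ]`.
- **centre**: `mean_t d(t, centre(S))`, where `centre(S)` minimises the
  total distance to the other members of *S*; tied centres are averaged.

Only the closest measure is defined explicitly in the source analysis; the
other three are named there by reference to the proximity toolbox
tradition, and the forms above follow those toolbox definitions. They are
comparators, not the primary statistic.

The inner loops use a deque-based multi-source breadth-first search on a
plain adjacency dictionary rather than generic graph-library calls: a
screen evaluates tens of thousands of BFS passes (one per permutation
replicate per pair), and the contract is exactness, not method — the test
suite asserts equality with an exhaustive all-pairs oracle on hundreds of
random graphs.

## Degree-matched permutation null

Significance is assessed against the expected distance between two random
protein groups of the same size and degree profile as *S* and *T*. Nodes
are grouped by exact degree and adjacent groups are merged in ascending
order until every bin holds at least `min_bin_size` nodes (default 100,
mirroring common toolbox practice; a trailing undersized bin merges into
its lower neighbor). Each template node is replaced by a uniform draw from
its bin, without replacement within a bin, so the sample has exactly
`|template|` distinct members. The sampled *S′* and *T′* may overlap each
other — nothing in an unconstrained random pick forbids it.

Per replicate, **both** groups are re-drawn by default ("two randomly
selected groups"); an option fixes *S* and re-draws only *T* (a common
variant). The default replicate count is 1000. The null's σ is the
population (divide-by-N) standard deviation, fixed for reproducibility.
z = (d − μ)/σ; when σ < 1e−12 the null is degenerate: z is defined as 0
when the observed distance equals μ and an error otherwise.

Randomness: each screen takes one integer seed; every drug × disease pair
derives its own 31-bit seed by hashing (seed, drug, disease), and each
replicate draws from its own spawned substream. Results are therefore
bit-identical across reruns and independent of evaluation order.

### Calibration and what it means

If a target set is itself drawn by the degree-matched sampler, its z
against the *fixed-S* null is a draw from that null, so the z distribution
must be centred at 0 with spread near 1 (slightly above 1, since μ and σ
are estimated from finitely many replicates). The calibration check in the
acceptance suite therefore uses the fixed-S (targets-only) randomization.
Under the default both-group null the z of a random target set also
carries a constant offset measuring how atypical the real module's
placement is relative to its own degree-matched resamples — for a planted,
deliberately clustered module that offset is negative and is exactly the
signal the screen exploits, not a calibration defect.

## Screening rules

- **Target curation**: a drug-target interaction requires a reported Ki,
  Kd, IC50 or EC50 ≤ 10 µM (boundary kept). Input affinities are converted
  to µM using an explicit units column (nM and mM supported; unknown units
  are an error). Drugs left with no passing targets are dropped with a
  report.
- **Module filter**: a disease module enters the screen only if ≥ 10 of
  its genes are in the interactome; out-of-network genes do not count.
- **High confidence**: z strictly below −4.0 (the boundary value is
  excluded); idempotent by construction.
- **ROC evaluation**: score = −z; positives are a supplied set of known
  drug–disease pairs and negatives are all other screened pairs (the
  negative set is configurable — no canonical gold standard defines it).
  The AUC is the Mann–Whitney statistic with ties counted 0.5, computed
  via scikit-learn and cross-checked against an O(n²) pair-counting oracle
  in tests.
- Drugs are classed cardiovascular / non-cardiovascular by a first-level
  ATC code beginning with "C"; drugs without ATC annotation are classed
  unknown and excluded from class-specific counts.
- Output rows are ordered by (disease, ascending z) for stable diffs.

## Tissue-specific subnetworks

A gene is *tissue-expressed* when RPKM ≥ 1 in strictly more than 80% of
that tissue's samples — the per-sample comparison is ≥, the across-sample
fraction is >, so 8 of 10 samples fails and 9 of 10 passes. "Samples"
means the samples of that tissue only (the alternative reading — all
samples — is not adopted). The tissue expression significance is
z_E(i,t) = (E(i,t) − ⟨E(i)⟩)/δ_E(i), with E(i,t) the arithmetic mean RPKM
over the tissue's samples and ⟨E(i)⟩, δ_E(i) the mean and **sample (n−1)**
standard deviation over the tissue-level means. Both granularity choices
(per-tissue means rather than per-sample values; sample rather than
population sd) are conventions fixed here and used consistently by the
tests; with tissue means [0, 10, 20] they give z = (−1, 0, 1).
Constant-expression genes get z = 0 with a flag rather than NaN. Per-gene
z rows sum to zero across tissues by construction.

The tissue subnetwork is the interactome induced on the expressed genes.
Mechanism paths enumerate **all** shortest paths from each drug target to
each disease gene inside that subnetwork, kept when the hop length is at
most `max_len`; genes absent from the subnetwork are skipped with a
report, and path nodes can be annotated with their tissue z_E for display
sizing.

## Incidence rates and two-database pooling

Incidence rate = events / person-years × 100 (the "per" scale is a
parameter). The 95% CI is the exact Poisson (Garwood / chi-square) bound
on the event count, scaled like the rate: the published intervals this
module reproduces are consistent with exact-Poisson bounds on spot checks,
and the method is fixed here since no method is named alongside the
printed values. Display rounding is 2 decimals, half-up; internal values
keep full precision.

DerSimonian–Laird pooling: Q under fixed-effect weights 1/σ̂²ᵢ;
τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)); final weights ∝ 1/(σ̂²ᵢ + τ²),
normalized. The overlap correction for two databases is

    σ̂²_corrected = Σ wᵢ² σ̂²ᵢ + w₁w₂ · (n₁σ̂²₁ + n₂σ̂²₂)/(n₁ + n₂) · p_overlap

with p_overlap = 0.2 by default (an assumed 20% shared membership between
the two claims databases). Two conventions are fixed where the printed
formula is silent: the wᵢ are the **normalized** random-effects weights
(the Σwᵢ²σ̂²ᵢ form presumes Σwᵢ = 1), and the σ̂²ᵢ inside the correction
are the **raw** study variances, not σ̂²ᵢ + τ². At p_overlap = 0 the
corrected variance reduces exactly to the plain pooled variance, and it is
non-decreasing in p_overlap. HR = exp(pooled), 95% CI =
exp(pooled ± 1.96·√σ̂²_corrected).

## Synthetic data

The generators are first-class, tested code and define the package's test
conditions:

- **Interactome**: preferential attachment (default 500 nodes, m = 2),
  chosen because degree bins are only meaningful on heterogeneous-degree
  graphs; always connected; nodes relabeled to string ids.
- **Disease module**: breadth-first growth from a random seed node with
  random frontier order (default 25 genes) — connected by construction,
  emulating the clustering of disease proteins.
- **Drugs**: *proximal* drugs sample targets (default 3) from the module
  and its first neighbors, so their closest distance is ≤ 1; *random*
  drugs degree-match a uniformly drawn template, so the two classes differ
  in placement, not connectivity.
- **Expression**: log-normal RPKM (per-gene log-mean ~ N(0.5, 1), sample
  noise σ = 0.5 on the log scale; roughly half of genes pass the
  expressed-gene rule), with an additive mean shift for designated effect
  genes in one tissue.
- **Study pairs**: two estimates drawn Normal(true log HR, σ̂²ᵢ) with
  default variances (0.04, 0.06) and sizes (50 000, 15 000), desk-scale
  stand-ins for paired claims-database cohorts.

Every generator is a pure function of its parameters and seed, and writes
the exact formats the loaders read.

What the synthetic data does **not** emulate: the real interactome's size
(16 677 nodes / 243 603 edges — generation is desk-scale by default), its
community structure and degree-correlation details, literature bias in
disease-gene curation, correlated expression between related tissues, and
confounding in patient data (study estimates are drawn unbiased around the
true effect). Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted signal under idealised conditions,
not performance on real curated inputs.

## Problem sizes

The self-contained checks run at desk scale by design: oracle equivalence
on 200 random graphs of ≤ 50 nodes; null calibration with 200 draws at 100
replicates on a 500-node graph; planted-signal recovery with 50 + 50 drugs
at 1000 replicates; CI coverage over 1000 simulated study pairs. The two
checks that need the published interactome, curated disease genes, drug
targets and the deposited screen table run only when those files are
placed under `data/external/` (paths and expected columns are printed by
the failing tests); they are deterministic parses plus four 1000-replicate
proximity computations.

## Known limitations

- Distances are unweighted and undirected; no edge confidence weighting.
- The null preserves degree via binning, not exact degree sequences;
  very coarse bins on small graphs flatten the degree matching
  (min_bin_size should be reduced on graphs much smaller than ~10× the
  bin size).
- The overlap-corrected variance is specific to two databases, as printed.
- No identifier mapping: gene ids are opaque strings and must already be
  consistent across the interactome, gene sets and target tables.
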