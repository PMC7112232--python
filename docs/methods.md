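# Methods

This note records the modelling assumptions behind ssikit, the defaults
that matter, and the places where the design was genuinely open.

## The classification model

The classifier is an ensemble of *filters*: conjunctions of 4–5 closed
numeric ranges on distinct molecular descriptors. The family is deliberately
simple — axis-aligned boxes — because its members are interpretable (each
filter reads as "MW between 210 and 340 AND logP between 1.1 and 2.7 AND
…") and because conjunctions of per-descriptor ranges suit data where
actives occupy compact descriptor sub-regions while inactives are diffuse.
The model assumes exactly that geometry; actives forming several disjoint
clusters per descriptor, or curved class boundaries, are represented only
as well as a union of up to 1000 boxes can manage.

Filter quality is the Matthews correlation coefficient (MCC) of the
pass/fail split against the active/inactive labels. MCC is used because
learning sets here are extremely imbalanced (defaults 30:6000 ≈ 1:200) and
accuracy-like scores saturate. Any zero factor in the MCC denominator is
treated as MCC = 0 (the filter carries no information about one margin).

### Range discretization and the single-range pool

Per training fold, each descriptor's observed min–max span is divided into
`n_divisions = 100` equal divisions; every pair of distinct grid boundaries
bounds a candidate closed sub-range, giving n(n−1)/2 = 4950 candidates.
Values outside a fold's grid at scoring time simply fail the range — the
grid is part of the model.

The pool holds **one** range per descriptor: the best single-range
classifier for that descriptor. Selecting that range by the literal argmax
of the MCC scan is statistically treacherous: the scan maximum over ~5000
overlapping windows is a scan statistic, and with only ~24 actives per
training fold its argmax is typically a chance-narrow window well inside
the true active region. Models built from such ranges fail a large
fraction of genuinely active held-out molecules. ssikit therefore treats
all windows whose MCC lies within a sampling-noise band of the maximum —
relative slack `range_slack_scale / √n_actives × (1 − best_mcc)`, default
scale 0.75 — as indistinguishable from the maximum, and uses the **union
span** of those windows as the consensus range. The band shrinks with more
actives and vanishes as the best window approaches perfection, so at large
n (or clean separation) the selector converges to the argmax; setting
`range_slack_scale = 0` restores the literal argmax with
narrowest-window/lowest-bound tie-breaking. Undershooting the active
region is far more damaging than overshooting it (a too-narrow range
silently vetoes true actives in every filter that uses it; a too-wide one
merely admits a few more inactives that the conjunction usually removes),
which is why the consensus errs wide.

### Stochastic elimination

While the number of possible filters (Σ over sizes of C(pool, size)) is at
or above `exhaustive_threshold = 10⁶`, each iteration samples
`sample_size = 50 000` random filters uniformly (sizes drawn from {4, 5}),
scores them, and examines the worst and best `decile_fraction = 10%` of
the MCC distribution. A range is eliminated iff it appears in the worst
decile more than `α = 2` times its expected count *and* in the best decile
less than `β = 0.5` times expected, where expected = its total sample
appearances × decile fraction. The α/β defaults quantify "much more /
much less than expected"; both are configurable. Elimination is skipped
(with a warning) when expected decile appearances are below 5, since the
rule is meaningless without evidence. If an iteration eliminates nothing
while the space is still too large, the single most worst-biased range is
dropped so the loop provably converges; a hard `max_iterations = 50` bound
aborts pathological configurations.

Below the threshold every remaining combination is enumerated exhaustively
(depth-first with shared prefix AND-masks over packed molecule bitsets, so
the ~10⁵–10⁶ evaluations cost seconds). In the exhaustive regime the
search is exact: its top MCC equals brute-force enumeration's, which the
test suite asserts against an independent pandas-based evaluator.

### Ensemble keep rule

The ensemble-selection rule has two branches — filters within 20% of the
top MCC, or the top 1000 filters. ssikit resolves them as: the ensemble is
the top `max_filters = 1000` filters by MCC (never keeping non-positive
MCC, except a lone best filter since an ensemble must be non-empty). When
the within-20% branch would select more, the cap binds; when it would
select fewer — which on low-dimensional problems leaves one or two filters
— the ensemble is filled to the cap. The pure within-fraction branch
(capped) remains available via `keep_mode="fraction"` for fidelity
experiments. The fill matters: MBI is an ensemble
*average*, and with one or two filters it degenerates to a near-binary
score in which molecules failing everything tie, destroying rank-based
evaluation. A graded ensemble also gives partial credit to molecules
matching most but not all of the active profile.

### Cross-validation and merging

`build_model` draws a seeded, stratified 5-fold split (round-robin within
each class; re-drawn up to 10 times if a fold ends up single-class). Each
fold trains on 4/5 and scores its held-out 1/5, so every learning-set
molecule receives exactly one out-of-fold MBI — the number used for all
AUC claims. Fold ensembles are then concatenated; two filters are
near-duplicates iff they use the same descriptor set and every pair of
corresponding ranges overlaps with interval Jaccard ≥ 0.8 (the higher-MCC
filter survives); the merged ensemble is re-sorted and re-capped.

### MBI

Default *proportion* mode uses efficiency `TP/(TP+FP)` and inefficiency
`TN/(TN+FN)`, bounding MBI in [−1, 1]; the candidate-tier thresholds
(0.85 / 0.2 / −0.97) presuppose that scale. A literal *ratio* mode
(`TP/FP`, `TN/FN`, add-one smoothing on zero denominators) is available
via `mbi_mode="ratio"` for fidelity experiments; it is unbounded and not
used by default. Absolute MBI values depend on ensemble composition (an
ensemble rich in five-range filters passes any given molecule less often,
shifting all scores down); ranks are the stable quantity, and cutoff
tables should be read per-model.

## Curation rules

Descriptor de-correlation removes, among pairs with r² > 0.81, the
descriptor with the larger total r² against all others, iterating until
clean (constant columns go first; ties break lexicographically). Diversity
pruning does the analogous thing on Tanimoto similarity at TC ≥ 0.7,
removing the member with the larger similarity sum (ties remove the
lexicographically later id). Both are verified post hoc in tests by
exhaustive pairwise checks.

The descriptor set is an open, documented set of 26 RDKit 2D descriptors
always containing the Lipinski four (`MolWt`, `LogP`, `HBD`, `HBA`).
Counting convention: donors = N–H plus O–H counts, acceptors = N plus O
counts. Descriptor names are recorded in model metadata, and scoring
refuses data missing any referenced descriptor. NaN descriptors are fatal
in model building and warn-and-exclude in screening.

Fingerprints default to RDKit path-based, 1024 bits, max path 7 — the
closest open analogue of linear-fragment FP2 fingerprints; Morgan/circular
is available via `FingerprintConfig(kind="circular")`. Exact bit-for-bit
FP2 reproduction is a non-goal.

## Fragment cleavage

The cleavage site is an sp2 carbonyl carbon bonded to the nitrogen of a
saturated 5- or 6-membered N-ring (SMARTS-configurable; defaults match
acyl-pyrrolidine and acyl-piperidine). The amide C–N bond is broken;
everything on the ring side, including ring substituents, is discarded.
The open valence is capped with hydroxyl by default — the fragment becomes
a carboxylic acid, preserving the H-bonding character of the amide it
replaces — with hydrogen capping (aldehyde) as the alternative. A molecule
with several sites yields one fragment per site; a retained portion still
carrying a site is cleaved recursively so no returned fragment matches any
ring pattern. Cleavage never produces radicals, and fragments deduplicate
by canonical SMILES with full parent provenance.

## Screening funnel

All interval checks are closed (boundary values pass). The applicability
domain is mean ± 2σ (sample σ, ddof = 1) per Lipinski descriptor of the
active set; zero-variance descriptors become flagged equality constraints.
The solubility gate requires ≥ 2 estimator predictions per molecule, mean
cLogS > −3.5 and sample σ < 1.5; estimators are pluggable callables and the
two built-ins (an ESOL-type linear model and a one-descriptor logP rule)
are stand-ins a practitioner should replace with their preferred
predictors. Candidate tiers: top (MBI > 0.85), mid (0.2 < MBI ≤ 0.85), and
a "similar-but-low-scored" tier (MBI < −0.97 *and* a similarity hit) that
exists to test whether structural similarity alone suffices — its members
are expected failures.

## Kinetics

Michaelis–Menten fits use bounded nonlinear least squares (`curve_fit`,
tolerances 1e-12) with Vmax₀ = max rate and Km₀ = S at half-max; ≥ 4
distinct substrate concentrations are required. Inhibition typing treats a
fold change within 15% of 1.0 as "unchanged" (the qualitative judgment
enzymologists apply by eye, made explicit; configurable, and recorded
inside every call):
Km↑/Vmax= → competitive, Km=/Vmax↓ → noncompetitive, both↓ →
uncompetitive, Km↑/Vmax↓ → mixed, both unchanged → none. The remaining
sign combinations (any Vmax increase, or Km decrease alone) are
inconsistent with simple reversible inhibition and classify as "none".
Dixon analysis regresses 1/v on [I] per substrate concentration (zero
rates dropped with a logged count), calls lines parallel below 5% relative
slope difference (→ uncompetitive), and otherwise classifies by the
intersection of the extreme-substrate lines: above the I-axis at I < 0 →
competitive, on it → noncompetitive. IC50 uses a four-parameter logistic
with auto-checked direction; "no transition in range" is a refusal, not a
fit. Selectivity ratios are computed from the fitted Km values and rounded
only at reporting time (2 decimals).

## Synthetic data

The descriptor generator plants a compact active region: four signal
descriptors with active sub-ranges of width 0.2 on [0, 1], 26 noise
descriptors, 30 actives vs 6000 inactives (the ~1:200 imbalance of
realistic screening learning sets). A 5% *leak* makes an active an
off-mechanism outlier, drawn uniform on every signal descriptor — leaked
actives are indistinguishable from inactives by construction and bound the
achievable held-out AUC near 0.975. Values live on [0, 1] without loss of
generality (the range grid is scale-free). What the generator does *not*
emulate: correlated descriptors, non-uniform inactive distributions,
multi-cluster actives, and descriptor noise — so passing recovery tests
demonstrates the search and scoring machinery, not performance on real
chemistry. The SMILES fixtures enumerate acyl-pyrrolidine/piperidine
variants (all cleavable by the default rule) and linker-combinatorial
decoys (none cleavable). The rate-law generator uses the closed-form
apparent-parameter laws (competitive Km′ = Km(1+I/Ki); noncompetitive
Vmax′ = Vmax/(1+I/Ki); uncompetitive both) with multiplicative Gaussian
noise — constant CV, the usual heteroscedasticity assumption for
initial-rate assays — clipped at zero.

All generators are pure functions of (spec, seed), and identical
(data, config, seed) triples yield byte-identical model JSON and score
CSVs; the test suite asserts this at the file level.

## Problem sizes and runtime

Defaults were chosen so a full synthetic study runs on a laptop: one
5-fold model build on the default 30:6000 learning set takes ~1 s
(bitset-packed exhaustive search), the 10-seed recovery study ~10 s, and
the complete test suite under a minute. The stochastic-elimination path is
exercised at 60 descriptors (≈ 6 × 10⁶ combinations) with a reduced
per-iteration sample in tests.

## Known limitations

- One range per descriptor per fold: bimodal active regions on a single
  descriptor are covered only via the union span, which then admits the
  inter-cluster gap.
- MBI calibration is ensemble-dependent; fixed tier thresholds transfer
  across models only qualitatively.
- The Dixon type heuristic uses the two extreme substrate concentrations
  and noise-free geometry thresholds; with noisy data the fold-change
  route is the more robust of the two.
- The built-in solubility estimators are coarse; the consensus gate is
  only as good as the estimators plugged into it.
- Tight-binding corrections, global Ki estimation across inhibitor series,
  and 3D/pharmacophore screening are out of scope.
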