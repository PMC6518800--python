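# Methods

## Pipeline

The ranking pipeline runs in five stages, all deterministic for fixed inputs:

1. **Cohort intersection.** The analysis cohort is the set of patients
   present in both the mutation and expression matrices; patients missing
   from either are dropped with a warning. Gene symbols are matched exactly
   (case-sensitive); symbols differing only by case across inputs are
   reported but never folded, since silent symbol munging is a classic
   source of irreproducibility.
2. **Outlier calling.** Expression values are transformed with `log2(x+1)`
   (skippable via `log_transform=False` for pre-normalized matrices) and
   standardized per gene across patients with the sample (n−1) standard
   deviation. A gene is outlying in a patient iff its z is strictly
   > `z_threshold` or < −`z_threshold` (default 2.0). Zero-variance genes
   get all-zero z and can never be outlying. The upstream normalization of
   the expression source is intentionally isolated behind this single
   operation so it can be swapped.
3. **Variation frequencies.** `M(g)` = mutated patients / N for every gene
   mutated at least once. Outlying genes reuse `M(g)` when they are ever
   mutated, else get the floor `1/N`. In subsample analyses the frequencies
   are recomputed on the subsample, with N the subsample size.
4. **Per-patient bipartite walk.** Each patient's mutated and outlying genes
   present in the influence graph form the two sides; edges come from the
   graph; zero-degree nodes are dropped from their side. Edge (i, j) is
   weighted by the maximum compartment significance `SC = C_X/C_M` over the
   genes' shared compartments, falling back to the minimum significance
   `C_N/C_M` when they share none — including when either gene has no
   localization annotation at all. Exactly three damped passes are run (see
   README); there is no iteration to convergence. `W` is deliberately left
   unnormalized: a mutated gene adjacent to many reliable outlying genes
   should accumulate mass, which is the driver signal being modeled.
   A gene both mutated and outlying in the same patient appears on both
   sides with `M(g)` and `O(g)` respectively; it never pairs with itself
   because the influence graph carries no self-loops.
5. **Aggregation.** Final score = sum of per-patient `Rm` over the patients
   where the gene was retained. Genes never entering any bipartite graph are
   absent from the ranking (equivalently, they would contribute zero).
   Ties break by higher mutation frequency, then lexicographic symbol, so
   rankings are fully reproducible.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.5 | damping: weight of a gene's own frequency vs its weighted neighborhood; α=1 is frequency-only, α=0 network-only |
| `z_threshold` | 2.0 | strict absolute z cutoff for outlier calls |
| `log_transform` | true | apply log2(x+1) before z-scoring (for raw counts) |
| compartment sizes | counted from the localization file | can be overridden with an explicit database-wide size table (`--compartment-sizes`), which is the recommended choice when the localization file covers only the analysis genes |

The shipped `HUMAN_COMPARTMENT_SIZES` table lists the protein counts of the
11 canonical human compartments (Nucleus 13,938 … Endosome 825), giving the
significance regime in which the method was characterized: nuclear/cytosolic
interactions near weight 1, disjointly localized pairs near 0.06.

## Evaluation machinery

Top-K metrics treat the ranked (mutated) genes as predictions against a
user-supplied benchmark list; the recall denominator is the full benchmark
size, with no filtering. fscore at precision = recall = 0 is defined as 0.
The PR-AUC integrates precision over recall by the trapezoid rule along the
K = 1..K_max sweep (K_max default 200); zero-width recall segments contribute
nothing. The AUC estimator is a pinned convention — different estimators
(step-wise interpolation, average precision) give systematically different
magnitudes, so cross-study AUC comparisons should re-run this estimator.
Bipartite density degree is realized edges over all mutated×outlying pairs.
Robustness draws ⌈fraction·N⌉ patients without replacement, `repeats` times
(default 10), reruns the full pipeline per subsample and averages top-K
precision; it is deterministic given its seed.

## Synthetic cohorts

`generate_cohort` emulates the structure the method exploits: drivers mutate
at 0.15 per patient vs 0.01 for passengers; the background network is
Erdős–Rényi at mean degree 6 with 10 extra edges per driver; localization
assigns each gene 1–3 compartments proportional to the size table, and
driver–neighbor pairs are co-assigned a top-2 compartment with probability
0.8; expression is log-normal (log2-space sd 0.25, gene means uniform on
[3, 10]). An entry (patient, gene) becomes a planted outlier with
probability 0.4 when the gene neighbors a driver mutated in that patient and
0.02 otherwise — one draw per entry, so setting the two rates equal is an
exact null. Planted entries are pushed upward in log-space and re-checked
against the package's own z-scoring, growing the offset until every planted
call strictly clears |z| > 2 ("plant, check, retry"), so planted always
means called.

Two structural consequences are worth knowing:

- **Planted fraction cap.** A standardized column can hold at most
  ~`1/(1+z²)` of its mass beyond z standard deviations; one-sided pushes top
  out at `z = sqrt((1−f)/f)`, so `f < 0.2` is a hard feasibility bound for
  z > 2. The generator caps the planted fraction per gene at 15% of the
  cohort and randomly discards the excess. Hub genes neighboring several
  drivers therefore saturate — a genuine property of cohort z-scoring, not
  an implementation limit.
- **Drivers are conditioned on ≥1 mutation** by redrawing their whole
  mutation column, i.e. they follow the ≥1-truncated distribution — the
  same truncation the ranking implicitly applies to passengers (unmutated
  genes are never ranked), which keeps the no-signal configuration an
  honest null.

All randomness flows from the single config seed through spawned
sub-streams (structure / localization / mutations / expression / driver
choice), so each stage is independently reproducible and same-seed runs are
byte-identical on disk.

### What passing tests on synthetic cohorts do and do not show

The generator plants exactly the signal the method models, so recovery
results certify the implementation (the walk finds the signal it should
find), not real-data performance. Real cohorts add unmodeled features —
mutational signatures, copy-number events, expression programs, annotation
errors in networks and localization databases — and real driver/passenger
frequency distributions overlap far more than the default 0.15/0.01 rates.
Notably, at those default rates mutation frequency alone already separates
drivers perfectly (a frequency-only α = 1 ranking also attains precision 1
at K = 20), so the synthetic recovery experiment cannot demonstrate the
walk's advantage over frequency ranking; the α = 0 limit, the oracle
equivalence tests and the null calibration carry that evidential weight
instead.

## Numerical choices and degenerate inputs

- Sample (ddof = 1) standard deviation throughout; cohorts of < 2 patients
  are rejected.
- The walk is three dense matrix-vector products per patient; scores are
  exact up to float64 round-off, and the test suite checks them against an
  independent pure-Python evaluation at 1e−10.
- Patients whose bipartite graph is empty contribute exactly zero and are
  skipped with a warning; a cohort where *every* patient is empty is an
  error.
- Readers are strict: malformed rows, non-binary mutation cells and
  duplicate patient rows raise immediately rather than being skipped.
- Problem sizes: the default synthetic experiments use 200 patients × 500
  genes with 20 drivers (5 seeds for recovery, 20 for null calibration),
  which characterizes the estimator well while keeping the full suite
  fast on a single CPU.

## Known limitations

- The localization weighting is binary-membership only; graded localization
  confidence scores and per-tissue localization are out of scope.
- Variation frequency is not normalized by gene length, so long genes are
  favored by the frequency term.
- The α-sweep and robustness procedures are demonstrated on synthetic
  cohorts; their absolute AUC/precision values are not comparable across
  AUC estimators or benchmark lists.
- Tumor-vs-normal outlier calling is not implemented; outliers are relative
  to the tumor cohort itself.
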