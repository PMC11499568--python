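# Methods

## Model and procedure

The package implements a cascaded classifier over tri-state immunomarker
data. A case is a map from marker names (32 canonical IHC/ISH markers; EBER
in-situ hybridization is treated as one marker like any other) to one of
{positive, negative, unknown}. Diagnosis proceeds through a decision tree of
five classification tasks aligned with the 4th revised WHO taxonomy: HL vs
NHL at the root; NHL lineage (B / T / NK); B-cell subtyping (9 classes);
T-cell subtyping (4 classes); and DLBCL cell of origin (GCB vs non-GCB).
Leaves are the 16 terminal diagnoses. The tree and task definitions are
data (`data/default_tasks.yaml`), not code, so alternate taxonomies can be
declared without touching the implementation.

Each task declares a *minimum-required* boolean expression over marker
**availability** (a marker "counts" when its status is known, regardless of
sign): `CD30` for the root; `CD3 AND CD20` for lineage;
`CD20 AND CD10 AND CyD1 AND (CD5 OR Bcl-2)` for B subtypes;
`CD3 OR CD8 OR CD30 OR ALK` for T subtypes; `CD10 AND MUM-1` for cell of
origin. Training and evaluation for a task use only cases that satisfy its
expression *and* whose true subtype lies under the task's subtree.

### Encodings

Linear/kernel/network families (LR, SVM, MLP) consume a paired one-hot
encoding: positive → (1, 0), negative → (0, 1), unknown → (0, 0). Unknown
therefore contributes no weight of its own and is absorbed into the
intercept — the only encoding consistent with giving these families exactly
two binary statuses per marker. Tree families (DT, RF, xGBoost) consume one
categorical code per marker (0 = negative, 1 = positive, 2 = unknown), which
lets splits isolate missingness directly.

### Family selection

Six families are fit per task; the family used system-wide maximizes the
summed one-vs-rest AUC over all tasks and all declared validation cohorts
(equivalently the mean — both are stored). Exact ties resolve to the fixed
order LR < SVM < MLP < DT < RF < GBM. Hyperparameters are conventional
defaults, all config-overridable: LR multinomial with L2 penalty, C = 1.0,
max 1000 lbfgs iterations; SVM RBF kernel ranked by decision values (no
Platt scaling — AUC only needs ranks); MLP with one hidden layer of 32 and
no early stopping; DT Gini with unlimited depth; RF 500 trees; xGBoost 300
rounds, depth 4, learning rate 0.1. None of the package's claims depend on
matching any particular cohort's AUC values with these defaults.

### Panel simplification

The package's core algorithm. Per task, with the selected family (LR —
importance is defined on its coefficients; other families are rejected):

1. Fit the full candidate panel; its train-set macro OvR AUC is the
   *reference AUC*.
2. Importance of marker m = max over classes and over m's two one-hot
   features of |coefficient|. Ranking is computed once from the full model
   and never re-ranked between steps; descending order, exact ties keep the
   full-panel order.
3. Markers appearing in any *ancestor task's simplified panel* (not its full
   panel) and in this task's candidate panel form the inherited block,
   ordered by candidate-panel order. The inherited-only model is fit first
   and the search stops immediately if it already retains the threshold
   fraction of the reference AUC.
4. Otherwise the remaining markers are appended one at a time in ranking
   order, refitting after each, stopping at the first panel whose train AUC
   ≥ threshold x reference. The comparison is a plain `>=` at full float
   precision — no tolerance fudge.
5. If the threshold is never met the task returns its full panel, flagged
   unsatisfied, with a warning.

The retention threshold is 0.99 of the reference AUC for four tasks and
0.95 for B-cell subtyping, which is intrinsically harder (several B
subtypes are poorly separable by immunostaining alone). Both thresholds
apply to the *train-set* AUC. Refits reuse the full model's hyperparameters
and derived seed so the panel is the only thing that varies.

Because the search checks the inherited block first and then strictly
extends it, the guarantee is: the returned panel meets the threshold and no
*evaluated* proper prefix does. A prefix inside the inherited block is never
evaluated (inherited markers are taken or left as a block), and train AUC is
not monotone in panel size, so no stronger minimality claim is made.

### Inference and cost accounting

A case routes root-to-leaf: each task's simplified model scores it, argmax
picks the child (ties → first class in declared order). Unknown markers are
allowed everywhere; a case with no known marker in any consulted panel is
predicted from intercepts and flagged low-information.

The cost report mirrors the clinical comparison table: one row per
hierarchy level, covering the leaves that terminate at that level (HL; the
NK leaf; the 8 non-DLBCL B leaves; GCB/non-GCB; the 4 T leaves). The
system's cost at a level is the *cumulative* count of distinct markers on
the root-to-leaf path (union of simplified panels, so reused markers are
counted once); the clinical cost is the mean number of markers actually
measured. Routing for cost purposes follows the **true** subtype — the
table answers "what would this diagnosis have cost" — while predicted
routing drives the classification metrics. The overall row is the
record-weighted mean over all terminal leaves. Savings are reported signed,
as (clinical − required)/clinical x 100, and are computed from means rounded
to two decimals: that is the printed-report convention this table mirrors,
and the percentage is only quotable to that precision anyway. P-values use
the panel-size test below when raw per-case clinical counts are available.

### Statistics

Marker-by-subtype composition is compared with Pearson's chi-square test
(no continuity correction). Required-vs-clinical marker counts use a
two-sided Mann-Whitney U test (normal approximation with tie correction)
unless both samples pass a Shapiro normality screen at alpha 0.05, in which
case Welch's t-test is used. Macro OvR AUC averages only classes present in
the evaluation set (OvR AUC is undefined without positives; skips are
logged); for two-class tasks it is the standard ROC AUC of the
positive-class score with midrank tie handling. "Weighted recall equals
accuracy" holds by construction for single-label problems and is used as a
test invariant.

### The Hans comparator

The classical immunohistochemical cell-of-origin rule ships as a fixed pure
function: CD10 positive → GCB; else Bcl-6 negative → non-GCB; else MUM-1
positive → non-GCB, negative → GCB. An unknown status *consulted by the
active branch* yields "indeterminate" — even when both completions of the
unknown would agree, matching how the rule is applied at the bench.

## Synthetic data generator

The generator exists so every stage is testable without patient data. Per
case: a subtype leaf is drawn from a prevalence map; each marker is
independently positive with a leaf-conditional probability, else negative;
statuses are then masked to unknown with per-marker missingness
(missing-completely-at-random by default, per-leaf missingness available);
a per-case clinically-tested count is drawn separately (Poisson, mean 13.3,
matching the order of magnitude of clinical practice).

The default configuration fixes the study conditions: leaf prevalences
honour the published conditional fractions P(NHL) = 0.8481,
P(B | NHL) = 0.7767, P(DLBCL | B) = 0.4593, with remaining mass spread over
sibling leaves in the proportions of the published primary-stage leaf
counts; positivity profiles encode canonical immunophenotypes (pan-B CD20,
pan-T CD3, CD30/CD15 in HL, CD56/EBERs/cytotoxic markers in NK, CyD1 in
MCL, CD5/CD23 in SLL, TdT in lymphoblastic leaves, CD10 high / MUM-1 low in
GCB and reversed in non-GCB, ALK in ALCL, CXCL-13 in AITL, ...). These are
plausible canon, **not** calibrated to any deposited dataset — the
supplementary marker-by-subtype tables were not available — and default
missingness is 0.2 everywhere.

What passing tests on this generator do and do not show: they verify the
*algorithmic* contracts (selection recovers planted informative markers;
thresholds are honoured; arithmetic and routing are exact; determinism
holds) on data whose conditional-independence structure makes the LR
posterior well-specified. They do not show that the selected panels match
the published ones — informative markers under the generator differ from
the real cohorts — nor how the system behaves under correlated stains or
availability-by-indication missingness, which real IHC ordering induces and
the default generator does not emulate (a per-leaf missingness map is the
hook for studying the latter).

## Numerical choices and edge cases

- Seeds: one pipeline seed; each fit derives `crc32(task_id:family)` mixed
  with it, kept below 2^31. Same seed → byte-identical panels and reports.
- Ties: argmax takes the first class in declared order; importance ties keep
  panel order; family-selection ties take the lower-ordered family.
- Degenerate inputs: an all-constant design matrix, a declared class absent
  from training, empty cohorts, zero contingency margins, and single-class
  AUC are errors, not silent results. Two identical constant samples in the
  panel-size test return p = 1 by convention.
- 0/0 precision or recall is defined as 0.
- Blank cells, "NA" and explicit "unknown" tokens are equivalent on read;
  marker names are normalized case-insensitively with hyphen-variant folding
  ("MUM1", "MUM‐1" → "MUM-1").

## Problem sizes

Defaults were chosen so the whole pipeline is interactive on one CPU: the
shipped examples and tests use training cohorts of 700–5000 cases
(simplification at n = 4000 takes ~2 s; the 100-seed recovery study ~10 s).
The acceptance script trains at n = 4000 and evaluates at n = 2500.

## Known limitations

- The simplification pipeline requires the LR family; coefficient-based
  importance has no canonical analogue for the kernel/tree families, and
  the selection stage chooses LR on data of this structure anyway.
- Greedy forward search with a fixed ranking is not optimal panel search;
  no exhaustive or L0 alternative is provided, and markers are costed by
  count, not price.
- Statuses are strictly tri-state: percent-positivity and staining
  intensity are out of scope, as is free-text report parsing.
- The published cohort-level AUCs cannot be reproduced without the original
  patient-level data; the package reproduces the published panel-reuse and
  cost arithmetic exactly and validates the learning machinery on synthetic
  cohorts instead.
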