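# Methods

This note documents the models behind `comornet`, the defaults they ship
with, and what the synthetic-data generators do and do not emulate.

## Disease and drug characterizations

A disease characterization is a set of signed protein effectors
(gene symbol, sign in {-1, +1} giving the activation direction that
induces the disease, one or more motive labels). Loading normalizes gene
symbols by uppercasing and stripping whitespace; matching is exact string
equality with no alias resolution, because the downstream logic operates at
the symbol level throughout. Composite cells such as `SLC6A2/NET1` are
stored under the first token with the remainder kept as an alias
annotation; multi-motive cells split on `/`. Duplicate rows for one gene
merge by motive union and error on conflicting signs. Effector signs that
are not documented in a source table can be marked `sign_imputed`; the
packaged eating-disorder characterization is such a synthetic stand-in and
says so in its filename and header.

Overlap statistics: the aggregate overlap of a base disease against a
collection of others is the fraction of base effectors present in at least
one other set; the connected variant additionally counts base effectors
adjacent (exactly one edge, direction ignored) to any other set's effector.
Both are reported in percent and are invariant under reordering of the
comparison diseases; the connected value can never be below the aggregate.

## Interactome

Edges are merged from SIF ("A rel B") and 2/3-column TSV inputs with
provenance tags. Undirected edges are stored with sorted endpoints so
duplicates collapse regardless of orientation; directed edges (regulatory
relations such as `activates`/`inhibits`) stay directed and carry a sign.
Path enumeration returns simple paths only, respects direction on directed
edges, traverses undirected edges both ways, and is reported in
lexicographic order; "three-step" mechanisms are read as *at most* three
edges, with an `exact` option for the stricter reading. The
degree-preserving null model applies double-edge swaps on the undirected
projection (signs, directions and provenance are deliberately dropped:
the null is used only for distance statistics, which ignore them).

## Relationship scoring

The proximity statistic is the mean, over drug targets, of the shortest
undirected path length to the nearest disease effector. Targets
disconnected from every effector contribute a capped distance of
(largest-component diameter + 1), so disconnection is penalised but finite.
Significance comes from a permutation null: random target sets of the same
size, sampled without replacement from logarithmic degree bins (width
factor 2) so hub bias is preserved. With `n_null` draws the empirical
p-value is `(1 + #{null <= observed}) / (n_null + 1)`, which cannot be
zero and is uniform under the null — a property the suite tests directly
by scoring null-drawn target sets (the rate of p <= 0.05 must sit in the
binomial 95% interval around 5% over 200 runs).

The p-to-score map is piecewise linear in log10(p) through the anchor
points (0.001, 100), (0.01, 92), (0.05, 77), (0.25, 37), (1.0, 0), clamped
to [0, 100]. These anchors encode the published band semantics: scores of
at least 92 correspond to p < 0.01 ("very high"), 77–92 to p < 0.05
("high"), 37–77 to p < 0.25 ("medium"), below 37 to p >= 0.25 ("low").
Bands are upper-half-open with the top band closed, so exactly one label
applies at each boundary. The scoring stack is a surrogate for a
proprietary trained model: the interface (0–100 score, p bands) is
preserved and calibrated, but no claim is made that the numeric scores of
the original system are reproduced.

## Virtual patients and PBPK

Cohorts use independent truncated normals for age, weight and height and a
Bernoulli sex draw; no covariance structure is published for the reference
trials, so none is imposed. Defaults: adult cohorts (ages 18–65, mean 35,
weight 75 ± 13 kg, 60% male) and pediatric-adolescent cohorts (ages 6 to
<18, mean 11.5, weight 42 ± 14 kg, 67% male, reflecting the male skew of
ADHD trial populations); 100 patients per cohort with an enforced floor of
71 (the statistical-power minimum adopted in the study design this package
models; lowering the floor is possible but flagged as a toy-run option).

The PBPK model is a linear, flow-limited, 14-compartment whole-body layout:
gut lumen, gut wall, liver, kidney, brain, arterial blood, venous blood,
lung, adipose, muscle, skin, heart, spleen and rest-of-body. Absorption
from the gut lumen is first order (`ka`, default 0.8 /h — the
prodrug-to-active-metabolite conversion step is folded into absorption); a
competing first-order luminal loss is calibrated as
`k_gut_loss = ka (1 - F)/F` so the absorbed fraction equals the target
oral bioavailability F = 0.964. Clearance is renal only (default 18 L/h,
referenced to kidney outflow concentration), matching a kidney-dominated
elimination route; with no hepatic extraction the AUC-ratio bioavailability
equals the absorbed fraction, so the calibration is exact by construction
and the oral/intravenous AUC ratio is computed independently as a check.
Tissue partition coefficients describe a basic lipophilic amine (brain Kp
6, liver/kidney 8, lung/adipose 4, lean tissues 3); flows are standard
fractions of a 312 L/h cardiac output and sum to it exactly.

Amounts evolve as x' = Ax with bookkeeping states for eliminated and
unabsorbed drug, so the columns of A sum to zero and mass balance holds to
numerical precision (the tests require < 1e-6 relative error; in practice
it is ~1e-14). Curves are propagated with one matrix exponential per fixed
step (default 0.1 h over 48 h) and cross-checked against an independent
stiff ODE solve at tight tolerance. AUCs are closed-form (-A_core^{-1} x0),
i.e. integrated to complete elimination. Per-patient scaling is allometric:
volumes proportional to weight, flows and clearance to weight^0.75.
Kinetics are strictly linear; saturable transport and fitting to published
plasma data are out of scope.

## Signed-propagation network models

The model class is a weight vector w in [-1,1]^E over interactome edges
(edges annotated with a known sign are constrained to that half-interval;
undirected edges act symmetrically). Activity propagates as
`a(t+1) = tanh(s + W^T a(t))`, `a(0) = s`, with stimulus nodes clamped, for
`n_steps = 3` — matching the three-edge depth of the mechanism-path
analysis. Boundedness in [-1, 1] is structural (tanh) and property-tested.

Training restrictions are stimulus/response sign maps. Compliance of one
restriction is the fraction of response genes whose propagated activity
matches the expected sign with magnitude above a dead zone of 0.05 (to
avoid crediting numerically-zero activities); the model accuracy is the
mean over restrictions. Solutions are sampled by seeded random
initialisation followed by coordinate hill-climbing on the mean compliance
margin (accuracy never decreases during climbing; only edges within the
propagation radius of any stimulus are touched, as no other edge can
influence a response), and accepted iff accuracy reaches the floor of 0.85.
This sampler is a declared surrogate for unpublished model-building
machinery: it realises the published properties — bounded activities,
training-set accuracy with a viability floor, a population of distinct
solutions, path-explainable signal flow — without gradient training.

Drug exposure enters per patient through an Emax stimulus: target g
receives `effect_g * C/(C + EC50)` with C the brain-curve summary under
the timepoint policy (default Cmax). Per-patient variability therefore
comes entirely from PBPK anthropometrics; molecular (expression-level)
variability between patients is not modelled.

## Mechanism-of-action outcomes

Reversion is strict on both conditions: predicted activity strictly
opposite in sign to the disease-inducing direction and |a| strictly above
the threshold (default 0.5), so boundary activities never count, and the
reverted set grows monotonically as the threshold drops. Effectors absent
from an activity map count as activity 0. The tSignal is defined here as
the signed mean of effector activity times disease sign — a declared
surrogate for a summary statistic whose exact published formula is external
to this work; it is -1 under complete reversion and 0 under no effect.

Population consensus uses the cohort-mean activity by default (a
deterministic function of the cohort; a per-patient majority rule is
available as a config switch), and genes are labelled Adult, Pediatric or
Both. Mechanism paths are enumerated from drug targets to effectors with
at most three edges; a path qualifies in a patient iff the terminal
effector is reverted there with |a| > 0.8 and every traversed edge carries
a non-zero weight whose sign product equals sign(initial target effect) x
sign(terminal activity); paths are kept at a population qualification
frequency of 100% by default. Frequency is counted per patient (one model
per patient), not per sampled solution.

## Synthetic data

The generators define the study conditions for everything not shipped as a
fixture: a preferential-attachment interactome (default 1,000 nodes,
attachment 3 — thousands of nodes with a heavy-tailed degree distribution,
like a real PPI network in miniature), with 30% of edges randomly signed
and 20% directed; six disease characterizations of 60 signed effectors
grouped into 4 motives, built so the base disease shares a controlled
fraction with each comorbidity (defaults 34/20/15/12/8%) and 53% with
their union; and training restrictions generated by propagating random
stimuli through a ground-truth weight vector, hence satisfiable by
construction with accuracy 1.

What the generators do *not* emulate: real gene identity and pathway
structure, correlated effector signs, literature-derived motive semantics,
and expression-level patient variability. Tests passing on synthetic data
therefore validate the machinery (set arithmetic, calibration, solver
behaviour, filters) and its published quantitative anchors, not any
biological claim about specific proteins.

The packaged fixtures transcribe published tables verbatim: the 7-target
drug definition and the two reverted-protein tables (8 eating-disorder
effectors of which 4 are flagged as base-disorder effectors; 49 adult / 44
pediatric depression effectors). One source lists 17 overlapping depression
effectors in its text while flagging 18 in its table; the fixture carries
the table's flags unchanged and no result is built on that count. The
packaged eating-disorder *characterization* is a synthetic stand-in (signs
imputed, flagged `sign_imputed`) because the underlying supplementary
characterization tables are an optional external input, not bundled.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give bit-identical outputs end to end.
- Degenerate inputs fail loudly: empty effector sets, effects outside
  {-1, +1}, weights on non-existent edges, non-brain curves in the drug
  stimulus, cohort sizes below the floor, PBPK parameter sets without an
  elimination path.
- The benchmark sizes used by the tests and the acceptance script (a
  1,000-node sampling benchmark with 20 restrictions and 10 accepted
  solutions; an 80-node tree for ground-truth sign recovery; a 300-node
  network for null calibration) are the package's own choices: large
  enough to exercise hub structure and stable statistics, small enough to
  iterate on quickly.
- Known limitations: linear PBPK only; no identifier mapping between
  gene-symbol conventions; the proximity score is not the proprietary
  score it replaces and printed scores of the original system are not
  reproducible here; hill-climbed solutions stop at the acceptance floor
  rather than maximising accuracy, so reported accuracies cluster near the
  configured minimum.
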