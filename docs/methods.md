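# Methods

## Scope and data model

`semmerge` operates on a declarative JSON dialect for ODE models: a model is
a named, ordered set of variables over exactly one temporal solution domain.
A variable is a constant (numeric value), an algebraic quantity (infix
expression), a state (right-hand side plus initial condition) or the
solution domain, and carries a unit name and optionally a composite
annotation and a submodel-group label. Expressions support the binary
operators `+ - * / ^`, unary minus, the functions `exp, ln, log10, sqrt,
abs, min, max`, the pulse-train helper `pulse(t, period, onset, duration)`,
and `piecewise(cond1, val1, ..., default)` with single-comparison
conditions. The grammar is deliberately Python-expression compatible and is
parsed with the standard-library `ast` module; there is no boolean algebra
in conditions and no event/reset mechanism — periodic stimulation is
encoded with `pulse`, which avoids event location in the integrator. The
dialect is this package's native exchange format and is not claimed to be
compatible with any existing model-exchange standard; nested submodels are
not represented (a flat per-variable group label is enough for name
disambiguation).

Validation is report-based: `validate_model` returns all violations
(duplicate names, dangling symbol references, unknown units, definition
forms inconsistent with the role, missing/multiple solution domains, and
algebraic cycles — cycles are permitted only through the integrated value of
a state) and never raises on invalid content. Editing primitives
(`add_variable`, `rename_variable`) are pure functions returning new
models; renaming rewrites every reference, so it is an alpha-renaming and
trajectories are invariant under it.

## Units

A unit is a vector of integer exponents over the seven SI base dimensions
plus a positive multiplicative scale to coherent base units. Offset units
(Celsius) and logarithmic units are excluded, so substituting a converted
variable is always the linear form `factor × x`. Two units are
commensurable iff their exponent vectors agree; the conversion factor is the
ratio of scales. Scales are stored internally as exact rationals parsed
from decimal text, which makes catalog conversions such as
microlitre→cubic-micrometre exactly `1e9` in floating point rather than
`1e-9/1e-18` rounded. A built-in catalog ships (second, millisecond, volt,
millivolt, ampere, nanoamp, litre, microlitre, cubic micrometre, mole,
molar, millimolar, millimolar/s, kelvin, coulomb/mole, dimensionless);
models may extend or shadow it with their own unit table. Dimensional
checking is applied only where the merge algebra needs it — at coupling
points and glue insertion — not to arbitrary expressions.

## Composite annotations and equivalence

Three annotation variants exist:

* **entity property** — an OPB property term plus an ordered partonomy
  chain of entity terms; position 0 bears the property.
* **process property** — an OPB rate property plus a named process with
  participant entity sets in source/sink/mediator roles; sources and sinks
  carry positive stoichiometric multipliers and the three role sets must be
  pairwise disjoint.
* **singular** — one reference term, used for pervasive constitutive
  constants (Faraday's constant, the gas constant). Other constitutive
  parameters are deliberately left unannotated.

Equivalence is purely structural. Reference terms are compared by
(ontology, id); labels are ignored. Entity properties are equivalent iff
the property terms match and the chains match pairwise at equal length —
no mereotopological reasoning is attempted, so chains at different
granularity (a custom "junctional SR" versus the reference SR term) do not
match, by design. Process properties are equivalent iff the property terms
match and the participant sets match role-for-role with equal multipliers;
the process *name* is ignored (each model names its processes with local
custom terms). Exchanging sources and sinks therefore breaks equivalence:
an association rate and the corresponding dissociation rate are treated as
distinct processes. Cross-variant comparisons are always false.

CUSTOM terms carry meaning only inside their own model: they are compared
by label within one model and never across models. Consequently any
annotation containing a custom term is invisible to automatic cross-model
matching, and the manual-mapping mechanism is the supported escape hatch.

`canonical_key` encodes an annotation's matchable content as deterministic
text, with participant sets serialised order-insensitively, so equivalence
testing reduces to string equality and overlap detection to a hash join.
Custom-containing annotations get keys prefixed with the owning model's
name: equal keys within a model (flowing into the duplicate-annotation
warning path), never-equal keys across models. The test suite checks the
indexed implementation against an independent brute-force double loop over
all variable pairs on 1000+ random annotated models.

## Overlap reports and resolution

`find_overlaps` emits one automatic item per variable pair with equivalent
annotations, plus exactly one item pairing the two solution domains (every
model has exactly one; merging is meaningless without a shared independent
variable, so the pairing does not depend on annotation). Items carry
unit-mismatch status and, when commensurable, the exact left→right
conversion factor. If two variables of one model share a canonical key the
ambiguity is reported as a warning and excluded from automatic pairing —
the package takes no position on which pairing is meant. Item order is a
stable sort by canonical key, so repeated runs are byte-identical.

Manual mappings add items for pairs the annotations cannot connect (custom
terms, granularity mismatches, unannotated counterparts); their unit status
is computed the same way, and incommensurable manual pairs carry no factor —
a keep on such a pair is later rejected by the merger.

A batch decisions file resolves items by concept label or variable pair;
unreferenced items default to `ignore`, except the solution-domain item
which defaults to `keep_left`. Duplicate or dangling decisions are
rejected.

## Merge algebra

For each `keep` resolution with kept variable K and discarded variable D,
D's entire definition — including any initial condition, when both sides
are states — is removed, and every surviving reference to D is replaced by
`c × K` where `c` converts K's units into D's declared units (omitted when
1). Surviving equations thus keep their original numeric meaning in their
original units. The conversion direction is fixed by this rule; the
discarded side's equations are the ones being rewritten, so they receive
the kept value expressed in the units they were written against. A keep
across incommensurable units (current vs concentration flow) is rejected
with both pairs named; the supported route is inserting a glue variable
(`add_variable`) that performs the biophysical conversion explicitly, after
which the glue's annotation makes the pairing automatic.

`ignore` keeps both representations intact. After discards, name
collisions among survivors are resolved by suffixing the right-model
variable with `__<right model name>` (numeric suffix on further collision),
deterministically and log-recorded; unit tables are unioned with the same
rename rule on conflicting definitions. The merged model keeps
`|A| + |B| − #keeps` variables (the solution-domain keep included) and must
pass validation; every resolve, rename and ignore is recorded in the merge
log. Discarded variables' private upstream parameters are left in place as
dead code — pruning is a separate, explicit operation, never applied
implicitly.

`prune(model, outputs)` keeps exactly the outputs, their ancestors in the
dependency graph (edge u→v iff v's definition references u, state
right-hand sides included), and the solution domain. Removed variables are
by construction never read by retained ones, so retained trajectories are
unchanged; the suite asserts agreement to 1e-9 absolute.

Three-way merges are performed as sequential pairwise merges.

## Simulation

A valid model compiles to one generated Python function: constants, then
algebraic variables in lexicographic-topological order, then state
derivatives. Evaluation at (t, state) is pure; variables are name-mangled
into function locals and only the fixed math vocabulary is in scope. The
integrator is classical fixed-step fourth-order Runge–Kutta with output at
every step. No adaptive stepping and no stiff solver: the fixtures are
constructed non-stiff, and bit-level determinism across runs and platforms
is worth more here than efficiency. Piecewise discontinuities are handled
by evaluation only; choosing a step commensurate with pulse edges (the
fixtures put edges on multiples of 1 ms) keeps the order-4 behaviour, which
the suite verifies by checking that the exponential-decay error falls ~16×
when the step is halved. Non-finite values abort integration naming the
variable and time. Trajectories serialise to CSV with `repr` formatting, so
identical inputs give byte-identical files.

## The fixture suite

The suite is the package's test surface and defines its study conditions:

* **E** — stimulus-driven membrane potential (mV): leak and background
  calcium currents in nA, a Nernst potential reading cytosolic calcium, a
  2 ms/1 Hz pulse train, cell volume 1.6e-5 µL, Faraday's constant
  annotated with a singular term, and a vestigial SR branch (uptake flux and
  SR calcium state) that reads cytosolic calcium but feeds nothing — the
  designed pruning target, annotated with a CUSTOM "junctional SR" entity.
* **E_epi** — E with identical names, perturbed parameters, no annotations:
  the annotation-transfer target.
* **C** — calcium dynamics (mM): background influx and sarcolemmal
  extrusion, SR uptake/release, troponin buffering with a CUSTOM
  "calcium-bound troponin" entity, a voltage-gated influx driven by an
  *unannotated* clamp voltage, volume 16000 µm³. Background transport is a
  chemical concentration flow rate (mM/s) — ontologically distinct from E's
  current.
* **C_prime** — C plus the glue variable `i_b_Ca_C = −(2·F·Vol·J)·1e-9`
  (flux × valence × Faraday × volume, scaled to nA), annotated as a charge
  flow rate with the same participants as E's background current.
* **T** — troponin buffering (duplicated at its own granularity, custom
  terms) driving first-order tension (kPa, a model-local unit extending the
  catalog).

The designed overlap manifest is part of the suite: E↔C share exactly
{calcium, volume, Faraday, time}; E↔C_prime additionally the background
current; the resolved excitation-calcium merge ↔ T share exactly {calcium,
time}. The canonical resolution set keeps C's calcium and current, E's
volume and time, C's Faraday, and maps E's membrane potential onto C's
clamp voltage manually — the one equivalency the annotations cannot express,
and the coupling that lets the stimulus reach calcium influx and hence
tension.

Parameters are package inventions tuned once for a stable 1 Hz-forced limit
cycle: resting calcium ~1.2e-4 mM with the influx/extrusion balance fixed
at that point, SR turnover fast enough (release 1/s, volume ratio 10) that
the SR re-equilibrates between beats, troponin with Kd 5e-4 mM providing
realistic-in-kind buffering (buffer capacity ≈ 55), and extrusion strong
enough (250/s) that the buffered transient decays with ~0.2 s effective
time constant. The dynamics are deliberately simple — linear fluxes, one
gate, no Hill functions, no stiffness — because the suite's purpose is
semantic-topology fidelity (which concepts are shared, in which units, with
which custom-term obstacles), not electrophysiological realism. Passing
tests therefore demonstrate correctness of annotation matching, merge
rewiring, unit substitution and pruning on models *shaped* like the real
use case; they say nothing about reproducing any published model's curves,
which would require those models' equations and annotation sets.

Random annotated models for the oracle property are drawn from a small
fixed term pool (including custom terms and a shorter-granularity calcium
chain) with high duplication probability, deterministic per seed; they are
valid but not necessarily simulatable, which is all overlap detection
needs.

## Numerical and design choices

* Problem sizes: trajectory-comparison checks integrate 2 s at dt = 1 ms;
  the coupled-beat check integrates 5 s (five stimulus periods); the oracle
  property uses 1000 random pairs of ≤ 50 variables. All chosen as the
  smallest sizes that exercise the behaviour being measured.
* Transients are counted as upward crossings of the midpoint between a
  trajectory's extremes — robust to the small beat-to-beat memory the SR
  introduces.
* Tolerances: non-interference to 1e-6 relative (identical integrator
  settings make this conservative; measured deviation is 0), unit
  substitution and pruning to 1e-9 absolute (both measured at exactly 0
  because substituted expressions are arranged to be floating-point
  identical), integrator order within a factor 2 of the ideal 16×.
* Stoichiometric multipliers must be equal for participant matching — the
  conservative choice where the semantics are underdetermined.
* Chain order is compared exactly at every position, not just position 0;
  users should annotate partonomies at consistent depth or fall back to
  manual mappings.

## Known limitations

* No semantic-similarity scoring: near-miss concepts (charge flow vs
  concentration flow, single-pool vs two-pool SR) are reported as absent,
  not as candidates.
* Custom terms cannot be linked to reference terms (no `has_part`
  relations), so custom-annotated concepts always need manual mappings.
* Opposite-directionality processes are not recognised as related.
* No dimensional validation inside arbitrary expressions; a dimensionally
  wrong glue expression is the annotator's responsibility.
* Fixed-step RK4 limits the package to non-stiff models at practical step
  sizes; there is no event handling beyond evaluated piecewise terms.
* Merging does not reformulate conservation laws when two processes merge;
  the glue-variable route is the supported mechanism.
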