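# Methods

## Model

`boolsense` infers which total Boolean functions `F : {0,1}^k -> {0,1}` can
explain the expression of one output gene across a population of `n`
equivalent cell units exposed to `k` extracellular signals. The inference
is exhaustive and parameter-free: no kinetics, no thresholds, no priors on
`F`. Its inputs are

1. per-signal *strength orderings* — weak orders over cells encoding who is
   more exposed to each signaling source;
2. per-signal *reception masks* — cells physically able to receive the
   ligand;
3. a roster of *conditions* — per-signal overrides (`none` / `force0` /
   `force1`) with per-cell observed output (`1` / `0` / `unknown`).

A *sensing pattern* assigns each cell one bit per signal. The
signaling-source rule keeps, per signal, only the up-closed state sets of
the ordering: for a chain of `g` tie-groups covering the mask these are the
`g + 1` chain prefixes; mask cells not mentioned by the ordering are
unconstrained (factor 2 each); cells outside the mask are pinned to 0. The
admissible set is the Cartesian product over signals, enumerated lazily and
counted in closed form.

The uniqueness rule is implemented as truth-table consistency. Each
condition deterministically transforms a candidate pattern — `force0`
zeroes a column, `force1` saturates it on the reception mask — and every
observed cell contributes the constraint `F(perturbed tuple) = observation`.
A candidate dies on the first tuple assigned both 0 and 1; the
contradiction object carries the offending tuple and both witnessing
(condition, cell) pairs so rejections are explainable. The textbook special
case ("cells with identical states cannot differ in output") is exactly the
unperturbed condition's instance of this check.

Survivors carry partial truth tables; completions are counted as
`2^#undetermined` and enumerated by binary counting over the sorted
undetermined rows (guarded at 20 open rows by default). Functions common to
all survivors are the completions of the conflict-checked merge of their
tables.

## Criticality

For a (pattern, function) pair with a non-uniform output, each signal is
classified by replacing its column with each constant (a forced 1 still
respects the reception mask) and recomputing outputs:

* both uniformizations collapse the output to a constant — **critical**:
  the signal's cell-to-cell differential is what carries the pattern;
* at least one uniformization reproduces the exact unperturbed output
  partition — **dispensable**;
* a constant column — **uniform** (no differential to remove).

The remaining combination (patterning changes but neither collapses nor is
preserved) is labeled critical with a `mixed` annotation in the detailed
view; the reference analyses never exercise it, so the labeling is a
package convention rather than an established one. When several functions
complete a survivor's table, the per-survivor summary reports a signal as
critical only if it is critical under every function with a differential
output. Note that with only two cells any differential signal whose
partner signals are uniform is automatically critical (both uniformizations
hand both cells identical tuples); criticality is most informative at
larger `n`.

A masked signal can be classified dispensable even when it visibly patterns
the tissue (forcing it "on" cannot reach cells outside the mask, so the
differential survives the uniformization). This is the intended semantics:
criticality asks whether the *differential* could in principle be removed
by a uniform treatment.

## Ordering derivation from contact areas

`ordering_from_contacts` sorts cells by descending contact area with
ligand-expressing cells and merges consecutive cells whose areas differ by
at most a relative `tie_tolerance` (default 0 — clean geometric data yield
strict chains; the tolerance exists for noisy measurements, and equal
evidence gives no basis for a threshold between two cells, hence forced
shared states within a tie-group). Zero-contact cells are appended after
all contacting cells, ordered by an optional fallback rank (e.g. distance
to the source, used when a diffusible ligand never touches a cell directly)
or as one final tie-group. The result is invariant under rescaling all
areas, and shrinking the tolerance never merges previously separate groups.
For membrane-tethered ligands the CSV loader can drop autocrine
(source == cell) rows before aggregation.

## Fixtures and what they do (and do not) show

The toy fixtures (`fig2_system`, `s1fig_system`, `s2fig_system`) are exact
two-cell worked examples: opposing sources, one induced cell, and two
knockdown experiments; the variants differ in `b`'s reception mask or
expression domain. They exercise every stage at a scale where brute force
over all 16 assignments and all 16 two-input functions is feasible, and the
test suite checks the pipeline against exactly that oracle.

The embryo fixtures model the animal hemisphere of the 32-cell ascidian
embryo: eight units (bilateral pairs `a6.5`–`b6.8`), four signals
(`admp`, `efn`, `fgf`, `gdf`), output *Otx*. Their strength orderings and
per-condition outcomes ship as data files, not code, so alternative
geometries are config swaps. **The shipped orderings and condition
outcomes are synthetic reconstructions**, not transcriptions of measured
contact-area tables or per-embryo scoring: they encode the known source
geometry (posterior b-line sources for Admp/Gdf with a-line cells ranked by
distance; vegetal Fgf strongest in the neural lineage; pan-ectodermal
tethered Efna.d weakest in the peripheral neural-lineage cells, autocrine
reception excluded) and the established qualitative phenotypes (wild-type
neural-lineage expression; ectopic expression throughout the ectoderm upon
Efn knockdown or Admp+Gdf double knockdown; loss upon Fgf-containing
knockdowns; neural-lineage-restricted rescue of the triple morphant by a
uniform bFGF+BMP4 bath; pan-ectodermal expression when Efn is also removed
under the bath). The `a6.7` unit, whose occasional *Otx* expression is not
tightly regulated, is scored `unknown` in every neural-lineage-like
observation so it contributes no constraint there (encoding it as 0 instead
is a one-line config change). Passing the embryo tests therefore shows the
machinery reproduces the reference analysis *given this reconstruction*;
it does not validate the reconstruction against raw geometry, which users
with measured areas can redo via `boolsense order`.

The `early` stage differs only in the Gdf ordering (the neural-lineage
`b6.5` drops to second-weakest), which admits a fourth survivor compatible
with eight Boolean functions — one of them the single function shared by
the mid-to-late survivors — without changing the criticality verdict.

## Synthetic-data generator

`random_system(n_cells, k_signals, n_conditions, seed)` draws random chain
orderings (uniform permutation, adjacent tie merges with probability 0.3),
occasionally (p = 0.2) excludes one cell from a signal's mask, picks the
ground-truth pattern uniformly from the admissible set and the truth
function uniformly from all `2^(2^k)` functions, and generates a wild type
plus random one- or two-signal `force0`/`force1` conditions whose
observations are computed from the truth. Everything derives from one
`random.Random(seed)`, so runs are fully reproducible. The generator
emulates noiseless, whole-population perturbations only: no observation
error, no mosaic (per-cell) perturbations, no partial knockdowns. Soundness
on this data (the truth always survives and the truth function completes
its table) is a property of the logic, not evidence about noisy real
measurements.

Note one subtlety established during testing: a surviving pattern *other*
than the truth maps the same observations onto different input tuples, so
the truth function need not complete every survivor's table — only the
true pattern's. Tests and the acceptance sweep assert exactly that.

## Numerical and interface choices

* Enumeration order is deterministic everywhere: per-signal states run
  all-0 to all-1 (chain depth outer, free-cell binary counter inner),
  whole-system patterns are the lexicographic product (first signal
  slowest), completions fill sorted undetermined rows by binary counting.
* Pattern enumeration streams through recursive generators, so admissible
  sets far too large to materialize can still be iterated; counts are
  always computed in closed form.
* The classical 1–16 numbering of two-cell patterns is reconstructed as
  `4·(i − 1) + j` over cell-state order (0,0), (0,1), (1,0), (1,1) and
  pinned in tests by the four exclusion lists it must reproduce.
* Function identity is the truth table itself; reports add a readable
  expression only for `k ≤ 2` (no canonical minimization beyond that).
* Problem sizes: the full embryo screen (6,561 patterns × 15 conditions ×
  8 cells) and the exhaustive small-system oracle comparison (194 systems)
  run in about a second each; the acceptance sweep uses 100 synthetic
  systems with 3–5 cells and 1–3 signals.

## Limitations

Binary activity levels (no dose–response); whole-population overrides only;
weak-order (chain) geometries rather than general posets; strictly logical
screening (a single inconsistent observation kills a candidate — no noise
model); and the embryo data files are reconstructions as described above.
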