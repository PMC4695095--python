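# boolsense

Parameter-free inference of Boolean functions for signal-driven gene
induction in populations of equivalent cells.

## The problem

Early embryos pattern fields of initially equivalent cells with a handful of
extracellular signals. In the 32-cell ascidian embryo, four ligands — Admp,
Efna.d, Fgf9/16/20 and Gdf1/3-r — jointly control which of the eight pairs
of ectodermal blastomeres switch on the neural marker *Otx*. Quantitative
gradient models need kinetic parameters that are hard to measure; `boolsense`
instead treats each pathway's activity in each cell as a binary value and
asks which logic is *compatible* with the observed expression, using only
expression patterns, source geometry, and perturbation outcomes.

Write the output of cell *c* as

```
X_o(c) = F(X_1(c), ..., X_k(c))
```

where `X_j(c) ∈ {0,1}` says whether cell *c* senses signal *j* above
threshold and `F` is an unknown total Boolean function shared by all cells.
The joint assignment `{X_j(c)}` over all cells is a **sensing pattern**.
Two principles prune the hypothesis space:

* **Signaling sources (Rule 1).** A cell with more exposure to a ligand
  source (larger contact area, shorter distance) cannot sense it more weakly
  than a less-exposed cell. Per signal, the admissible state sets are the
  up-closed sets of the strength ordering — for a strict chain over *n*
  cells, exactly *n* + 1 of the 2^*n* possibilities.
* **Uniqueness (Rule 2).** One input tuple cannot map to both expression
  and silence, in any cell, under any experimental condition. Knockdowns
  (`force0`) and gain-of-function treatments (`force1`, respecting each
  ligand's reception mask) transform a candidate pattern deterministically,
  so every observation becomes a truth-table constraint; candidates whose
  constraints clash are discarded.

Surviving patterns each carry a partial truth table; every undetermined row
doubles the count of compatible Boolean functions (`2^#undetermined`). The
package intersects function sets across survivors and classifies each
signal as `uniform`, `dispensable`, or `critical` — critical meaning the
output pattern collapses whenever that signal's cell-to-cell differential
is removed.

## Worked example

The classic two-cell system: signals *a* and *b* from opposite poles, gene
*o* on in cell I only; knocking down *a* silences *o*, knocking down *b*
turns it on everywhere.

```
$ boolsense fixture fig2 --out-dir demo
$ boolsense count demo/fig2_system.yaml --unconstrained
16
$ boolsense count demo/fig2_system.yaml
9
$ boolsense screen demo/fig2_system.yaml demo/fig2_conditions.yaml --text
Screen of 'o': 2 of 9 admissible sensing patterns survive

sensing pattern 1
  cell      X_a  X_b
  I         1    1
  II        0    1
  compatible Boolean functions: 1
  unique function: F = a OR NOT b
  criticality: a: critical, b: uniform

sensing pattern 2
  cell      X_a  X_b
  I         1    0
  II        1    1
  compatible Boolean functions: 1
  unique function: F = a AND NOT b
  criticality: a: uniform, b: critical

functions compatible with every survivor: 0
conflicting rows across survivors: (0,0), (1,1)
```

Reading: geometry cuts 16 joint states to 9; the two experiments cannot
distinguish "a activates o and is the patterning signal" from "b represses
o and is the patterning signal", but they *prove* these are the only two
consistent readings — and that a joint perturbation probing F(0,0) or
F(1,1) would discriminate them.

The embryo-scale fixture works the same way at 8 cells × 4 signals:
`boolsense screen demo/embryo_system.yaml demo/embryo_conditions.yaml`
reduces (2^4)^8 ≈ 4.3 × 10^9 conceivable sensing patterns to 9^4 = 6,561
admissible ones and then to 3 survivors, all compatible with a single
Boolean function whose only patterning-critical input is the
contact-dependent Efna.d signal. See `docs/methods.md` for the model's
assumptions and the provenance of the embryo fixture data.

The same machinery is available as a library:

```python
from boolsense import fixtures, screen_system

system, conditions = fixtures.embryo_system("mid_late")
result = screen_system(system, conditions)
len(result.surviving_patterns)   # 3
len(result.common_functions)     # 1
result.criticality[0]["efn"]     # 'critical'
```

Orderings can be derived from measured contact areas with
`boolsense order areas.csv --tie-tol 0.05 [--fallback ranks.csv]`.

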