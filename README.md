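# growthzones

Bifurcation analysis of competing growth-zone activation in fission yeast.

*Schizosaccharomyces pombe* grows from its cell tips: after division only
the inherited old end extends, and partway through the cycle the new end
switches on — *new-end take-off* (NETO). This package implements a minimal
dynamical model of that length-sensing switch: growth zones (polarisome
complexes) at the tips activate autocatalytically while competing for a
single diffusible substrate whose total amount is proportional to cell
length. It is aimed at modellers of cell polarity who want the full
bifurcation structure of such substrate-competition models — branch
continuation, fold/pitchfork detection, parameter-plane phenotype maps and
quasi-static cell-cycle simulation — from one reproducible toolkit.

## Model

Each of *n* growth zones carries an active fraction *xᵢ* ∈ [0, 1]. With
zone weights *aᵢ* (share of total polarisome, Σaᵢ = 1), substrate
parameter *l* (total substrate in units of total polarisome) and free
substrate *s = l − Σⱼ aⱼxⱼ*, the non-dimensional dynamics are

    dxᵢ/dτ = (ε + β (aᵢ xᵢ)²) · s · (1 − xᵢ) − xᵢ ,

basal activation at strength ε, autocatalytic activation quadratic in the
active amount at strength β, and first-order inactivation setting the time
scale. *l* < 1 means the substrate cannot activate every zone fully. As
*l* grows (the cell lengthens) the steady states reorganise:

* a single low-activity state (the round **orb** phenotype),
* a sub-critical pitchfork creating a pair of mirror **monopolar** states,
* a second pitchfork restabilising the symmetric **bipolar** state,
* saddle-node folds terminating the monopolar branches — **NETO**: the
  growing cell tracks the monopolar branch until it ceases to exist, then
  jumps to bipolar growth.

Unequal tip weights make the pitchforks imperfect: the disfavoured tip's
monopolar states detach into a closed *island* with exactly two folds,
predicting a tip-switching growth pattern at moderate asymmetry; a third
(lateral) zone yields monopolar/bipolar/tripolar hierarchies.

## Worked example

```python
from growthzones import NondimParams, build_diagram, neto_length

params = NondimParams(epsilon=0.1, beta=20.0, a=(0.5, 0.5))
diagram = build_diagram(params, l_range=(0.05, 2.5))
for b in diagram.branches:
    print(b.label, round(float(b.l.min()), 4), round(float(b.l.max()), 4))
print("NETO at l* =", round(neto_length(diagram, "monopolar_1"), 4))
```

prints

```
orb 0.05 1.0136
symmetric_unstable 1.0136 1.1862
bipolar 1.1862 2.5
monopolar_2 0.9829 1.2558
monopolar_1 0.9831 1.2557
NETO at l* = 1.2558
```

The symmetric state loses stability at the first pitchfork (l ≈ 1.014) and
regains it at the second (l ≈ 1.186); the monopolar branches reach back to
l ≈ 0.983 (sub-critical overlap with the orb state) and end in the NETO
fold at l* ≈ 1.256, beyond the bipolar onset — so monopolar and bipolar
growth coexist over 1.186 < l < 1.256, and a growing cell takes off only
at l*. Every assembled diagram is validated against brute-force
grid-seeded Newton enumeration of equilibria at sampled l values.

The `examples/` scripts walk through each capability (nullclines,
wild-type constraint solving, cycle simulation, islands, three zones,
parameter-plane scans, lineages), and the `growthzones` command exposes
the same operations from the shell (`growthzones diagram --epsilon 0.1
--beta 20 --out run`).

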