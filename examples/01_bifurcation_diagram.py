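"""Build the wild-type-like bifurcation diagram of a symmetric cell.

The substrate parameter l (total substrate in units of total polarisome)
stands in for cell length.  As l grows the cell passes from the inactive
orb state through a monopolar window to bipolar growth; NETO is the fold
at which the monopolar branch disappears.
"""
from growthzones import NondimParams, build_diagram, neto_length

params = NondimParams(epsilon=0.1, beta=20.0, a=(0.5, 0.5))
diagram = build_diagram(params, l_range=(0.05, 2.5))

print("branches found:")
for b in diagram.branches:
    folds = [round(sp.l, 4) for sp in b.special_points if sp.kind == "fold"]
    print(f"  {b.label:20s} l in [{b.l.min():.4f}, {b.l.max():.4f}]"
          + (f"  folds at {folds}" if folds else ""))

pfs = sorted({round(sp.l, 4) for b in diagram.branches
              for sp in b.special_points if sp.kind == "branch_point"})
print(f"pitchforks of the symmetric state at l = {pfs}")
print(f"NETO length (monopolar fold): l* = {neto_length(diagram, 'monopolar_1'):.4f}")
print("Between the second pitchfork and l* the monopolar and bipolar states")
print("coexist: a growing cell stays monopolar until l* and then jumps — NETO.")
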