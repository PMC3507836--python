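"""Imperfect pitchforks: the island of the disfavoured tip.

Unequal polarisome shares break the pitchforks; the weaker tip's monopolar
states detach into a closed island that shrinks and vanishes as the
asymmetry grows — predicting a transient tip-switching growth pattern at
moderate asymmetry only.
"""
from growthzones import ContinuationSettings, NondimParams, build_diagram

for delta in (0.008, 0.02, 0.1):
    p = NondimParams(0.1, 20.0, (0.5 + delta, 0.5 - delta))
    d = build_diagram(p, (0.05, 2.5), ContinuationSettings(validate=False))
    islands = [b for b in d.branches if b.closed]
    if islands:
        isl = islands[0]
        folds = sorted(sp.l for sp in isl.special_points if sp.kind == "fold")
        print(f"delta={delta}: island ({isl.label}) between folds "
              f"l = {folds[0]:.4f} and {folds[1]:.4f}")
    else:
        print(f"delta={delta}: no island — only the favoured tip's connected branch")
print("A cell born on the island switches to the opposite tip when the island")
print("ends; once the island is gone only the standard pattern remains.")
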