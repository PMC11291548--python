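"""Assemble domain architectures with tiered chitin-binding domains.

Chitin-binding (CBM_14) hits are tiered by independent e-value alone:
confident below 1e-5, degenerate CBM_14L1 in [1e-5, 1), barely
recognizable CBM_14L2 in [1, 1e4).
"""

from archetyper import (SyntheticSpec, assemble_architecture, assign_tier,
                        plant_family)
from archetyper.lg_inserts import locate_anchor_pair

for ev in (1e-6, 0.5, 5000.0, 20000.0):
    print(f"independent e-value {ev:>8g} -> tier {assign_tier(ev)}")
print()

spec = SyntheticSpec(n_per_subfamily=2, seed=42)
proteins, hits, truth = plant_family(spec)
by_prot = {}
for h in hits:
    by_prot.setdefault(h.protein_id, []).append(h)

for prot in proteins[::2]:
    n_span, c_span = locate_anchor_pair(prot)
    arch = assemble_architecture(prot, by_prot[prot.id],
                                 n_anchor_span=n_span,
                                 c_anchor_span=c_span)
    layout = " - ".join(e.tier or e.cls for e in arch.elements)
    print(f"{prot.id:10s} n_vwa={arch.n_vwa}  LG={arch.lg_status:8s} "
          f"{layout}")
# The BMSP-like template shows four tandem VWA domains; the PifCCP-like
# one interleaves Sushi repeats between VWA and the CB domain, matching
# the canonical family architectures.
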