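"""Tagged replicons and core<->total coordinate liftover.

Builds a small replicon carrying one ISH2 insertion with an 8 bp target-site
duplication, writes it in the tagged dialect, and shows how removing the
element (plus one TSD copy) maps coordinates between the total and the core
frame.
"""

import random

from mgecore import CoordinateMap, parse_tagged_replicon, write_tagged_replicon

rng = random.Random(0)
rand = lambda n: "".join(rng.choice("ACGT") for _ in range(n))

u1, tsd, elem, u2 = rand(499), rand(8), rand(1520), rand(965)
text = (
    ">demo topology=linear strain=demo\n"
    + u1 + "\n"
    + f">>MGE type=ISH2 tsd={tsd}\n"
    + tsd + elem + tsd + "\n"
    + "<<MGE\n"
    + u2 + "\n"
)
rep = parse_tagged_replicon(text)
print("segments:", [(s.start, s.end, s.kind) for s in rep.segments])
print("round-trips byte-identically:",
      parse_tagged_replicon(write_tagged_replicon(rep)).segments == rep.segments)

# removing the element + downstream TSD copy: 1528 bp starting at 508
cmap = CoordinateMap(total_length=len(rep), removals=[(508, 1528)])
print(f"total length {len(rep)} -> core length {cmap.core_length}")
for core_pos in (499, 507, 508, 900):
    print(f"core {core_pos} -> total {cmap.core_to_total(core_pos)}")
# core 508 maps past the removed element: the empty pre-insertion site is
# restored, so downstream coordinates shift by element + one TSD (1528 bp)
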