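"""Design a positional crosslinker-substitution array for the bait panel.

Each bait is expanded into 12 spots with the pBpa crosslinker at a
different, evenly spread position plus one unmodified control spot, and
the spots are laid out on a 24x16 SPOT membrane.
"""

from paxms.array_design import DesignProfile, design_substitution_series, layout_membranes
from paxms.baits import bait_panel
from paxms.motif_domain import scan_motifs
from paxms.array_design import annotate_motif_overlap

profile = DesignProfile()  # 12 substituted spots + unmodified control
spots = []
for bait in bait_panel():
    series = design_substitution_series(bait, profile)
    hits = scan_motifs(bait.sequence, bait_id=bait.id)
    spots += annotate_motif_overlap(series, hits)

spots = layout_membranes(spots)
print(f"{len(spots)} spots for {len(bait_panel())} baits on membrane 1 "
      f"(capacity 384 = 24 x 16)")
for s in spots[:4] + spots[-2:]:
    m, r, c = s.grid
    flag = " motif-overlap" if s.motif_overlap else ""
    print(f"  {s.bait_id:8s} pos {s.crosslinker_position:2d} -> row {r:2d} col {c:2d}{flag}")
# A spot whose substituted residue falls inside a consensus motif is
# expected to lose binding; the flag marks those positions in advance.
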