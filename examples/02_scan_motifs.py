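"""Scan the bait panel for consensus motifs and the domains they predict.

Each motif class (PxxP, NPF, PPxxF, PPLP, (F/L)PPPP) maps to the domain
family known to bind it (SH3, EH, EVH1 class II, WW, EVH1 class I); the
union over a bait's motifs is the set of domains a legitimate direct
binder should carry.
"""

from paxms.baits import bait_panel
from paxms.motif_domain import expected_domains, scan_motifs

for bait in bait_panel():
    hits = scan_motifs(bait.sequence, bait_id=bait.id)
    domains = expected_domains(bait)
    motifs = ", ".join(f"{h.motif_name}@{h.start}" for h in hits) or "none"
    print(f"{bait.id:8s} {bait.sequence:20s} motifs: {motifs}")
    print(f"{'':8s} expected binder domains: {sorted(domains) or 'none'}")
# The motif-free control peptide predicts no domains: any protein it
# captures is by definition a non-specific binder.
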