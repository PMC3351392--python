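"""Packaged worked example: a six-peptide proline-motif bait panel.

Five 14-18-mer proline-motif peptides drawn from well-characterized
signaling proteins (SOS1, Stonin2, Epsin1, mGluR5, WAVE1) plus a motif-free
negative-control peptide with no close mammalian homology.  Together they
cover the PxxP/SH3, NPF/EH, PPxxF/EVH1-classII, PPLP/WW and
(F/L)PPPP/EVH1-classI motif-domain pairings.

``CURATED_DOMAINS`` is a small curated fixture mapping the panel's
best-known prey proteins to their peptide-binding domain classes; it is a
hand-maintained illustration set, not a database snapshot — in real use the
annotation table is exported from Pfam/InterPro.  ``KNOWN_PAIRS`` lists
previously reported bait-prey interactions for the panel, for the
known-interaction flag in reports.
"""

from __future__ import annotations

from .array_design import BaitPeptide

__all__ = ["BAIT_PANEL", "CONTROL_BAIT_ID", "CURATED_DOMAINS", "KNOWN_PAIRS", "bait_panel"]

CONTROL_BAIT_ID = "Control"

_PANEL = (
    ("Control", "AYGDLPFYVRSDGLRSHF", "synthetic control", "motif-free negative control"),
    ("SOS1", "VPPPVPPRRRPESAPAES", "Son of sevenless homolog 1", "PxxP / SH3 ligand"),
    ("Stonin2", "PWRATNPFLNETLQ", "Stonin-2", "NPF / EH ligand"),
    ("Epsin1", "GAKASNPFLPSGAP", "Epsin-1", "NPF + PxxP ligand"),
    ("mGluR5", "ELVALTPPSPFRDSVDS", "Metabotropic glutamate receptor 5", "PPxxF / EVH1 class II ligand"),
    ("WAVE1", "PQGEVQGLPPPPPPPPLP", "WASP-family verprolin homolog 1", "poly-proline ligand"),
)


def bait_panel() -> list[BaitPeptide]:
    """Fresh BaitPeptide objects for the packaged worked-example panel."""
    return [BaitPeptide(i, s, source_protein=p, notes=n) for i, s, p, n in _PANEL]


BAIT_PANEL: tuple[BaitPeptide, ...] = tuple(bait_panel())

# Curated fixture: prey protein -> peptide-binding domain classes.
CURATED_DOMAINS: dict[str, frozenset[str]] = {
    "Grb2": frozenset({"SH3"}),
    "Itsn1": frozenset({"SH3", "EH"}),
    "Pacsin1": frozenset({"SH3"}),
    "Sh3kbp1": frozenset({"SH3"}),
    "Cd2ap": frozenset({"SH3"}),
    "Amph": frozenset({"SH3"}),
    "Eps15l1": frozenset({"EH"}),
    "Ehd3": frozenset({"EH"}),
    "Homer1": frozenset({"EVH1_classII"}),
    "Homer3": frozenset({"EVH1_classII"}),
    "Vasp": frozenset({"EVH1_classI"}),
    "Enah": frozenset({"EVH1_classI"}),
    "Gas7": frozenset({"WW"}),
}

# Previously reported bait-prey interactions for the panel (bait id, prey).
KNOWN_PAIRS: tuple[tuple[str, str], ...] = (
    ("SOS1", "Grb2"),
    ("SOS1", "Itsn1"),
    ("SOS1", "Pacsin1"),
    ("SOS1", "Sh3kbp1"),
    ("SOS1", "Cd2ap"),
    ("Stonin2", "Eps15l1"),
    ("Stonin2", "Itsn1"),
    ("Epsin1", "Eps15l1"),
    ("mGluR5", "Homer1"),
    ("mGluR5", "Homer3"),
)
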