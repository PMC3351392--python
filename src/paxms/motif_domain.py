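"""Consensus-motif scanning and interaction-domain expectation mapping.

Short peptide ligands are recognized by families of protein interaction
domains via consensus motifs: poly-proline PxxP by SH3 domains, NPF by EH
domains, PPxxF by class II EVH1 domains (Homer/Vesl), PPLP by WW domains and
(F/L)PPPP by class I EVH1 domains (Ena/VASP).  Scanning a bait peptide for
these motifs predicts which domain classes a legitimate direct binder should
carry, which is the basis of the domain-filtering stage.

Pattern language: an upper-case amino-acid letter matches itself, ``x`` (or
``X``) matches any of the 20 standard residues, and ``{FL}`` matches any
residue in the braces.  A crosslinker placeholder (``@``) in a variant
sequence matches no pattern position: substituting a motif residue with the
crosslinker destroys the motif.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "AMINO_ACIDS",
    "MotifClass",
    "MotifHit",
    "default_registry",
    "scan_motifs",
    "expected_domains",
    "read_registry",
    "write_registry",
]


def _parse_pattern(pattern: str) -> list[frozenset[str] | None]:
    """Compile a motif pattern into per-position residue sets.

    ``None`` marks a wildcard position.  Raises ``ValueError`` on malformed
    patterns (unclosed braces, non-amino-acid letters).
    """
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "{":
            j = pattern.find("}", i)
            if j < 0:
                raise ValueError(f"unclosed '{{' in pattern {pattern!r}")
            alts = pattern[i + 1 : j].upper()
            if not alts or not set(alts) <= AMINO_ACIDS:
                raise ValueError(f"bad alternative set in pattern {pattern!r}")
            positions.append(frozenset(alts))
            i = j + 1
        elif ch in "xX":
            positions.append(None)
            i += 1
        else:
            up = ch.upper()
            if up not in AMINO_ACIDS:
                raise ValueError(f"invalid pattern character {ch!r} in {pattern!r}")
            positions.append(frozenset(up))
            i += 1
    if len(positions) < 3:
        raise ValueError(f"pattern {pattern!r} shorter than 3 positions")
    return positions


@dataclass(frozen=True)
class MotifClass:
    """A consensus motif and the domain classes expected to bind it."""

    name: str
    pattern: str
    expected_domains: frozenset[str]
    _compiled: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.expected_domains:
            raise ValueError(f"motif {self.name!r} has no expected domains")
        object.__setattr__(self, "expected_domains", frozenset(self.expected_domains))
        object.__setattr__(self, "_compiled", tuple(_parse_pattern(self.pattern)))

    def __len__(self) -> int:
        return len(self._compiled)

    def matches_at(self, sequence: str, start0: int) -> bool:
        """True if the pattern matches ``sequence`` at 0-based ``start0``."""
        if start0 < 0 or start0 + len(self._compiled) > len(sequence):
            return False
        for pos, allowed in zip(sequence[start0 : start0 + len(self._compiled)], self._compiled):
            if allowed is None:
                if pos not in AMINO_ACIDS:  # wildcard still requires a real residue
                    return False
            elif pos not in allowed:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    """One motif match in a bait: 1-based start and the matched substring."""

    bait_id: str
    motif_name: str
    start: int
    match: str

    @property
    def end(self) -> int:
        """1-based index of the last matched residue."""
        return self.start + len(self.match) - 1


def default_registry() -> list[MotifClass]:
    """The proline-motif registry for the packaged bait panel.

    PxxP -> SH3, NPF -> EH, PPxxF -> EVH1 class II, PPLP -> WW,
    (F/L)PPPP -> EVH1 class I.
    """
    return [
        MotifClass("PxxP", "PxxP", frozenset({"SH3"})),
        MotifClass("NPF", "NPF", frozenset({"EH"})),
        MotifClass("PPxxF", "PPxxF", frozenset({"EVH1_classII"})),
        MotifClass("PPLP", "PPLP", frozenset({"WW"})),
        MotifClass("{FL}PPPP", "{FL}PPPP", frozenset({"EVH1_classI"})),
    ]


def scan_motifs(
    sequence: str,
    registry: Sequence[MotifClass] | None = None,
    bait_id: str = "",
) -> list[MotifHit]:
    """Report every match of every registry motif at every start position.

    Overlapping and nested matches are all reported (poly-proline runs
    legitimately generate many PxxP instances); hits are sorted by
    (start, motif_name) and the scan is deterministic.
    """
    if registry is None:
        registry = default_registry()
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for motif in registry:
        m = len(motif)
        for s in range(len(seq) - m + 1):
            if motif.matches_at(seq, s):
                hits.append(MotifHit(bait_id, motif.name, s + 1, seq[s : s + m]))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def expected_domains(
    sequence_or_bait,
    registry: Sequence[MotifClass] | None = None,
) -> set[str]:
    """Union of expected domain classes over motifs present in the bait.

    Accepts either a raw sequence or any object with a ``sequence``
    attribute.  Motif-free baits yield the empty set.
    """
    if registry is None:
        registry = default_registry()
    sequence = getattr(sequence_or_bait, "sequence", sequence_or_bait)
    bait_id = getattr(sequence_or_bait, "id", "")
    hit_names = {h.motif_name for h in scan_motifs(sequence, registry, bait_id)}
    out: set[str] = set()
    for motif in registry:
        if motif.name in hit_names:
            out |= motif.expected_domains
    return out


def read_registry(path) -> list[MotifClass]:
    """Load a motif registry from TSV (motif_name, pattern, expected_domains)."""
    registry = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"motif_name", "pattern", "expected_domains"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"registry TSV must have columns {sorted(required)}")
        for row in reader:
            domains = frozenset(d.strip() for d in row["expected_domains"].split(",") if d.strip())
            registry.append(MotifClass(row["motif_name"], row["pattern"], domains))
    return registry


def write_registry(registry: Iterable[MotifClass], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["motif_name", "pattern", "expected_domains"])
        for m in registry:
            writer.writerow([m.name, m.pattern, ",".join(sorted(m.expected_domains))])
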