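"""Design of positional crosslinker-substitution peptide arrays.

Each bait peptide is expanded into a series of array spots in which the
photo-activatable crosslinker p-benzoyl-L-phenylalanine (pBpa) replaces one
residue per spot, so that at least one spot places the crosslinker at a
position permissive for binding without prior knowledge of the binding
register.  An unmodified spot is appended as an on-membrane control.  Spots
are laid out row-major on SPOT-synthesis membranes of 24 columns x 16 rows
(384 spots), up to 4 membranes per run.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .motif_domain import AMINO_ACIDS, MotifHit

__all__ = [
    "BaitPeptide",
    "DesignProfile",
    "ArraySpot",
    "design_substitution_series",
    "even_spread_positions",
    "annotate_motif_overlap",
    "layout_membranes",
    "export_array",
    "read_array",
    "write_bait_fasta",
    "read_bait_fasta",
]

RECOMMENDED_LENGTH = (14, 18)


class InvalidBaitError(ValueError):
    """Raised for bait peptides that cannot be arrayed."""


class CapacityExceededError(ValueError):
    """Raised when a spot list exceeds the available membrane capacity."""


@dataclass(frozen=True)
class BaitPeptide:
    """A named bait peptide with optional source-protein metadata."""

    id: str
    sequence: str
    source_protein: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id:
            raise InvalidBaitError("bait id must be non-empty")
        if not self.sequence:
            raise InvalidBaitError(f"bait {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise InvalidBaitError(
                f"bait {self.id!r}: non-standard residues {sorted(bad)}"
            )
        lo, hi = RECOMMENDED_LENGTH
        if not lo <= len(self.sequence) <= hi:
            warnings.warn(
                f"bait {self.id!r} has length {len(self.sequence)}, outside the "
                f"recommended {lo}-{hi}-mer range for SPOT synthesis",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DesignProfile:
    """Array-design knobs: spot budget per bait and crosslinker tokens."""

    spot_budget: int = 12
    include_unmodified: bool = True
    crosslinker_token: str = "[Bpa]"
    internal_symbol: str = "@"

    def __post_init__(self) -> None:
        if self.spot_budget < 1:
            raise ValueError("spot_budget must be >= 1")
        if len(self.internal_symbol) != 1 or self.internal_symbol in AMINO_ACIDS:
            raise ValueError(
                "internal_symbol must be a single character outside the 20 "
                "standard amino-acid letters"
            )


@dataclass(frozen=True)
class ArraySpot:
    """One synthesized peptide variant.

    ``crosslinker_position`` is the 1-based substituted residue index, or 0
    for the unmodified control spot.  ``grid`` is (membrane, row, column)
    once the membrane layout is assigned.
    """

    bait_id: str
    variant_sequence: str
    crosslinker_position: int
    motif_overlap: bool = False
    grid: tuple[int, int, int] | None = None


def even_spread_positions(length: int, budget: int) -> list[int]:
    """Choose ``budget`` substitution positions spread evenly over 1..length.

    p_i = 1 + round((i-1)(L-1)/(k-1)), rounding half away from zero, with
    duplicates removed and the smallest unused positions appended until the
    budget is filled.  Always includes both termini when budget >= 2.
    """
    if budget >= length:
        return list(range(1, length + 1))
    if budget == 1:
        return [1]
    chosen: list[int] = []
    seen: set[int] = set()
    for i in range(1, budget + 1):
        x = (i - 1) * (length - 1) / (budget - 1)
        p = 1 + int(x + 0.5)  # round half away from zero (x >= 0)
        if p not in seen:
            seen.add(p)
            chosen.append(p)
    fill = 1
    while len(chosen) < budget:
        while fill in seen:
            fill += 1
        seen.add(fill)
        chosen.append(fill)
    return sorted(chosen)


def design_substitution_series(
    bait: BaitPeptide,
    profile: DesignProfile | None = None,
    positions: Sequence[int] | None = None,
) -> list[ArraySpot]:
    """Expand a bait into its positional-substitution spot series.

    One substituted spot per selected position (even-spread rule when the
    budget is below the peptide length; an explicit ``positions`` list
    overrides the rule), ordered by increasing crosslinker position, with
    the unmodified spot appended last when the profile asks for it.
    """
    if profile is None:
        profile = DesignProfile()
    if positions is None:
        positions = even_spread_positions(len(bait), profile.spot_budget)
    else:
        positions = sorted(set(int(p) for p in positions))
        if any(p < 1 or p > len(bait) for p in positions):
            raise ValueError("explicit positions must lie within the bait sequence")
    spots = []
    for p in positions:
        variant = bait.sequence[: p - 1] + profile.internal_symbol + bait.sequence[p:]
        spots.append(ArraySpot(bait.id, variant, p))
    if profile.include_unmodified:
        spots.append(ArraySpot(bait.id, bait.sequence, 0))
    return spots


def annotate_motif_overlap(
    spots: Sequence[ArraySpot], hits: Sequence[MotifHit]
) -> list[ArraySpot]:
    """Flag spots whose substituted residue falls inside a motif match.

    Such substitutions are expected to abolish the motif-mediated
    interaction, so the flag marks spots likely to lose binding.  The
    unmodified spot is always False.
    """
    bait_ids = {s.bait_id for s in spots}
    foreign = {h.bait_id for h in hits if h.bait_id} - bait_ids
    if foreign:
        raise ValueError(f"motif hits refer to other baits: {sorted(foreign)}")
    out = []
    for spot in spots:
        p = spot.crosslinker_position
        overlap = p > 0 and any(h.start <= p <= h.end for h in hits)
        out.append(replace(spot, motif_overlap=overlap))
    return out


def layout_membranes(
    spots: Sequence[ArraySpot],
    columns: int = 24,
    rows: int = 16,
    max_membranes: int = 4,
) -> list[ArraySpot]:
    """Assign (membrane, row, column) grid coordinates, row-major.

    The column index varies fastest; membrane 1 fills completely before
    membrane 2.  Capacity is columns x rows per membrane.
    """
    capacity = columns * rows * max_membranes
    if not spots:
        raise ValueError("no spots to lay out")
    if len(spots) > capacity:
        raise CapacityExceededError(
            f"{len(spots)} spots exceed the capacity of {max_membranes} "
            f"membranes of {columns}x{rows} = {capacity} spots"
        )
    per_membrane = columns * rows
    out = []
    for idx, spot in enumerate(spots):
        membrane = idx // per_membrane + 1
        within = idx % per_membrane
        out.append(replace(spot, grid=(membrane, within // columns + 1, within % columns + 1)))
    return out


def _display_sequence(spot: ArraySpot, profile: DesignProfile) -> str:
    return spot.variant_sequence.replace(profile.internal_symbol, profile.crosslinker_token)


def export_array(
    spots: Sequence[ArraySpot],
    tsv_path,
    fasta_path=None,
    profile: DesignProfile | None = None,
    strict_fasta: bool = False,
) -> None:
    """Write the synthesis sheet (TSV) and optionally variant FASTA.

    TSV columns: bait_id, membrane, row, column, crosslinker_position,
    motif_overlap, sequence (crosslinker shown as the display token).
    FASTA headers are ``baitid|posN``; in strict mode the internal
    crosslinker symbol on the sequence line is replaced by ``X`` with a
    warning, otherwise it is written as-is for lossless round-trips.
    """
    if profile is None:
        profile = DesignProfile()
    unassigned = [s for s in spots if s.grid is None]
    if unassigned:
        raise ValueError("cannot export: spots without grid assignment (run layout_membranes)")
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["bait_id", "membrane", "row", "column", "crosslinker_position", "motif_overlap", "sequence"]
        )
        for s in spots:
            m, r, c = s.grid
            writer.writerow(
                [s.bait_id, m, r, c, s.crosslinker_position, str(s.motif_overlap).lower(), _display_sequence(s, profile)]
            )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for s in spots:
                seq = s.variant_sequence
                if strict_fasta and profile.internal_symbol in seq:
                    warnings.warn(
                        "strict FASTA: crosslinker symbol replaced by 'X' on the sequence line",
                        stacklevel=2,
                    )
                    seq = seq.replace(profile.internal_symbol, "X")
                fh.write(f">{s.bait_id}|pos{s.crosslinker_position} {_display_sequence(s, profile)}\n{seq}\n")


def read_array(tsv_path, profile: DesignProfile | None = None) -> list[ArraySpot]:
    """Re-read a synthesis sheet written by :func:`export_array`."""
    if profile is None:
        profile = DesignProfile()
    spots = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            variant = row["sequence"].replace(profile.crosslinker_token, profile.internal_symbol)
            spots.append(
                ArraySpot(
                    bait_id=row["bait_id"],
                    variant_sequence=variant,
                    crosslinker_position=int(row["crosslinker_position"]),
                    motif_overlap=row["motif_overlap"] == "true",
                    grid=(int(row["membrane"]), int(row["row"]), int(row["column"])),
                )
            )
    return spots


def write_bait_fasta(baits: Iterable[BaitPeptide], path) -> None:
    with open(path, "w") as fh:
        for b in baits:
            desc = f" {b.source_protein}" if b.source_protein else ""
            fh.write(f">{b.id}{desc}\n{b.sequence}\n")


def read_bait_fasta(path) -> list[BaitPeptide]:
    """Read bait peptides from FASTA (Biopython-backed)."""
    from Bio import SeqIO

    baits = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            baits.append(BaitPeptide(rec.id, str(rec.seq), source_protein=rec.description.partition(" ")[2]))
    return baits
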