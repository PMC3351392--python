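"""High-confidence interaction calling: control elimination + domain filtering.

Two complementary analyses select high-confidence peptide-protein
interactions from the normalized count matrix:

1. Cluster analysis of single-bait interactors (``paxms.clustering``) — the
   other baits serve as internal negative controls.
2. Domain filtering — proteins associated with the motif-free control
   peptide are eliminated, and the remainder are kept only when they carry
   an interaction-domain class expected from the bait's consensus motifs.

The union of both evidence streams is the final call set.  A known-pair
table (exported from whatever interaction database the user prefers) can
flag previously reported interactions.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .array_design import BaitPeptide
from .identifications import CountMatrix
from .motif_domain import MotifHit

__all__ = [
    "InteractionCall",
    "drop_control_binders",
    "domain_filter",
    "combine_evidence",
    "annotate_known",
    "report",
    "read_domain_annotations",
    "write_domain_annotations",
    "read_known_pairs",
    "calls_from_clusters",
]

logger = logging.getLogger(__name__)

EVIDENCE_KINDS = ("single_bait_cluster", "domain_filter")


@dataclass(frozen=True)
class InteractionCall:
    """A called (bait, prey) interaction with its evidence labels."""

    bait_id: str
    protein: str
    evidence: frozenset[str]
    matched_domains: frozenset[str] = frozenset()
    known: bool = False
    mean_count: float = 0.0

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("an interaction call requires at least one evidence label")
        bad = set(self.evidence) - set(EVIDENCE_KINDS)
        if bad:
            raise ValueError(f"unknown evidence labels: {sorted(bad)}")
        has_domains = bool(self.matched_domains)
        if has_domains != ("domain_filter" in self.evidence):
            raise ValueError("matched_domains must be non-empty iff domain_filter evidence present")


def drop_control_binders(
    m: CountMatrix, control_bait: str, tau: float = 0.0
) -> CountMatrix:
    """Eliminate every protein with control-peptide signal above ``tau``.

    The control column itself is removed from the result.  Any control
    association disqualifies a protein at the default threshold, the strict
    stance toward non-specific binders.
    """
    if m.stage != "replicate_mean":
        raise ValueError(f"drop_control_binders expects replicate_mean, got {m.stage!r}")
    if control_bait not in m.data.columns:
        raise ValueError(f"control bait {control_bait!r} has no column in the matrix")
    keep = m.data[control_bait] <= tau
    trimmed = m.data.loc[keep].drop(columns=[control_bait])
    return CountMatrix(trimmed, "replicate_mean")


def domain_filter(
    m: CountMatrix,
    annotations: Mapping[str, set[str] | frozenset[str]],
    expected: Mapping[str, set[str] | frozenset[str]],
    tau: float = 0.0,
) -> list[InteractionCall]:
    """Call (bait, prey) pairs where signal and expected domains agree.

    A call is emitted iff the prey's mean count for the bait exceeds
    ``tau`` and the prey carries at least one domain class expected from
    the bait's motifs; the matched intersection is recorded.  A protein may
    be called for several baits.  Proteins absent from the annotation table
    are treated as domain-free and logged.
    """
    if m.stage != "replicate_mean":
        raise ValueError(f"domain_filter expects replicate_mean, got {m.stage!r}")
    calls: list[InteractionCall] = []
    unannotated = [p for p in m.proteins if p not in annotations]
    if unannotated:
        logger.info(
            "%d protein(s) missing from the domain annotation table, treated as domain-free: %s",
            len(unannotated), unannotated,
        )
    for bait in m.data.columns:
        exp = frozenset(expected.get(bait, frozenset()))
        if not exp:
            continue
        col = m.data[bait]
        for protein, value in col.items():
            if value <= tau:
                continue
            matched = frozenset(annotations.get(protein, frozenset())) & exp
            if matched:
                calls.append(
                    InteractionCall(
                        bait_id=str(bait),
                        protein=str(protein),
                        evidence=frozenset({"domain_filter"}),
                        matched_domains=matched,
                        mean_count=float(value),
                    )
                )
    return calls


def calls_from_clusters(
    clusters: Sequence[tuple[str, Sequence[str]]],
    m: CountMatrix | None = None,
) -> list[InteractionCall]:
    """Turn bait-pure clusters into single-bait-cluster interaction calls."""
    calls = []
    for bait, proteins in clusters:
        for protein in proteins:
            mean = 0.0
            if m is not None and protein in m.data.index and bait in m.data.columns:
                mean = float(m.data.at[protein, bait])
            calls.append(
                InteractionCall(
                    bait_id=bait,
                    protein=protein,
                    evidence=frozenset({"single_bait_cluster"}),
                    mean_count=mean,
                )
            )
    return calls


def combine_evidence(
    cluster_calls: Iterable[InteractionCall],
    domain_calls: Iterable[InteractionCall],
) -> list[InteractionCall]:
    """Union of the two analyses keyed by (bait, protein), evidence merged."""
    merged: dict[tuple[str, str], InteractionCall] = {}
    for call in list(cluster_calls) + list(domain_calls):
        key = (call.bait_id, call.protein)
        if key not in merged:
            merged[key] = call
        else:
            prev = merged[key]
            merged[key] = InteractionCall(
                bait_id=call.bait_id,
                protein=call.protein,
                evidence=prev.evidence | call.evidence,
                matched_domains=prev.matched_domains | call.matched_domains,
                known=prev.known or call.known,
                mean_count=max(prev.mean_count, call.mean_count),
            )
    return list(merged.values())


def annotate_known(
    calls: Iterable[InteractionCall],
    known_pairs: Iterable[tuple[str, str]],
) -> list[InteractionCall]:
    """Flag calls whose (bait source, prey) pair appears in a known-pair table.

    Matching is case-insensitive and order-insensitive on the pair.
    """
    pairs = {frozenset((a.lower(), b.lower())) for a, b in known_pairs}
    out = []
    for call in calls:
        key = frozenset((call.bait_id.lower(), call.protein.lower()))
        out.append(replace(call, known=key in pairs))
    return out


def report(
    calls: Sequence[InteractionCall],
    baits: Sequence[BaitPeptide],
    motif_hits: Mapping[str, Sequence[MotifHit]],
    expected: Mapping[str, set[str] | frozenset[str]],
) -> tuple[pd.DataFrame, dict]:
    """Bait-by-bait summary table plus JSON-ready totals.

    One row per bait: peptide, motifs found, expected domains, called prey
    with evidence and known flags.  Totals count distinct prey proteins,
    distinct (bait, protein) interactions, and known interactions.
    """
    by_bait: dict[str, list[InteractionCall]] = {}
    for call in calls:
        by_bait.setdefault(call.bait_id, []).append(call)
    rows = []
    for bait in baits:
        bait_calls = sorted(by_bait.get(bait.id, []), key=lambda c: (-c.mean_count, c.protein))
        hits = motif_hits.get(bait.id, [])
        motif_names = sorted({h.motif_name for h in hits})
        prey_parts = []
        for c in bait_calls:
            tags = sorted(c.evidence)
            if c.known:
                tags.append("known")
            prey_parts.append(f"{c.protein}[{';'.join(tags)}]")
        rows.append(
            {
                "bait_id": bait.id,
                "peptide": bait.sequence,
                "motifs_found": ",".join(motif_names),
                "expected_domains": ",".join(sorted(expected.get(bait.id, set()))),
                "prey": ",".join(prey_parts),
            }
        )
    table = pd.DataFrame(rows, columns=["bait_id", "peptide", "motifs_found", "expected_domains", "prey"])
    distinct_pairs = {(c.bait_id, c.protein) for c in calls}
    summary = {
        "n_proteins": len({c.protein for c in calls}),
        "n_interactions": len(distinct_pairs),
        "n_known": len({(c.bait_id, c.protein) for c in calls if c.known}),
    }
    return table, summary


def read_domain_annotations(path) -> dict[str, frozenset[str]]:
    """Read a protein -> domain-set table (TSV: protein, comma-separated domains)."""
    out: dict[str, frozenset[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"protein", "domains"} <= set(reader.fieldnames):
            raise ValueError("domain annotation TSV needs columns: protein, domains")
        for row in reader:
            domains = frozenset(d.strip() for d in row["domains"].split(",") if d.strip())
            out[row["protein"].strip()] = domains
    return out


def write_domain_annotations(annotations: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein", "domains"])
        for protein in sorted(annotations):
            writer.writerow([protein, ",".join(sorted(annotations[protein]))])


def read_known_pairs(path) -> list[tuple[str, str]]:
    """Read a known-interaction pair table (TSV: bait_protein, prey_protein)."""
    pairs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"bait_protein", "prey_protein"} <= set(reader.fieldnames):
            raise ValueError("known-pair TSV needs columns: bait_protein, prey_protein")
        for row in reader:
            pairs.append((row["bait_protein"].strip(), row["prey_protein"].strip()))
    return pairs
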