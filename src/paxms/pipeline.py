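"""End-to-end orchestration: scan -> normalize -> cluster -> filter -> report.

``run_all`` executes the computational tail of a PAX experiment from the
identification table onward, writing every intermediate artifact plus a
manifest of content hashes so that re-runs on identical inputs are
verifiably identical.  ``validate_inputs`` checks the input files against
the schemas and cross-references before anything runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import array_design, clustering, identifications, interaction_filter, motif_domain

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Finding", "run_all", "validate_inputs"]

RECOMMENDED_LENGTH = array_design.RECOMMENDED_LENGTH


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    baits: str
    ids: str
    domains: str
    out_dir: str
    control_bait: str = "Control"
    known_pairs: str | None = None
    registry: str | None = None
    tau_association: float = 0.0
    tau_control: float = 0.0
    linkage: str = "average"
    fdr_convention: str = "d_over_t"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class Finding:
    """One validation finding: ``level`` is 'error' or 'warning'."""

    level: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.message}"


def validate_inputs(cfg: PipelineConfig) -> list[Finding]:
    """Check schemas and cross-references of every configured input."""
    findings: list[Finding] = []

    def err(msg: str) -> None:
        findings.append(Finding("error", msg))

    def warn(msg: str) -> None:
        findings.append(Finding("warning", msg))

    bait_ids: set[str] = set()
    if not Path(cfg.baits).exists():
        err(f"bait file not found: {cfg.baits}")
    else:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                baits = array_design.read_bait_fasta(cfg.baits)
            for w in caught:
                warn(str(w.message))
            bait_ids = {b.id for b in baits}
            lo, hi = RECOMMENDED_LENGTH
            for b in baits:
                if not lo <= len(b) <= hi:
                    warn(f"bait {b.id!r} length {len(b)} outside the recommended {lo}-{hi} range")
            if cfg.control_bait not in bait_ids:
                err(f"control bait {cfg.control_bait!r} absent from the bait file")
        except Exception as exc:  # malformed FASTA / invalid bait
            err(f"bait file unreadable: {exc}")

    if not Path(cfg.ids).exists():
        err(f"identification file not found: {cfg.ids}")
    else:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                records = identifications.read_identifications(cfg.ids)
            for w in caught:
                warn(str(w.message))
            if bait_ids:
                unknown_rows = [
                    i + 2 for i, r in enumerate(records) if r.bait_id not in bait_ids
                ]
                if unknown_rows:
                    err(
                        f"identification rows citing unknown baits at line(s) "
                        f"{unknown_rows[:20]}{'...' if len(unknown_rows) > 20 else ''}"
                    )
        except ValueError as exc:
            err(f"identification table: {exc}")

    if not Path(cfg.domains).exists():
        err(f"domain annotation file not found: {cfg.domains}")
    else:
        try:
            interaction_filter.read_domain_annotations(cfg.domains)
        except ValueError as exc:
            err(f"domain annotation table: {exc}")

    if cfg.known_pairs is not None:
        if not Path(cfg.known_pairs).exists():
            err(f"known-pair file not found: {cfg.known_pairs}")
        else:
            try:
                interaction_filter.read_known_pairs(cfg.known_pairs)
            except ValueError as exc:
                err(f"known-pair table: {exc}")

    if cfg.registry is not None and not Path(cfg.registry).exists():
        err(f"motif registry not found: {cfg.registry}")
    if cfg.linkage not in clustering.LINKAGES:
        err(f"unknown linkage {cfg.linkage!r}")
    return findings


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Run scan -> normalize -> cluster -> filter -> combine -> report.

    Writes motifs.tsv, matrices at every stage, the .cdt/.gtr pair, the
    cluster report, the interaction report and summary.json under
    ``cfg.out_dir``, plus manifest.json listing each artifact's sha256.
    Re-running on identical inputs reproduces identical hashes (the
    timestamped run.log is excluded from the manifest).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("paxms")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: list[Path] = []
    try:
        root.info("pipeline start; config=%s", json.dumps(asdict(cfg), sort_keys=True))

        stage = "validate"
        findings = validate_inputs(cfg)
        for f in findings:
            (root.warning if f.level == "warning" else root.error)("%s", f)
        errors = [f for f in findings if f.level == "error"]
        if errors:
            raise StageError(stage, ValueError("; ".join(f.message for f in errors)))

        stage = "scan"
        try:
            baits = array_design.read_bait_fasta(cfg.baits)
            registry = (
                motif_domain.read_registry(cfg.registry)
                if cfg.registry
                else motif_domain.default_registry()
            )
            hits = {b.id: motif_domain.scan_motifs(b.sequence, registry, b.id) for b in baits}
            expected = {b.id: motif_domain.expected_domains(b, registry) for b in baits}
            motifs_path = out / "motifs.tsv"
            with open(motifs_path, "w", newline="") as fh:
                fh.write("bait_id\tmotif_name\tstart\tmatch\n")
                for b in baits:
                    for h in hits[b.id]:
                        fh.write(f"{h.bait_id}\t{h.motif_name}\t{h.start}\t{h.match}\n")
            artifacts.append(motifs_path)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc)

        stage = "normalize"
        try:
            records = [r for r in identifications.read_identifications(cfg.ids) if not r.decoy]
            raw = identifications.build_matrix(records)
            qv = identifications.quantitative_values(raw)
            pct = identifications.percent_of_total(qv)
            mean = identifications.mean_across_replicates(pct)
            mean_path = out / "mean_matrix.tsv"
            mean.to_tsv(mean_path)
            artifacts.append(mean_path)
            root.info("normalized %d proteins x %d samples", len(raw.proteins), len(raw.samples))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc)

        stage = "cluster"
        try:
            assignment = clustering.single_bait_interactors(mean, tau=cfg.tau_association)
            single = mean.data.loc[[p for p in mean.proteins if p in assignment]]
            cluster_calls: list[interaction_filter.InteractionCall] = []
            clusters: list[tuple[str, list[str]]] = []
            if len(single) >= 2:
                sub = identifications.CountMatrix(single, "replicate_mean")
                labels, dist = clustering.distance_matrix(sub)
                dend = clustering.hierarchical_cluster(dist, linkage=cfg.linkage, labels=labels)
                clusters = clustering.bait_pure_clusters(dend, assignment)
                clustering.write_cdt_gtr(sub, dend, out / "single_bait")
                artifacts += [out / "single_bait.cdt", out / "single_bait.gtr"]
            elif len(single) == 1:
                protein = single.index[0]
                clusters = [(assignment[protein], [protein])]
            # clusters of control-specific proteins are not interaction evidence
            interactor_clusters = [c for c in clusters if c[0] != cfg.control_bait]
            cluster_calls = interaction_filter.calls_from_clusters(interactor_clusters, mean)
            clusters_path = out / "clusters.tsv"
            with open(clusters_path, "w", newline="") as fh:
                fh.write("cluster_id\tbait_id\tprotein\n")
                for idx, (bait, proteins) in enumerate(clusters, start=1):
                    for p in proteins:
                        fh.write(f"{idx}\t{bait}\t{p}\n")
            artifacts.append(clusters_path)
            root.info("single-bait interactors: %d; bait-pure clusters: %d",
                      len(assignment), len(clusters))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc)

        stage = "filter"
        try:
            annotations = interaction_filter.read_domain_annotations(cfg.domains)
            control_free = interaction_filter.drop_control_binders(
                mean, cfg.control_bait, tau=cfg.tau_control
            )
            domain_calls = interaction_filter.domain_filter(
                control_free, annotations, expected, tau=cfg.tau_association
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc)

        stage = "combine"
        try:
            calls = interaction_filter.combine_evidence(cluster_calls, domain_calls)
            if cfg.known_pairs:
                pairs = interaction_filter.read_known_pairs(cfg.known_pairs)
                calls = interaction_filter.annotate_known(calls, pairs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc)

        stage = "report"
        try:
            table, summary = interaction_filter.report(calls, baits, hits, expected)
            report_path = out / "report.tsv"
            table.to_csv(report_path, sep="\t", index=False, lineterminator="\n")
            summary_path = out / "summary.json"
            with open(summary_path, "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
                fh.write("\n")
            artifacts += [report_path, summary_path]
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc)

        manifest = {
            "config": asdict(cfg),
            "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
            "summary": summary,
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        root.info("pipeline done; %d artifact(s)", len(artifacts))
        return manifest
    except StageError as exc:
        root.error("halted at stage %r: %s (partial outputs flagged: %s)",
                   exc.stage, exc.cause, [p.name for p in artifacts])
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
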