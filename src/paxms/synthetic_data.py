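"""Seeded synthetic PAX-MS experiments with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
proteins x (bait, replicate) spectral-count matrix in which

* *specific* interactors bind exactly one motif-bearing bait and carry a
  domain from that bait's expected set (the planted positives);
* *sticky* background proteins are highly abundant and bind every strip,
  including the motif-free control — the non-specific binders both filters
  must reject;
* *multibait* proteins bind two baits through two different domains
  (the Itsn1-style case the domain filter is designed to keep);
* *decoy-domain* proteins carry an expected domain but never bind — probes
  that the filter must not call on annotation alone.

Counts are Poisson with rate lambda = abundance x binding strength, so the
~3-orders-of-magnitude abundance spread of a tissue lysate and the
interaction strength are separable; per-replicate dropout models the
stochastic sampling of data-dependent MS acquisition that motivates n = 2
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .array_design import BaitPeptide, write_bait_fasta
from .baits import CONTROL_BAIT_ID, bait_panel
from .identifications import IdentificationRecord
from .interaction_filter import write_domain_annotations
from .motif_domain import default_registry, expected_domains

__all__ = [
    "SimulationConfig",
    "TruthEntry",
    "SimulatedExperiment",
    "simulate_experiment",
    "write_experiment",
    "simulate_peptide_responses",
    "simulate_target_decoy",
    "CALIBRANT_ID",
]

CALIBRANT_ID = "ADH1_YEAST"
CALIBRANT_AMOUNT = 50.0  # fmol per ug lysate, the spike-in level

# Non-expected "housekeeping" domain labels for background proteins.
_BACKGROUND_DOMAINS = ("WD40", "coiled_coil", "TBC", "ANK")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic experiment generator.

    Defaults reproduce the reference design: 4 motif-bearing baits plus a
    motif-free control, 3-8 specific interactors per bait, 13 promiscuous
    sticky background proteins (the observed count of highly abundant
    control-peptide binders), 2 multibait proteins, n = 2 replicates,
    abundances spanning 3 orders of magnitude and 10% per-replicate
    dropout.
    """

    seed: int = 1
    n_baits: int = 4
    interactors_per_bait: tuple[int, int] = (3, 8)
    n_sticky: int = 13
    n_multibait: int = 2
    n_decoy_domain: int = 5
    replicates: int = 2
    abundance_log10_range: float = 3.0
    dropout_prob: float = 0.1
    # log10 binding-strength windows (lambda = abundance * strength)
    specific_strength_log10: tuple[float, float] = (0.7, 1.5)
    sticky_strength_log10: tuple[float, float] = (-1.0, -0.3)
    sticky_abundance_log10: tuple[float, float] = (2.0, 3.0)
    peptide_noise_sigma: float = 0.25
    peptides_per_protein: tuple[int, int] = (2, 12)

    def __post_init__(self) -> None:
        if self.n_baits < 1:
            raise ValueError("need at least one motif-bearing bait")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.abundance_log10_range < 0:
            raise ValueError("abundance range must be >= 0")
        if min(self.n_sticky, self.n_multibait, self.n_decoy_domain) < 0:
            raise ValueError("protein counts must be non-negative")


@dataclass(frozen=True)
class TruthEntry:
    """Planted ground truth for one simulated protein."""

    protein: str
    role: str  # specific | sticky | multibait | decoy_domain
    true_baits: frozenset[str]
    domains: frozenset[str]
    abundance: float


@dataclass(frozen=True)
class SimulatedExperiment:
    """In-memory synthetic experiment: baits, records, annotations, truth."""

    config: SimulationConfig
    baits: tuple[BaitPeptide, ...]
    control_bait: str
    records: tuple[IdentificationRecord, ...]
    domain_annotations: dict[str, frozenset[str]]
    truth: dict[str, TruthEntry]

    def specific_proteins(self) -> list[str]:
        return [p for p, t in self.truth.items() if t.role == "specific"]

    def sticky_proteins(self) -> list[str]:
        return [p for p, t in self.truth.items() if t.role == "sticky"]


def _select_baits(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[list[BaitPeptide], BaitPeptide]:
    """The packaged motif-bearing baits (extended with random motif-carrier
    peptides when more baits are requested than the panel provides) plus the
    control."""
    panel = bait_panel()
    control = next(b for b in panel if b.id == CONTROL_BAIT_ID)
    motif_baits = [b for b in panel if b.id != CONTROL_BAIT_ID]
    if cfg.n_baits <= len(motif_baits):
        return motif_baits[: cfg.n_baits], control
    extra = []
    letters = np.array(list("ACDEGHIKQRSTV"))  # avoid accidental motif residues
    for i in range(cfg.n_baits - len(motif_baits)):
        core = "".join(rng.choice(letters, size=12))
        seq = core[:4] + "PPLP" + core[4:]  # plant a WW-class motif
        extra.append(BaitPeptide(f"SYN{i + 1}", seq, source_protein="synthetic bait"))
    return motif_baits + extra, control


def simulate_experiment(cfg: SimulationConfig) -> SimulatedExperiment:
    """Generate one seeded synthetic PAX-MS experiment.

    Deterministic under a fixed config (single numpy Generator seeded from
    ``cfg.seed``).  Specific interactors draw counts only for their bait;
    sticky proteins draw counts for every bait including the control;
    decoy-domain proteins produce no records at all.
    """
    rng = np.random.default_rng(cfg.seed)
    registry = default_registry()
    motif_baits, control = _select_baits(cfg, rng)
    all_baits = motif_baits + [control]
    expected = {b.id: expected_domains(b, registry) for b in motif_baits}

    truth: dict[str, TruthEntry] = {}
    rates: dict[str, dict[str, float]] = {}  # protein -> bait -> lambda

    lo_s, hi_s = cfg.specific_strength_log10
    for bait in motif_baits:
        n_spec = int(rng.integers(cfg.interactors_per_bait[0], cfg.interactors_per_bait[1] + 1))
        domains = sorted(expected[bait.id])
        for i in range(n_spec):
            name = f"SPEC_{bait.id}_{i + 1:02d}"
            abundance = 10.0 ** rng.uniform(0.0, cfg.abundance_log10_range)
            strength = 10.0 ** rng.uniform(lo_s, hi_s)
            domain = domains[int(rng.integers(len(domains)))]
            truth[name] = TruthEntry(name, "specific", frozenset({bait.id}),
                                     frozenset({domain}), abundance)
            rates[name] = {bait.id: abundance * strength}

    lo_k, hi_k = cfg.sticky_strength_log10
    lo_a, hi_a = cfg.sticky_abundance_log10
    for i in range(cfg.n_sticky):
        name = f"STICKY_{i + 1:02d}"
        abundance = 10.0 ** rng.uniform(lo_a, hi_a)
        # a minority of sticky proteins also carry an expected domain, so
        # control elimination (not annotation) must be what removes them
        if i < max(1, cfg.n_sticky // 4):
            domains = frozenset({"SH3"})
        else:
            domains = frozenset({_BACKGROUND_DOMAINS[i % len(_BACKGROUND_DOMAINS)]})
        truth[name] = TruthEntry(name, "sticky", frozenset(b.id for b in all_baits),
                                 domains, abundance)
        rates[name] = {
            b.id: abundance * 10.0 ** rng.uniform(lo_k, hi_k) for b in all_baits
        }

    multi_candidates = [b for b in motif_baits if expected[b.id]]
    for i in range(cfg.n_multibait):
        name = f"MULTI_{i + 1:02d}"
        if len(multi_candidates) >= 2:
            idx = rng.choice(len(multi_candidates), size=2, replace=False)
            pair = [multi_candidates[j] for j in sorted(idx)]
        else:
            pair = multi_candidates
        abundance = 10.0 ** rng.uniform(0.0, cfg.abundance_log10_range)
        domains = frozenset(
            sorted(expected[b.id])[int(rng.integers(len(expected[b.id])))] for b in pair
        )
        truth[name] = TruthEntry(name, "multibait", frozenset(b.id for b in pair),
                                 domains, abundance)
        rates[name] = {
            b.id: abundance * 10.0 ** rng.uniform(lo_s, hi_s) for b in pair
        }

    all_expected = sorted(set().union(*expected.values())) or ["SH3"] if expected else ["SH3"]
    for i in range(cfg.n_decoy_domain):
        name = f"DDOM_{i + 1:02d}"
        abundance = 10.0 ** rng.uniform(0.0, cfg.abundance_log10_range)
        domain = all_expected[i % len(all_expected)]
        truth[name] = TruthEntry(name, "decoy_domain", frozenset(), frozenset({domain}), abundance)
        # no rates: never observed

    records: list[IdentificationRecord] = []
    for name in truth:
        for bait_id, lam in rates.get(name, {}).items():
            for rep in range(1, cfg.replicates + 1):
                if rng.random() < cfg.dropout_prob:
                    continue
                count = int(rng.poisson(lam))
                if count <= 0:
                    continue
                uniq = max(1, min(count, 1 + int(rng.poisson(min(count, 6) / 2))))
                records.append(
                    IdentificationRecord(name, bait_id, rep, count, unique_peptides=uniq)
                )

    annotations = {p: t.domains for p, t in truth.items() if t.domains}
    return SimulatedExperiment(
        config=cfg,
        baits=tuple(all_baits),
        control_bait=control.id,
        records=tuple(records),
        domain_annotations=annotations,
        truth=truth,
    )


def write_experiment(exp: SimulatedExperiment, out_dir) -> dict[str, Path]:
    """Write ids.tsv, domains.tsv, baits.fasta and truth.tsv to ``out_dir``.

    Output is byte-identical across runs of the same config/seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "identifications": out / "ids.tsv",
        "domains": out / "domains.tsv",
        "baits": out / "baits.fasta",
        "truth": out / "truth.tsv",
    }
    with open(paths["identifications"], "w", newline="") as fh:
        fh.write("protein\tbait_id\treplicate\tspectral_count\tunique_peptides\tdecoy\n")
        for r in exp.records:
            fh.write(
                f"{r.protein}\t{r.bait_id}\t{r.replicate}\t{r.spectral_count}\t"
                f"{r.unique_peptides if r.unique_peptides is not None else ''}\t"
                f"{str(r.decoy).lower()}\n"
            )
    write_domain_annotations(exp.domain_annotations, paths["domains"])
    write_bait_fasta(exp.baits, paths["baits"])
    with open(paths["truth"], "w", newline="") as fh:
        fh.write("protein\trole\ttrue_baits\tdomains\tabundance\n")
        for name in sorted(exp.truth):
            t = exp.truth[name]
            fh.write(
                f"{t.protein}\t{t.role}\t{','.join(sorted(t.true_baits))}\t"
                f"{','.join(sorted(t.domains))}\t{t.abundance:.6g}\n"
            )
    return paths


def simulate_peptide_responses(
    cfg: SimulationConfig,
    truth: dict[str, TruthEntry],
    seed: int | None = None,
) -> list[tuple[str, str, float]]:
    """Per-protein peptide MS responses, log-normal around true abundance.

    Each protein yields 2-12 peptide responses r = abundance * exp(sigma*z);
    the spike-in calibrant is included with a fixed six-peptide complement
    at its known 50 fmol/ug level.  With sigma = 0 the Hi3 pipeline
    recovers every abundance exactly.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sigma = cfg.peptide_noise_sigma
    rows: list[tuple[str, str, float]] = []
    for i in range(6):
        rows.append((CALIBRANT_ID, f"{CALIBRANT_ID}_pep{i + 1}",
                     float(CALIBRANT_AMOUNT * np.exp(sigma * rng.standard_normal()))))
    lo, hi = cfg.peptides_per_protein
    for name in sorted(truth):
        t = truth[name]
        n_pep = int(rng.integers(lo, hi + 1))
        for j in range(n_pep):
            rows.append((name, f"{name}_pep{j + 1}",
                         float(t.abundance * np.exp(sigma * rng.standard_normal()))))
    return rows


def write_peptide_responses(rows, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("protein\tpeptide\tresponse\n")
        for protein, peptide, response in rows:
            fh.write(f"{protein}\t{peptide}\t{response:.8g}\n")


def simulate_target_decoy(
    cfg: SimulationConfig,
    true_fdr: float,
    n_psms: int = 10000,
    threshold: float = 5.0,
    seed: int | None = None,
) -> list[tuple[str, float, bool]]:
    """Scored PSM list against a concatenated target+decoy database.

    Correct matches score ~ N(8, 1) and are always targets; random matches
    score ~ U(0, 10) and hit the target and decoy halves with equal
    probability.  The random-match count is sized so that the decoy/target
    estimate at ``threshold`` equals ``true_fdr`` in expectation, within
    binomial error.  Returns (psm_id, score, is_decoy) tuples.
    """
    if not 0 <= true_fdr <= 1:
        raise ValueError("true_fdr must be in [0, 1]")
    if true_fdr >= 1:
        raise ValueError("true_fdr must be < 1 for a target-decoy simulation")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    # expected false targets above threshold f satisfies f = fdr * (n_correct + f)
    # random matches: P(above threshold) = 0.5, P(target) = 0.5 -> n_random = 4f
    if true_fdr == 0:
        n_random = 0
    else:
        f = true_fdr / (1.0 - true_fdr)
        n_random = int(round(4.0 * f * n_psms / (1.0 + 4.0 * f)))
    n_correct = n_psms - n_random
    psms: list[tuple[str, float, bool]] = []
    for i in range(n_correct):
        psms.append((f"PSM{i + 1}", float(rng.normal(8.0, 1.0)), False))
    for j in range(n_random):
        decoy = bool(rng.random() < 0.5)
        psms.append((f"PSM{n_correct + j + 1}", float(rng.uniform(0.0, 10.0)), decoy))
    return psms


def estimate_fdr_at(psms, threshold: float, convention: str = "d_over_t") -> float:
    """Target-decoy FDR estimate of a scored PSM list at a score threshold."""
    from .identifications import compute_fdr

    n_target = sum(1 for _, s, dec in psms if s >= threshold and not dec)
    n_decoy = sum(1 for _, s, dec in psms if s >= threshold and dec)
    return compute_fdr(n_target, n_decoy, convention)
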