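"""Spectral-count ingestion, normalization, FDR and Hi3 abundance estimation.

The clustering input is a proteins x (bait, replicate) spectral-count matrix
taken through three stages:

1. ``quantitative_values`` — first-pass normalization scaling each sample
   column to the average total spectral count across samples;
2. ``percent_of_total`` — each count expressed as a percentage of the total
   spectra observed in that sample (columns sum to 100);
3. ``mean_across_replicates`` — arithmetic mean over the replicates of each
   bait (n = 2 in the reference design), keyed by bait only.

Stages 1 and 2 commute in the sense that percent-of-total of the
quantitative values equals percent-of-total of the raw counts (per-column
rescaling cancels in the ratio), which makes the downstream analysis robust
to the exact first-pass normalization.

Also here: target-decoy FDR arithmetic and Hi3 (top-three peptide) label-free
quantitation calibrated against a spike-in standard.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IdentificationRecord",
    "CountMatrix",
    "AbundanceEstimate",
    "read_identifications",
    "build_matrix",
    "quantitative_values",
    "percent_of_total",
    "mean_across_replicates",
    "compute_fdr",
    "hi3_quantify",
    "absolute_quantity",
    "abundance_rank",
    "top_n_membership",
    "read_peptide_responses",
]

DECOY_PREFIXES = ("REV_", "DECOY_")

STAGES = ("raw", "quantitative_value", "percent_of_total", "replicate_mean")


@dataclass(frozen=True)
class IdentificationRecord:
    """One protein identification in one bait strip / replicate."""

    protein: str
    bait_id: str
    replicate: int
    spectral_count: int
    unique_peptides: int | None = None
    decoy: bool = False

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"{self.protein}: replicate must be >= 1")
        if self.spectral_count < 0:
            raise ValueError(f"{self.protein}: negative spectral count")
        if self.unique_peptides is not None:
            if self.unique_peptides < 0 or self.unique_peptides > self.spectral_count:
                raise ValueError(
                    f"{self.protein}: need spectral_count >= unique_peptides >= 0"
                )


@dataclass(frozen=True)
class CountMatrix:
    """Proteins x samples count matrix at a named pipeline stage.

    ``data`` rows are protein accessions.  For stages before replicate
    averaging, columns are a (bait_id, replicate) MultiIndex; after
    averaging they are keyed by bait only.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate protein rows")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample columns")

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def baits(self) -> list[str]:
        if self.stage == "replicate_mean":
            return list(self.data.columns)
        return list(dict.fromkeys(b for b, _ in self.data.columns))

    def values_for(self, protein: str) -> np.ndarray:
        return self.data.loc[protein].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        if self.stage == "replicate_mean":
            df.columns = [str(b) for b in df.columns]
        else:
            df.columns = [f"{b}|{r}" for b, r in df.columns]
        df.index.name = "protein"
        df.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path, stage: str) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="protein")
        if stage != "replicate_mean":
            cols = []
            for c in df.columns:
                bait, _, rep = str(c).rpartition("|")
                cols.append((bait, int(rep)))
            df.columns = pd.MultiIndex.from_tuples(cols, names=["bait", "replicate"])
        return cls(df, stage)


def read_identifications(source) -> list[IdentificationRecord]:
    """Read identification records from a TSV file or text stream.

    Required columns: protein, bait_id, replicate, spectral_count.
    Optional: unique_peptides, decoy.  When no decoy column is present the
    flag is parsed from the accession prefix (REV_ / DECOY_).  Malformed
    rows are skipped with a warning naming their line numbers.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(io.StringIO(source.read()), sep="\t", dtype=str, keep_default_na=False)
    required = {"protein", "bait_id", "replicate", "spectral_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"identification table missing required columns: {sorted(missing)}")
    records: list[IdentificationRecord] = []
    bad_lines: list[int] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        try:
            protein = row.protein.strip()
            if not protein:
                raise ValueError("empty accession")
            if "decoy" in df.columns:
                decoy = str(getattr(row, "decoy")).strip().lower() in ("true", "1", "yes")
            else:
                decoy = protein.upper().startswith(DECOY_PREFIXES)
            uniq = None
            if "unique_peptides" in df.columns:
                raw = str(getattr(row, "unique_peptides")).strip()
                uniq = int(raw) if raw else None
            records.append(
                IdentificationRecord(
                    protein=protein,
                    bait_id=row.bait_id.strip(),
                    replicate=int(row.replicate),
                    spectral_count=int(row.spectral_count),
                    unique_peptides=uniq,
                    decoy=decoy,
                )
            )
        except (ValueError, TypeError):
            bad_lines.append(line_no)
    if bad_lines:
        warnings.warn(
            f"skipped {len(bad_lines)} malformed identification row(s) at line(s) {bad_lines}",
            stacklevel=2,
        )
    return records


def build_matrix(records: Sequence[IdentificationRecord]) -> CountMatrix:
    """Pivot records into a raw proteins x (bait, replicate) count matrix.

    Decoy records must be filtered out first.  Missing cells are zero;
    duplicate (protein, bait, replicate) rows are summed with a warning.
    """
    decoys = [r.protein for r in records if r.decoy]
    if decoys:
        raise ValueError(
            f"decoy records present ({len(decoys)}); filter them before building the matrix"
        )
    if not records:
        return CountMatrix(pd.DataFrame(index=pd.Index([], name="protein"),
                                        columns=pd.MultiIndex.from_tuples([], names=["bait", "replicate"])),
                           "raw")
    df = pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "bait": [r.bait_id for r in records],
            "replicate": [r.replicate for r in records],
            "count": [r.spectral_count for r in records],
        }
    )
    n_cells = df.groupby(["protein", "bait", "replicate"], sort=False).size()
    if (n_cells > 1).any():
        dup = n_cells[n_cells > 1]
        warnings.warn(
            f"summed {int(dup.sum() - len(dup))} duplicate identification row(s)",
            stacklevel=2,
        )
    # preserve first-appearance order of proteins and samples
    proteins = list(dict.fromkeys(df["protein"]))
    samples = list(dict.fromkeys(zip(df["bait"], df["replicate"])))
    wide = df.pivot_table(index="protein", columns=["bait", "replicate"], values="count",
                          aggfunc="sum", fill_value=0)
    wide = wide.reindex(index=proteins, columns=pd.MultiIndex.from_tuples(samples, names=["bait", "replicate"]),
                        fill_value=0)
    return CountMatrix(wide.astype(float), "raw")


def quantitative_values(m: CountMatrix) -> CountMatrix:
    """First-pass normalization: scale each sample to the mean column total.

    Column scale factor = (mean of all column totals) / (own column total);
    all-zero columns are left at zero with a warning.
    """
    if m.stage != "raw":
        raise ValueError(f"quantitative_values expects a raw matrix, got {m.stage!r}")
    totals = m.data.sum(axis=0)
    if len(totals) == 0 or len(m.data) == 0:
        return CountMatrix(m.data.copy(), "quantitative_value")
    mean_total = totals.mean()
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample column(s) have zero total spectra; left unscaled",
            stacklevel=2,
        )
    factors = np.where(zero, 0.0, mean_total / totals.replace(0, np.nan))
    scaled = m.data * factors
    return CountMatrix(scaled, "quantitative_value")


def percent_of_total(m: CountMatrix) -> CountMatrix:
    """Express each count as a percentage of its sample's total spectra."""
    if m.stage not in ("raw", "quantitative_value"):
        raise ValueError(f"percent_of_total expects raw or quantitative_value, got {m.stage!r}")
    totals = m.data.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * m.data.div(totals.where(totals != 0), axis=1)
    return CountMatrix(pct.fillna(0.0), "percent_of_total")


def mean_across_replicates(m: CountMatrix) -> CountMatrix:
    """Average the normalized counts over each bait's replicates."""
    if m.stage != "percent_of_total":
        raise ValueError(f"mean_across_replicates expects percent_of_total, got {m.stage!r}")
    baits = m.baits
    mean = m.data.T.groupby(level="bait", sort=False).mean().T
    mean = mean[baits]
    mean.columns.name = None
    return CountMatrix(mean, "replicate_mean")


def compute_fdr(n_target: int, n_decoy: int, convention: str = "d_over_t") -> float:
    """Target-decoy false-discovery-rate estimate.

    ``d_over_t``: decoys / targets.  ``2d_over_td``: 2*decoys / (targets +
    decoys), the convention for searches against a concatenated
    forward+reverse database where a false match is equally likely to hit
    either half.
    """
    if n_target < 0 or n_decoy < 0:
        raise ValueError("counts must be non-negative")
    if n_target + n_decoy == 0:
        raise ValueError("no identifications: FDR undefined")
    if convention == "d_over_t":
        if n_target == 0:
            raise ValueError("zero targets: d/t FDR undefined")
        return n_decoy / n_target
    if convention == "2d_over_td":
        return 2.0 * n_decoy / (n_target + n_decoy)
    raise ValueError(f"unknown FDR convention {convention!r}")


def hi3_quantify(peptide_responses: Sequence[float], k: int = 3) -> float:
    """Mean MS response of the top-``k`` (default three) most intense peptides.

    With fewer than ``k`` peptides the mean over all available is used; a
    single-peptide protein is low-evidence and triggers a warning.
    """
    responses = [float(r) for r in peptide_responses]
    if not responses:
        raise ValueError("hi3_quantify needs at least one peptide response")
    if any(r < 0 for r in responses):
        raise ValueError("peptide responses must be non-negative")
    if len(responses) == 1:
        warnings.warn("single-peptide protein: Hi3 estimate is low-evidence", stacklevel=2)
    top = sorted(responses, reverse=True)[: min(k, len(responses))]
    return float(np.mean(top))


def absolute_quantity(
    hi3_response: float, calibrant_hi3: float, calibrant_amount: float = 50.0
) -> float:
    """Convert a Hi3 response to fmol/ug via the spike-in calibrant.

    The default calibrant amount (50 fmol per ug of lysate) matches a yeast
    alcohol-dehydrogenase spike.
    """
    if calibrant_hi3 <= 0:
        raise ValueError("calibrant Hi3 response must be positive")
    if hi3_response < 0:
        raise ValueError("Hi3 response must be non-negative")
    return hi3_response / calibrant_hi3 * calibrant_amount


@dataclass(frozen=True)
class AbundanceEstimate:
    """Per-protein Hi3 abundance with absolute quantity and rank."""

    protein: str
    hi3_response: float
    absolute_quantity: float
    rank: int | None = None


def abundance_rank(estimates: Sequence[AbundanceEstimate]) -> list[AbundanceEstimate]:
    """Assign ranks 1..N by descending absolute quantity, accession tie-break."""
    ordered = sorted(estimates, key=lambda e: (-e.absolute_quantity, e.protein))
    return [replace(e, rank=i + 1) for i, e in enumerate(ordered)]


def top_n_membership(
    estimates: Sequence[AbundanceEstimate], proteins: Iterable[str], n: int
) -> list[str]:
    """Which of the queried proteins rank within the top ``n`` most abundant."""
    ranked = abundance_rank(estimates)
    top = {e.protein for e in ranked if e.rank <= n}
    return [p for p in proteins if p in top]


def read_peptide_responses(source) -> dict[str, list[float]]:
    """Read a peptide-response TSV (protein, peptide, response) into per-protein lists."""
    df = pd.read_csv(source, sep="\t")
    required = {"protein", "response"}
    if not required <= set(df.columns):
        raise ValueError(f"peptide response table missing columns: {sorted(required - set(df.columns))}")
    out: dict[str, list[float]] = {}
    for protein, grp in df.groupby("protein", sort=False):
        out[str(protein)] = [float(v) for v in grp["response"]]
    return out
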