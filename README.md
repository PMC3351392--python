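# paxms

Analysis pipeline for **Peptide Array X-linking (PAX)** experiments — a
proteomics strategy in which arrayed bait peptides carrying the
photo-activatable amino-acid crosslinker *p*-benzoyl-L-phenylalanine (pBpa)
covalently trap directly interacting proteins from a cell or tissue lysate.
After stringent denaturing washes, the trapped proteins on each bait strip
are identified by LC-MS/MS and quantified by spectral counting.

Because the permissive crosslinker position within an uncharacterized
peptide ligand is unknown, each bait is synthesized as a *positional
substitution series*: one spot per selected residue with pBpa at that
position (12 spots per bait by default, plus an unmodified control spot),
in the 24×16 = 384-spot SPOT-membrane format.

`paxms` implements the computational side of this workflow for proteomics
researchers running or emulating such screens:

- **Array design** — positional substitution series (even-spread position
  selection when the spot budget is below the peptide length), motif-overlap
  annotation, membrane layout, synthesis-sheet/FASTA export.
- **Motif/domain mapping** — consensus-motif scanning (PxxP, NPF, PPxxF,
  PPLP, (F/L)PPPP) and the domain classes expected to bind them (SH3, EH,
  EVH1 class II, WW, EVH1 class I).
- **Spectral-count normalization** — per-sample scaling to the mean total
  spectra ("quantitative values"), percent-of-sample-total, replicate
  averaging (n = 2 by default).
- **Cluster analysis** — hierarchical clustering of protein bait-association
  profiles by **uncentered Pearson correlation**,

  r(x, y) = Σᵢ xᵢyᵢ / (√Σᵢxᵢ² · √Σᵢyᵢ²),   d = 1 − r,

  with average linkage and deterministic tie-breaking; selection of
  *single-bait interactors* (the other baits act as internal negative
  controls) and extraction of bait-pure clusters; TreeView-compatible
  `.cdt`/`.gtr` export.
- **Interaction filtering** — elimination of control-peptide binders,
  expected-domain filtering, evidence combination, known-pair annotation,
  bait-by-bait reporting.
- **FDR and quantitation** — target-decoy FDR arithmetic and Hi3 (top-three
  peptide) label-free quantitation calibrated to a 50 fmol/µg spike-in.
- **Synthetic experiments** — a seeded generator planting bait-specific
  interactors, promiscuous sticky background binders, multi-bait proteins
  and domain-only decoys, with Poisson counts (rate = abundance × binding
  strength) over a ~3-orders-of-magnitude abundance range.

## Worked example

The package ships a six-peptide proline-motif bait panel (SOS1, Stonin2,
Epsin1, mGluR5, WAVE1 and a motif-free control). Scanning it
(`python examples/02_scan_motifs.py`) prints, e.g.:

```
WAVE1    PQGEVQGLPPPPPPPPLP   motifs: {FL}PPPP@8, PxxP@9, PxxP@10, PxxP@11, PxxP@12, PxxP@13, PPLP@15, PxxP@15
         expected binder domains: ['EVH1_classI', 'SH3', 'WW']
```

i.e. the WAVE1 poly-proline peptide carries all three motif classes, so
legitimate direct binders should contain an SH3, WW or class I EVH1 domain.

Running the full pipeline on a simulated experiment
(`python examples/03_normalize_and_cluster.py`) prints:

```
32 proteins x 10 samples -> replicate-mean matrix over baits ['SOS1', 'Stonin2', 'Epsin1', 'mGluR5', 'Control']
17 single-bait interactors (of 32 proteins; the rest touch several baits)
4 bait-pure clusters:
  SOS1      5 proteins, e.g. ['SPEC_SOS1_01', 'SPEC_SOS1_02', 'SPEC_SOS1_03']
  ...
```

One bait-pure cluster per motif-bearing bait: the sticky background binders
touch every strip and are excluded by the single-bait rule, while each
planted specific interactor clusters with its bait. Example 04 adds the
control-elimination and domain-filtering stream and combines the evidence;
example 05 shows target-decoy FDR estimation and Hi3 quantitation.

The same stages are available from the shell via the thin `pax` CLI
(`pax simulate`, `pax design`, `pax scan`, `pax normalize`, `pax cluster`,
`pax filter`, `pax fdr`, `pax quant`, `pax run-all`, `pax validate`);
`pax run-all` writes every artifact plus a sha256 manifest so re-runs are
verifiably identical.

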