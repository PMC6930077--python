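# repsim

Synthetic iNKT TCR repertoire simulation and AIRR-seq clonal-structure
analysis.

Invariant natural killer T (iNKT) cells carry a semi-invariant T-cell
receptor: a near-invariant alpha chain (mouse Valpha14-Jalpha18, i.e.
TRAV11–TRAJ18 with a conserved 15-aa CDR3alpha) paired with a diverse
beta chain. Bulk RNA-seq of sorted iNKT cells from different lymphoid
tissues shows tissue-specific TRBV usage and, strikingly, tissue-specific
clonal expansion: the fraction of CDR3beta clonotypes seen exactly once
drops from roughly 65% in spleen and thymus to ~50% in mesenteric and
~40% in inguinal lymph nodes. `repsim` packages the full desk-scale
analysis behind such findings, driven by a synthetic repertoire
generator, so every stage is testable without sequencing data:

- **Simulation** — tissue presets generate AIRR-format repertoires with
  log-series clone sizes p(k) = θ^k / (k·(−ln(1−θ))), tissue TRBV usage
  vectors, a canonical-alpha fraction (default 0.97), a CDR3beta length
  spectrum with mode 14 aa, a configurable nonproductive fraction, and a
  ground-truth table. θ is calibrated through the closed-form singleton
  fraction p₁ = θ/(−ln(1−θ)): 0.60 → 0.655, 0.80 → 0.497, 0.90 → 0.391.
- **Extraction** — V/J assignment by anchored matching, CDR3 junction
  extraction between the conserved V cysteine and the J [FW]GXG
  phenylalanine (both codons included), productivity filtering
  (in-frame, stop-free) and clonotype assembly keyed by (V gene, CDR3
  nucleotide), per sample or pooled.
- **Repertoire statistics** — V/J usage (count- or clonotype-weighted),
  V–J pairing percentages, clone-size classes {1, 2, 3, 4, ≥5}, median
  clone counts, top-N cumulative frequencies, and rare-vs-abundant V
  usage contrasts.
- **CDR3 physicochemistry** — Kyte–Doolittle mean hydrophobicity
  (GRAVY), isoelectric point by bisection on the EMBOSS pK set, polar /
  aliphatic / aromatic residue fractions, length spectra, and position
  frequency matrices with per-column information content (bits).
- **Group comparisons** — Mann–Whitney U with a tie-aware exact
  enumeration mode for pooled n ≤ 14, paired/Welch t tests, one-way
  ANOVA with Tukey HSD, Pearson correlation.

## Worked example

```python
from repsim import (GeneratorConfig, assemble_clonotypes,
                    default_reference, generate_repertoire, tissue_preset)
from repsim.stats import clone_size_distribution

reference = default_reference()
cfg = GeneratorConfig(preset=tissue_preset("iLN"), n_clonotypes=20000, seed=42)
records, truth = generate_repertoire(cfg, reference)
trb = [r for r in records if r.locus == "TRB"]
clones = assemble_clonotypes(trb, scope="pooled")
print(clone_size_distribution(clones))
```

Running `python examples/03_clonal_structure.py` prints:

```
 tissue      1      2      3      4    >=5  median   top25
 spleen  0.642  0.200  0.080  0.038  0.040     1.0  0.0173
    mLN  0.487  0.202  0.107  0.061  0.143     2.0  0.0182
    iLN  0.383  0.172  0.108  0.073  0.263     2.0  0.0217
```

Each row is the fraction of distinct productive CDR3beta clonotypes
observed once, twice, …, five-or-more times; the singleton column tracks
the preset calibration (0.655 / 0.497 / 0.391) and falls as clonal
expansion rises, while the median count and the cumulative share of the
25 most prevalent clonotypes rise. The other `examples/` scripts cover
simulation, extraction round-trips, CDR3 profiling and the comparison
tests; each prints a line explaining its numbers.

A thin CLI mirrors the library:

```sh
repsim simulate --preset iLN --n-clonotypes 20000 --seed 42 --out out/
repsim stats --in out/airr.tsv --pooled --out out/stats
repsim props --in out/airr.tsv --locus TRB --fixed-length 14 --out out/props
repsim run --config pipeline.yaml --out out/run   # end-to-end with manifest
```

## Layout

- `src/repsim/` — library (`simulate`, `extract`, `stats`, `properties`,
  `compare`, `pipeline`, `io`, `germline`, `cli`)
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model assumptions, parameter choices, limitations
- `tests/` — pytest suite (unit, property-based, study-scale)
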