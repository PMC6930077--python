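# Methods

## The clone-size model

Clone sizes are modelled as i.i.d. draws from the logarithmic-series
distribution, p(k) = θ^k / (k·(−ln(1−θ))) for k ≥ 1. It was chosen as
the simplest one-parameter heavy-tailed count distribution whose
singleton fraction has a closed form, p₁ = θ/(−ln(1−θ)), so each tissue
preset can be calibrated exactly to a target singleton level rather than
fitted:

| preset | θ | closed-form p₁ |
|---|---|---|
| thymus | 0.60 | 0.655 |
| spleen | 0.60 | 0.655 |
| mLN | 0.80 | 0.497 |
| iLN | 0.90 | 0.391 |

Sampling is by inverse CDF over a table truncated where the tail mass
falls below 1e-12 (uniforms beyond the table clamp to the last entry;
probability < 1e-12 per draw). The tests cross-check the sampler against
`scipy.stats.logser` (χ² goodness of fit at n = 50,000) and against the
closed forms for p₁ and the mean at n = 100,000 within 3 standard
errors.

## The synthetic repertoire

Each simulated tissue contains `n_clonotypes` beta clonotypes and a
parallel alpha set, each emitted as one AIRR record whose
`duplicate_count` is the clone size (counts are treated as read counts
throughout). Per beta clonotype: a TRBV/TRBJ pair drawn from the preset
vectors, a CDR3 length from the spectrum {11: .03, 12: .09, 13: .18,
14: .30, 15: .20, 16: .12, 17: .06, 18: .02} (mode 14 aa; tail shape a
modelling default), and a junction built as V-templated prefix from the
conserved Cys codon + untemplated N region + J-templated suffix ending
at the [FW]GXG Phe codon. Exonucleolytic chewback is modelled by
trimming the templated tails (each keeps ≥ one codon, preserving the
anchors); the N region is drawn in 0–18 nt and rejection-sampled until
the junction is stop-free. There is no explicit D segment: the single
untemplated stretch stands in for D plus both N additions, which is why
its upper bound is larger than a pure N insert would be.

A `nonproductive_rate` share of beta clonotypes (default 0.10, a
modelling default that exists to exercise the productivity filter) is
spoiled either by a 1–2 nt frameshift at the V/N boundary or by an
in-frame interior stop codon, with equal probability. Alpha records are
the canonical TRAV11–TRAJ18 junction CVVGDRGSALGRLHF with probability
`canonical_alpha_fraction` (default 0.97, consistent with the >96%
dominance reported for mouse iNKT cells); the junction itself is the
widely reported canonical mouse iNKT sequence, 15 aa, fully templated by
the toy germline pair. Non-canonical alpha clonotypes draw any alpha V/J
pair and a random junction.

All randomness flows from one `numpy` Generator seeded per run; rerunning
a config is byte-identical.

### Toy germline reference

The bundled reference carries seven TRBV segments (the six named genes
plus an aggregate "TRBVother"), three TRBJ, and two alpha pairs:
TRAV11/TRAJ18 (templating the canonical junction) and a decoy
TRAV9/TRAJ12. The decoy exists so that canonical-alpha dominance is a
real measurement — with a single alpha pair every record would trivially
be TRAV11–TRAJ18. Segments are short (~36–63 nt) synthetic sequences
with valid Cys and [FW]GXG anchors; any IMGT-derived FASTA annotated
with the two anchor offsets is accepted in its place.

### What the generator does not emulate

No sequencing errors, read-level (FASTQ) simulation, quality scores,
allele-level gene calls, or explicit D segments; V/J draws are
independent (no preferential pairing); clone sizes are independent of
gene usage and CDR3 sequence. Consequently, passing tests show that the
pipeline's measurements are correct and well calibrated on data with
known structure — not that the extraction heuristics would survive noisy
reads, nor that real repertoires follow a log-series law.

## Extraction

V genes are assigned by Hamming-distance matching of each germline
prefix (through the Cys codon) anchored at read position 0; J genes by
scanning the germline anchor-containing suffix over the read (exact
`str.find` fast path, mismatch-tolerant scan otherwise). The default
mismatch budget is 2; reads failing either assignment go to a rejects
table with a reason code. The junction is the substring from the first
base of the Cys codon through the last base of the Phe codon;
productivity is the conjunction of frame (length divisible by 3) and a
stop-free translation. Clonotypes are keyed by (V gene, CDR3
nucleotide) — J is reported but excluded from the key, the common
convention; both an amino-acid key and J inclusion are switchable.
Assembly is per-sample by default with a pooled mode that merges the
samples of a tissue first.

On clean generator output, extraction recovers (V, junction,
productivity) for 100% of records; this exact round-trip is asserted in
the tests.

### Convergent junctions

Short junctions can be fully templated (N region of zero), so distinct
simulated clonotypes occasionally produce identical (V, CDR3 nt) pairs
and merge at assembly. At 20,000 clonotypes this removes ~4% of
clonotypes and biases the assembled singleton fraction ~1–2 percentage
points below the closed form — the synthetic analogue of convergent
recombination, and the reason pipeline-level singleton checks carry a
±2-point band while sampler-level checks use 3 binomial SE.

## CDR3 physicochemistry

Hydrophobicity is the mean Kyte–Doolittle value per residue (the mean,
not the sum, so values are comparable across lengths; a `sum` option
exists). The isoelectric point solves Q(pH) = Σ_basic n_g/(1+10^(pH−pK_g))
− Σ_acidic n_g/(1+10^(pK_g−pH)) = 0 by bisection on [0, 14] to a bracket
of 1e-6 pH; Q is strictly decreasing so the root is unique, and the
EMBOSS default pK set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5,
D 3.9, E 4.1, C 8.5, Y 10.1) is used with free cysteines and no
disulfide handling. Tests compare bisection against a 1e-4-resolution
grid-search oracle within 2e-4 on 1,000 random peptides.

Residue classes are polar {D,E,H,K,N,Q,R,S,T}, aliphatic {A,I,L,V},
aromatic {F,H,W,Y}, implemented literally — histidine belongs to both
polar and aromatic, so the three fractions can sum above 1. Ambiguous
residues (X) contribute no hydrophobicity, no charge and no class
membership, and are excluded from class denominators; each occurrence
warns.

Position frequency matrices are computed over sequences filtered to one
fixed length (defaults 15 aa alpha / 14 beta, the modal classes); the
kept count is reported. Information content is log₂20 − H(column) in
bits with no small-sample correction — the raw IC plus the kept count
keep any correction recomputable downstream.

## Statistics and comparisons

Gene-usage "frequency of sequences" statistics are count-weighted;
clone-size classes are over distinct clonotypes; both weightings are
exposed because the two denominators answer different questions.
Prevalence ranking ties break deterministically (count desc, CDR3 aa
asc, nt asc) so top-N values are bit-reproducible. The rare-vs-abundant
contrast defaults to singletons vs count ≥ 2; the threshold is a
parameter.

Mann–Whitney U (U = Σ 1[a>b] + ½·1[a=b]) uses full enumeration of all
C(n_a+n_b, n_a) group assignments when the pooled size is ≤ 14 —
conditioning on the observed values, so ties are handled exactly, where
classical exact tables are not valid — and a tie-corrected normal
approximation with continuity correction above. The cutoff of 14 keeps
the worst case at 3,432 assignments. Two-sidedness is distance of U from
its null mean. t tests default to Welch for unpaired data (pooled
variance by flag); zero-variance degenerate inputs raise rather than
return a misleading p. ANOVA/Tukey and Pearson delegate to scipy
(Tukey p values from the studentized-range distribution); no
multiple-testing correction beyond Tukey is applied anywhere.

## Problem sizes and numerical choices

Study-scale checks run at 20,000 clonotypes per tissue with a fixed
seed — large enough that 3-SE sampler bands are ~1 percentage point and
the ±2-point pipeline bands are comfortably discriminating, while a full
reproduction run completes in tens of seconds on one CPU. Probability
vectors must sum to 1 within 1e-9; usage/pairing conservation identities
are asserted to the same tolerance. Empty repertoires, empty strata
(warning + empty map), inverted anchors and infeasible junction
geometries raise typed errors.

## Known limitations

- Extraction anchors V matching at read position 0; 5'-truncated reads
  are rejected rather than rescued.
- The exact Mann–Whitney mode is exponential in pooled size and is
  capped at 14 by design.
- The log-series clone-size model has no overdispersion control beyond
  θ; it cannot represent a repertoire whose singleton fraction and mean
  clone size disagree with the one-parameter family.
- TRBJ usage is uniform by default (unconstrained); V–J draws are
  independent, so preferential-pairing signals cannot be planted without
  custom preset vectors.
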