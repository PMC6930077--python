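"""Simulate tissue-specific iNKT repertoires and inspect their structure.

Each tissue preset fixes a log-series clone-size parameter theta, a TRBV
usage vector, the canonical-alpha fraction and a nonproductive rate.
Larger theta means heavier clonal expansion, hence fewer singletons.
"""

from repsim import GeneratorConfig, default_reference, generate_repertoire
from repsim.simulate import logseries_singleton_fraction, tissue_preset

reference = default_reference()

for tissue in ("spleen", "mLN", "iLN"):
    preset = tissue_preset(tissue)
    cfg = GeneratorConfig(preset=preset, n_clonotypes=5000, seed=42)
    records, truth = generate_repertoire(cfg, reference)
    trb = [r for r in records if r.locus == "TRB"]
    productive = sum(r.productive for r in trb)
    singletons = sum(r.duplicate_count == 1 for r in trb) / len(trb)
    print(f"{tissue:>7}: theta={preset.theta:.2f}  "
          f"expected singleton fraction "
          f"{logseries_singleton_fraction(preset.theta):.3f}  "
          f"observed {singletons:.3f}  "
          f"productive beta records {productive}/{len(trb)}")

# The expected column is the closed form theta/(-ln(1-theta)); the observed
# record-level fraction tracks it, and falls from spleen to mLN to iLN as
# clonal expansion rises.
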