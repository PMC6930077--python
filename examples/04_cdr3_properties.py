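"""CDR3 physicochemical profiling and position frequency matrices."""

import numpy as np

from repsim import (
    GeneratorConfig,
    default_reference,
    generate_repertoire,
    tissue_preset,
)
from repsim.properties import (
    consensus,
    length_distribution,
    position_frequency_matrix,
    property_table,
)

reference = default_reference()
cfg = GeneratorConfig(preset=tissue_preset("spleen"), n_clonotypes=5000,
                      seed=42)
records, _ = generate_repertoire(cfg, reference)

beta = [r.junction_aa for r in records if r.locus == "TRB" and r.productive]
alpha = [r.junction_aa for r in records if r.locus == "TRA" and r.productive]

freqs, mode = length_distribution(beta)
print(f"beta CDR3 modal length: {mode} aa "
      f"(frequency {freqs[mode]:.2f} of {len(beta)} sequences)")

table = property_table(beta[:1000])
print(f"mean hydrophobicity {table.hydrophobicity.mean():+.3f}, "
      f"mean pI {table.isoelectric_point.mean():.2f}, "
      f"mean polar fraction {table.frac_polar.mean():.2f}")

# logo matrix for the 14-aa beta junctions (the modal class)
pfm, ic, kept = position_frequency_matrix(beta, 14)
print(f"beta 14-aa logo from {kept} sequences; "
      f"anchors C/F carry {ic[0]:.2f}/{ic[-1]:.2f} bits, "
      f"centre positions {np.mean(ic[5:9]):.2f} bits")

# the invariant alpha chain gives a maximally sharp 15-aa logo
pfm_a, ic_a, kept_a = position_frequency_matrix(alpha, 15)
print(f"alpha 15-aa consensus: {consensus(pfm_a)} "
      f"(mean IC {ic_a.mean():.2f} bits over {kept_a} sequences)")
# High information content at the conserved anchors and across the whole
# canonical alpha junction; diverse centre positions in beta.
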