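"""Clone-size classes, median counts and top-25 cumulative frequency.

Low-singleton, high-top-25 repertoires indicate clonal expansion; the
inguinal-LN preset is the most expanded, the spleen preset the least.
"""

from repsim import (
    GeneratorConfig,
    assemble_clonotypes,
    default_reference,
    generate_repertoire,
    tissue_preset,
)
from repsim.stats import (
    clone_size_distribution,
    median_count,
    top_n_cumulative,
)

reference = default_reference()

print(f"{'tissue':>7} {'1':>6} {'2':>6} {'3':>6} {'4':>6} {'>=5':>6}"
      f" {'median':>7} {'top25':>7}")
for tissue in ("spleen", "mLN", "iLN"):
    cfg = GeneratorConfig(preset=tissue_preset(tissue),
                          n_clonotypes=20000, seed=42)
    records, _ = generate_repertoire(cfg, reference)
    trb = [r for r in records if r.locus == "TRB"]
    clones = assemble_clonotypes(trb, scope="pooled")
    sizes = clone_size_distribution(clones)
    row = " ".join(f"{sizes[k]:6.3f}" for k in ("1", "2", "3", "4", ">=5"))
    print(f"{tissue:>7} {row} {median_count(clones):7.1f} "
          f"{top_n_cumulative(clones, 25):7.4f}")

# Singleton fractions fall (~0.65 -> ~0.49 -> ~0.39) while the cumulative
# share of the 25 most prevalent clonotypes rises from spleen to iLN:
# the two views of the same increase in clonal expansion.
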