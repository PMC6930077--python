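"""Comparison statistics on repertoire summaries across tissues.

Per-sample singleton fractions for two presets are compared with the
exact Mann-Whitney test; per-sample TRBV13-2 usage across four tissues
with one-way ANOVA + Tukey HSD.
"""

from repsim import (
    GeneratorConfig,
    assemble_clonotypes,
    default_reference,
    generate_repertoire,
    tissue_preset,
)
from repsim.compare import mann_whitney, one_way_anova
from repsim.stats import singleton_fraction, v_usage

reference = default_reference()


def per_sample_stat(tissue, seed, stat):
    cfg = GeneratorConfig(preset=tissue_preset(tissue), n_clonotypes=4000,
                          seed=seed)
    records, _ = generate_repertoire(cfg, reference)
    trb = [r for r in records if r.locus == "TRB"]
    clones = assemble_clonotypes(trb, scope="per-sample")
    by_sample = {}
    for c in clones:
        by_sample.setdefault(c.sample_id, []).append(c)
    return [stat(group) for _, group in sorted(by_sample.items())]


spleen = per_sample_stat("spleen", 1, singleton_fraction)
iln = per_sample_stat("iLN", 2, singleton_fraction)
res = mann_whitney(spleen, iln)
print("per-sample singleton fractions")
print(f"  spleen {[round(x, 3) for x in spleen]}")
print(f"  iLN    {[round(x, 3) for x in iln]}")
print(f"  {res.method}: U={res.statistic:.1f}, p={res.p_value:.4f}")

usage = [per_sample_stat(t, i + 10,
                         lambda g: v_usage(g).get("TRBV13-2", 0.0))
         for i, t in enumerate(("spleen", "thymus", "mLN", "iLN"))]
anova = one_way_anova(usage, tukey=True)
print("\nper-sample TRBV13-2 usage across four tissues")
print(f"  {anova.method}: F({anova.df_between},{anova.df_within})="
      f"{anova.f_statistic:.1f}, p={anova.p_value:.2e}")
print(f"  Tukey spleen-vs-mLN p={anova.tukey[(0, 2)]:.4f}, "
      f"spleen-vs-thymus p={anova.tukey[(0, 1)]:.4f}")
# A small exact-p Mann-Whitney separates the expansion levels; ANOVA
# strongly flags the depressed TRBV13-2 usage in the lymph-node presets,
# while the small spleen-thymus preset difference is only marginal.
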