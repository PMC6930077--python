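"""Config-driven end-to-end runs and the fixed-seed reproduction harness.

A run executes the enabled stages in order (simulate -> extract -> stats
-> props), writes every statistic as TSV/JSON, and leaves a manifest
(config copy, root seed, package version, constant tables, input
checksums, per-stage record counts) so every number is traceable to a
config.  Re-running an identical config reproduces byte-identical
statistic files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .constants import EMBOSS_PK, KYTE_DOOLITTLE
from .extract import assemble_clonotypes, extract_rearrangements
from .germline import default_reference
from .io import airr_dataframe, read_airr, write_airr
from .model import GeneratorConfig, RepsimError
from .properties import length_distribution, position_frequency_matrix, property_table
from .simulate import generate_repertoire, tissue_preset, PRESET_NAMES
from .stats import summarize
from . import stats as rstats

log = logging.getLogger("repsim")

DEFAULT_CONFIG = {
    "seed": 7,
    "stages": {"simulate": True, "extract": False, "stats": True,
               "props": True},
    "simulate": {"presets": list(PRESET_NAMES), "n_clonotypes": 2000,
                 "samples_per_tissue": 4, "nonproductive_rate": 0.10,
                 "canonical_alpha_fraction": 0.97},
    "extract": {"max_mismatch": 2},
    "stats": {"pooled": True, "top_n": 25, "abundant_threshold": 2},
    "props": {"locus": "TRB", "fixed_length": 14},
    "input": None,  # AIRR TSV path when the simulate stage is disabled
}


class ConfigError(RepsimError):
    """Invalid pipeline configuration; message names the offending key."""


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if key not in cfg:
                raise ConfigError(f"unknown config key: {key}")
            if isinstance(cfg[key], dict) and isinstance(value, dict):
                for sub, sval in value.items():
                    if sub not in cfg[key]:
                        raise ConfigError(f"unknown config key: {key}.{sub}")
                    cfg[key][sub] = sval
            else:
                cfg[key] = value
    for name in cfg["simulate"]["presets"]:
        if name not in PRESET_NAMES:
            raise ConfigError(f"simulate.presets: unknown preset {name!r}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path | None, outdir: str | Path) -> Path:
    """Execute the configured stages; returns the output directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "constants": {"kyte_doolittle": dict(KYTE_DOOLITTLE),
                      "emboss_pk": dict(EMBOSS_PK)},
        "stages": {},
        "inputs": {},
    }
    stages = config["stages"]
    reference = default_reference()

    if stages.get("simulate"):
        sim = config["simulate"]
        all_records, truths = [], []
        for i, preset_name in enumerate(sim["presets"]):
            preset = tissue_preset(
                preset_name,
                nonproductive_rate=sim["nonproductive_rate"],
                canonical_alpha_fraction=sim["canonical_alpha_fraction"])
            gcfg = GeneratorConfig(
                preset=preset, n_clonotypes=int(sim["n_clonotypes"]),
                seed=(seed + 97 * i) % (2 ** 31),
                samples_per_tissue=int(sim["samples_per_tissue"]))
            records, truth = generate_repertoire(gcfg, reference)
            all_records.extend(records)
            truths.append(truth)
            log.info("simulate[%s]: %d records", preset_name, len(records))
        write_airr(all_records, out / "airr.tsv")
        pd.concat(truths, ignore_index=True).to_csv(
            out / "ground_truth.tsv", sep="\t", index=False)
        manifest["stages"]["simulate"] = {"n_records": len(all_records)}
        records = all_records
    else:
        if not config.get("input"):
            raise ConfigError("input: an AIRR TSV is required when the "
                              "simulate stage is disabled")
        records = read_airr(config["input"])
        manifest["inputs"][str(config["input"])] = _sha256(Path(config["input"]))
        log.info("loaded %d records from %s", len(records), config["input"])

    if stages.get("extract"):
        ex = config["extract"]
        reads = [(r.sequence_id, r.sequence) for r in records]
        counts = {r.sequence_id: r.duplicate_count for r in records}
        labels = {r.sequence_id: (r.sample_id, r.tissue) for r in records}
        result = extract_rearrangements(
            reads, reference, max_mismatch=int(ex["max_mismatch"]),
            read_counts=counts, read_labels=labels)
        result.rejects.to_csv(out / "rejects.tsv", sep="\t", index=False)
        write_airr(result.records, out / "airr_extracted.tsv")
        n_prod = sum(r.productive for r in result.records)
        manifest["stages"]["extract"] = {
            "n_in": len(records), "n_extracted": len(result.records),
            "n_productive": n_prod, "n_rejected": len(result.rejects)}
        log.info("extract: %d/%d extracted, %d productive",
                 len(result.records), len(records), n_prod)
        records = result.records

    if stages.get("stats"):
        st = config["stats"]
        pooled = bool(st["pooled"])
        scope = "pooled" if pooled else "per-sample"
        summaries = {}
        for locus in sorted({r.locus for r in records}):
            locus_records = [r for r in records if r.locus == locus]
            clonotypes = assemble_clonotypes(locus_records, scope=scope)
            by_scope: dict[str, list] = {}
            for c in clonotypes:
                label = c.tissue if pooled else f"{c.tissue}/{c.sample_id}"
                by_scope.setdefault(label, []).append(c)
            for label, group in sorted(by_scope.items()):
                s = summarize(group, scope=label, pooled=pooled,
                              top_n=(10, int(st["top_n"]), 50))
                summaries[f"{locus}:{label}"] = s.to_dict()
                rare, abundant = rstats.rare_vs_abundant_usage(
                    group, threshold=int(st["abundant_threshold"]))
                summaries[f"{locus}:{label}"]["rare_v_usage"] = rare
                summaries[f"{locus}:{label}"]["abundant_v_usage"] = abundant
        (out / "summaries.json").write_text(
            json.dumps(summaries, indent=2, sort_keys=True))
        _summary_tables(summaries, out)
        manifest["stages"]["stats"] = {"n_scopes": len(summaries)}
        log.info("stats: %d scopes summarised", len(summaries))

    if stages.get("props"):
        pr = config["props"]
        seqs = [r.junction_aa for r in records
                if r.productive and r.locus == pr["locus"]]
        if seqs:
            table = property_table(seqs)
            table.to_csv(out / "properties.tsv", sep="\t", index=False)
            freqs, mode = length_distribution(seqs)
            pd.DataFrame({"length": list(freqs), "frequency":
                          list(freqs.values())}).to_csv(
                out / "length_distribution.tsv", sep="\t", index=False)
            pfm, ic, kept = position_frequency_matrix(
                seqs, int(pr["fixed_length"]))
            pfm.to_csv(out / "pfm.tsv", sep="\t")
            pd.DataFrame({"position": range(1, len(ic) + 1),
                          "information_bits": ic}).to_csv(
                out / "information_content.tsv", sep="\t", index=False)
            manifest["stages"]["props"] = {
                "n_sequences": len(seqs), "modal_length": mode,
                "n_in_logo": kept}
            log.info("props: %d sequences, modal length %d", len(seqs), mode)

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _summary_tables(summaries: dict, out: Path) -> None:
    """Flatten per-scope summaries into one TSV per statistic."""
    usage_rows, size_rows = [], []
    for label, s in summaries.items():
        for gene, freq in s["v_usage"].items():
            usage_rows.append({"scope": label, "gene": gene, "frequency": freq})
        for klass, frac in s["size_classes"].items():
            size_rows.append({"scope": label, "size_class": klass,
                              "fraction": frac})
    pd.DataFrame(usage_rows).to_csv(out / "v_usage.tsv", sep="\t", index=False)
    pd.DataFrame(size_rows).to_csv(out / "size_classes.tsv", sep="\t",
                                   index=False)


# -- fixed-seed reproduction harness ----------------------------------------

def reproduce_acceptance(seed: int = 42, n_clonotypes: int = 20000) -> dict:
    """Recompute the headline synthetic-repertoire quantities from scratch.

    Runs the generator at the stated study conditions and measures, via
    the ordinary pipeline stages:

    - singleton percentage of distinct productive CDR3beta clonotypes for
      the spleen / mLN / iLN presets (log-series theta 0.60 / 0.80 / 0.90);
    - the count-weighted percentage of alpha sequences assigned to
      TRAV11-TRAJ18 after extraction and assembly;
    - modal productive CDR3alpha and CDR3beta lengths.

    Returns {name: {"value": float, "n": int}}.
    """
    reference = default_reference()
    results: dict[str, dict] = {}

    singleton_keys = {"spleen": "singleton_pct_spleen",
                      "mLN": "singleton_pct_mln",
                      "iLN": "singleton_pct_iln"}
    spleen_records = None
    for i, tissue in enumerate(("spleen", "mLN", "iLN")):
        gcfg = GeneratorConfig(preset=tissue_preset(tissue),
                               n_clonotypes=n_clonotypes,
                               seed=(seed + 97 * i) % (2 ** 31))
        records, _ = generate_repertoire(gcfg, reference)
        if tissue == "spleen":
            spleen_records = records
        trb = [r for r in records if r.locus == "TRB"]
        clonotypes = assemble_clonotypes(trb, scope="pooled")
        sizes = rstats.clone_size_distribution(clonotypes)
        results[singleton_keys[tissue]] = {
            "value": 100.0 * sizes["1"], "n": len(clonotypes)}

    tra = [r for r in spleen_records if r.locus == "TRA"]
    extraction = extract_rearrangements(
        [(r.sequence_id, r.sequence) for r in tra], reference,
        read_counts={r.sequence_id: r.duplicate_count for r in tra},
        read_labels={r.sequence_id: (r.sample_id, r.tissue) for r in tra})
    tra_clonotypes = assemble_clonotypes(extraction.records, scope="pooled",
                                         include_j=True)
    total = sum(c.count for c in tra_clonotypes)
    canonical = sum(c.count for c in tra_clonotypes
                    if c.v_call == "TRAV11" and c.j_call == "TRAJ18")
    results["canonical_alpha_pct"] = {
        "value": 100.0 * canonical / total, "n": len(tra_clonotypes)}

    _, mode_a = length_distribution(
        [r.junction_aa for r in extraction.records if r.productive])
    results["modal_cdr3a_length"] = {
        "value": float(mode_a),
        "n": sum(r.productive for r in extraction.records)}
    trb_prod = [r.junction_aa for r in spleen_records
                if r.locus == "TRB" and r.productive]
    _, mode_b = length_distribution(trb_prod)
    results["modal_cdr3b_length"] = {"value": float(mode_b),
                                     "n": len(trb_prod)}
    return results
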