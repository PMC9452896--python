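"""Config-driven end-to-end orchestration.

One YAML config names the inputs (a SAM directory + GFF3, or a count
matrix + sample sheet), the stage parameters, and a seed; the pipeline
runs quantification (when alignments are given), filtering and the
dual-normalization contrast plan, MB↔EV correlations, preferential
expression, optional over-representation analysis and the
normalization-method comparison, writing stable-named TSVs plus a JSON
manifest (config hash, seed, versions, per-stage row counts). Reruns
with the same config and inputs are bit-identical; every stage writes
only into the run directory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import Contrast, compare_normalizations
from .differential import run_all_contrasts
from .enrichment import ora_hypergeometric
from .io import (
    MirCountMatrix,
    read_count_matrix,
    read_gmt,
    read_mirbase_gff,
    read_sample_sheet,
    write_results_table,
)
from .normalize import cpm
from .paired import compartment_correlation, overlap_sets, preferential_expression
from .quantify import QuantifyConfig, quantify_dataset

__all__ = ["run_pipeline", "load_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "quantify": {"max_hits": 13, "max_3p_var": 2, "seed_mode": "anchor"},
    "filter": {"cpm_threshold": 0.5, "min_samples_exceeding": 2},
    "de": {"prior_df": 10.0, "alpha": 0.05, "all_groups_f": False, "fdr": False},
    "correlate": {"significant_only": True},
    "compare_norm": {
        "enabled": True,
        "thresholds": [0.05, 0.01],
        "subset": {"compartment": "MB"},
        "group": "treatment",
        "levels": ["CTL", "CLFS"],
    },
}


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _preflight(config: dict[str, Any]) -> None:
    inputs = config.get("inputs") or {}
    if "samples" not in inputs:
        raise ValueError("config missing inputs.samples (sample sheet path)")
    have_counts = "counts" in inputs
    have_sam = "sam_dir" in inputs and "gff" in inputs
    if not (have_counts or have_sam):
        raise ValueError("config must name inputs.counts or inputs.sam_dir + inputs.gff")
    paths = [inputs["samples"]]
    paths += [inputs["counts"]] if have_counts else [inputs["sam_dir"], inputs["gff"]]
    if "gmt" in inputs:
        paths.append(inputs["gmt"])
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")


def run_pipeline(config: dict[str, Any] | str | Path, out_dir: str | Path) -> Path:
    """Run every stage; returns the output directory.

    The manifest (``manifest.json``) records the config hash, the seed,
    the package version and per-stage row counts.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    _preflight(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = config["inputs"]
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": config.get("seed", 0),
        "version": __version__,
        "stages": {},
    }

    samples = read_sample_sheet(inputs["samples"])
    if "counts" in inputs:
        matrix = MirCountMatrix(read_count_matrix(inputs["counts"])[list(samples.index)], samples)
    else:
        qc = config["quantify"]
        annotations = read_mirbase_gff(inputs["gff"])
        sam_dir = Path(inputs["sam_dir"])
        sam_paths = {sid: sam_dir / f"{sid}.sam" for sid in samples.index}
        matrix, stats = quantify_dataset(
            sam_paths,
            annotations,
            samples,
            QuantifyConfig(
                max_hits=qc.get("max_hits", 13),
                max_3p_var=qc.get("max_3p_var", 2),
                seed_mode=qc.get("seed_mode", "anchor"),
            ),
        )
        write_results_table(matrix.counts, out / "counts.tsv")
        manifest["stages"]["quantify"] = {
            sid: vars(s) for sid, s in stats.items()
        }
    manifest["stages"]["input"] = {
        "n_mirs": len(matrix.mir_ids),
        "n_samples": len(matrix.sample_ids),
    }

    de_cfg = config["de"]
    flt = config["filter"]
    alpha = de_cfg.get("alpha", 0.05)
    result = run_all_contrasts(
        matrix,
        cpm_threshold=flt["cpm_threshold"],
        min_samples_exceeding=flt["min_samples_exceeding"],
        prior_df=de_cfg.get("prior_df", 10.0),
        fdr=de_cfg.get("fdr", False),
        all_groups_f=de_cfg.get("all_groups_f", False),
    )
    de_counts: dict[str, int] = {}
    sig_within: dict[str, set[str]] = {}
    for t, table in result.within_treatment.items():
        write_results_table(table.sort_values("p_value"), out / f"de_within_{t}.tsv")
        sig_within[t] = set(table.index[table["p_value"] < alpha])
        de_counts[f"within_{t}"] = len(sig_within[t])
    for (comp, name), table in result.between_treatment.items():
        write_results_table(table.sort_values("p_value"), out / f"de_{comp}_{name}.tsv")
        de_counts[f"{comp}_{name}"] = int((table["p_value"] < alpha).sum())
    for comp, table in result.anova_like.items():
        write_results_table(table.sort_values("p_value"), out / f"de_{comp}_all_treatments.tsv")
    manifest["stages"]["differential"] = {
        "n_filtered_joint": len(result.joint_kept),
        "n_filtered_mb": len(result.mb_kept),
        "n_filtered_ev": len(result.ev_kept),
        "significant": de_counts,
    }

    # Venn regions of the within-treatment DE sets
    regions = overlap_sets(sig_within)
    venn = pd.DataFrame(
        [("&".join(k), len(v), ";".join(sorted(v))) for k, v in sorted(regions.items())],
        columns=["region", "n", "mir_ids"],
    ).set_index("region")
    write_results_table(venn, out / "de_within_overlap.tsv", index_label="region")

    # MB↔EV correlations on TMM-normalized counts from the joint matrix
    norm_counts = cpm(result.joint_matrix, result.joint_factors)
    corr_rows = []
    for t in result.within_treatment:
        subset = sorted(sig_within[t]) if config["correlate"]["significant_only"] else None
        table = compartment_correlation(norm_counts, result.joint_matrix.samples, subset, t)
        table.insert(0, "treatment", t)
        corr_rows.append(table)
    corr = pd.concat(corr_rows)
    write_results_table(corr.sort_values(["treatment", "p_value"]), out / "correlations.tsv")
    manifest["stages"]["correlation"] = {
        "n_significant": int((corr["p_value"] < alpha).sum()),
        "n_tested": len(corr),
    }

    pref = preferential_expression(
        result.joint_kept, result.mb_kept, result.ev_kept, matrix, alpha=alpha
    )
    for comp, ps in pref.items():
        table = ps.paired_t_p.copy()
        table.insert(0, "anova_p", ps.anova_p)
        write_results_table(table, out / f"preferential_{comp}.tsv")
    manifest["stages"]["preferential"] = {c: len(p.mir_ids) for c, p in pref.items()}

    if "gmt" in inputs:
        pathways = read_gmt(inputs["gmt"])
        hits = set().union(*sig_within.values())
        universe = set(matrix.mir_ids)
        ora = ora_hypergeometric(hits & universe, universe, pathways)
        write_results_table(ora, out / "ora.tsv", index_label="pathway")
        manifest["stages"]["ora"] = {
            "n_hits": len(hits & universe),
            "n_universe": len(universe),
            "n_significant_pathways": int((ora["p_value"] < alpha).sum()),
        }

    cn = config["compare_norm"]
    if cn.get("enabled", True):
        report = compare_normalizations(
            matrix,
            Contrast(
                group=cn["group"],
                levels=tuple(cn["levels"]),
                subset=cn.get("subset"),
            ),
            thresholds=tuple(cn["thresholds"]),
            cpm_threshold=flt["cpm_threshold"],
            min_samples_exceeding=flt["min_samples_exceeding"],
            prior_df=de_cfg.get("prior_df", 10.0),
        )
        rows = []
        for thr, sets in sorted(report.de_sets.items()):
            for method, ids in sorted(sets.items()):
                rows.append((thr, method, len(ids), ";".join(sorted(ids))))
        summary = pd.DataFrame(rows, columns=["threshold", "method", "n_de", "mir_ids"])
        summary.to_csv(out / "norm_comparison.tsv", sep="\t", index=False)
        loose = max(report.de_sets)
        manifest["stages"]["compare_norm"] = {
            "set_sizes": report.set_sizes(loose),
            "tpm_strict_size": len(report.tpm_strict),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
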