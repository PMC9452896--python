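"""Normalization-method comparison: the same quasi-NB differential-
expression engine fed by TMM factors, median-of-ratios size factors, or
TPM-transformed counts, with overlap summaries of the resulting
differentially-expressed sets at two stringencies.

The TPM arm rescales per-sample TPM values back to the sample's
original depth and rounds to integers so the common count-based engine
applies; depth is then uniform by construction and the engine runs with
unit factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import build_design, estimate_dispersions, fit_nb_glm, group_columns, ql_f_test
from .io import MirCountMatrix
from .normalize import (
    NormFactors,
    filter_low_expressors,
    median_of_ratios_factors,
    tmm_factors,
    tpm_normalize,
)
from .paired import overlap_sets

__all__ = ["Contrast", "NormComparisonReport", "compare_normalizations"]

METHODS = ("tmm", "median_of_ratios", "tpm")


@dataclass(frozen=True)
class Contrast:
    """A pairwise contrast: which samples, and which factor level pair.

    ``group`` is the metadata column ("treatment" or "compartment");
    ``levels`` is (baseline, alternative); ``subset`` optionally fixes
    the other factor, e.g. ``{"compartment": "MB"}`` for the myobundle
    CLFS-vs-CTL comparison.
    """

    group: str
    levels: tuple[str, str]
    subset: dict[str, str] | None = None


@dataclass
class NormComparisonReport:
    tables: dict[str, pd.DataFrame]  # method -> DE table
    de_sets: dict[float, dict[str, set[str]]]  # threshold -> method -> ids
    overlaps: dict[float, dict[tuple[str, ...], set[str]]]
    tpm_strict: set[str]  # the TPM set at the stricter threshold

    def set_sizes(self, threshold: float) -> dict[str, int]:
        return {m: len(s) for m, s in self.de_sets[threshold].items()}


def _run_engine(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: Contrast,
    offsets: np.ndarray,
    prior_df: float,
) -> pd.DataFrame:
    design = build_design(samples, contrast.group, contrast.levels)
    keep = counts.sum(axis=1) > 0
    counts = counts.loc[keep]
    disp = estimate_dispersions(counts, design, offsets, prior_df=prior_df)
    fit = fit_nb_glm(counts, design, offsets, disp.tagwise)
    return ql_f_test(fit, group_columns(design, contrast.group), prior_df=prior_df)


def compare_normalizations(
    counts: MirCountMatrix,
    contrast: Contrast,
    lengths: pd.Series | None = None,
    thresholds: tuple[float, float] = (0.05, 0.01),
    cpm_threshold: float = 0.5,
    min_samples_exceeding: int = 2,
    prior_df: float = 10.0,
) -> NormComparisonReport:
    """Run the three normalization arms through one DE engine.

    ``lengths`` (nt per miR) feeds the TPM arm; if omitted, all miRs are
    treated as the canonical 22 nt, making TPM a pure depth rescaling.
    Thresholds are (primary, strict); DE sets and their Venn overlaps
    are reported at the primary threshold and, for the TPM arm, at the
    strict one as well.
    """
    loose, strict = max(thresholds), min(thresholds)
    sel = counts
    if contrast.subset:
        sel = counts.select(**contrast.subset)
    sel = sel.select(**{contrast.group: list(contrast.levels)})
    kept, _ = filter_low_expressors(sel, cpm_threshold, min_samples_exceeding)

    tables: dict[str, pd.DataFrame] = {}
    for method in ("tmm", "median_of_ratios"):
        factors: NormFactors = (
            tmm_factors(kept) if method == "tmm" else median_of_ratios_factors(kept)
        )
        offsets = np.log(factors.effective_lib_sizes.to_numpy(dtype=float))
        tables[method] = _run_engine(kept.counts, kept.samples, contrast, offsets, prior_df)

    if lengths is None:
        lengths = pd.Series(22.0, index=kept.counts.index)
    tpm = tpm_normalize(kept, lengths)
    depth = kept.lib_sizes.to_numpy(dtype=float)
    pseudo = np.rint(tpm.to_numpy() * depth[None, :] / 1e6).astype("int64")
    pseudo_df = pd.DataFrame(pseudo, index=kept.counts.index, columns=kept.counts.columns)
    offsets = np.log(pseudo_df.sum(axis=0).to_numpy(dtype=float))
    tables["tpm"] = _run_engine(pseudo_df, kept.samples, contrast, offsets, prior_df)

    de_sets: dict[float, dict[str, set[str]]] = {}
    overlaps: dict[float, dict[tuple[str, ...], set[str]]] = {}
    for thr in (loose, strict):
        de_sets[thr] = {
            m: set(t.index[t["p_value"] < thr]) for m, t in tables.items()
        }
        overlaps[thr] = overlap_sets(de_sets[thr])
    return NormComparisonReport(
        tables=tables,
        de_sets=de_sets,
        overlaps=overlaps,
        tpm_strict=de_sets[strict]["tpm"],
    )
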