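"""Myobundle↔EV paired analyses: per-miR Pearson correlation within a
treatment, Venn-region set overlaps, and the preferential-expression
("informative missingness") procedure.

Preferential expression flags miRs that pass low-expressor filtering in
one compartment's matrix but not the other's — expression concentrated
in a single compartment that joint-matrix filtering would discard.
Flagged miRs are confirmed on raw counts with a repeated-measures
comparison across compartments (two within-levels over subject ×
treatment units, equivalent to a paired t-test and implemented as such)
followed, where significant, by paired t-tests within each treatment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import COMPARTMENTS, MirCountMatrix

__all__ = [
    "CorrelationResult",
    "compartment_correlation",
    "overlap_sets",
    "PreferentialSet",
    "preferential_expression",
]

ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one miR between compartments in one treatment.

    ``flag`` is "ok", "boundary" (|r| = 1, p reported as the smallest
    positive float) or "undefined" (zero variance in a compartment).
    """

    mir_id: str
    treatment: str
    r: float
    r_squared: float
    p_value: float
    n_pairs: int
    flag: str = "ok"


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0.0 or sy == 0.0:
        return np.nan, np.nan, "undefined"
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        return r, np.nextafter(0.0, 1.0), "boundary"
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, min(p, 1.0), "ok"


def compartment_correlation(
    norm_counts: pd.DataFrame,
    samples: pd.DataFrame,
    mir_subset: list[str] | None,
    treatment: str,
) -> pd.DataFrame:
    """Subject-paired MB-vs-EV Pearson correlation per miR in one treatment.

    ``norm_counts`` holds normalized (e.g. TMM-scaled CPM) values with
    one column per sample. Returns a table indexed by mir_id with
    columns r, r_squared, p_value, n_pairs, flag. Vectors are paired by
    subject; every subject must contribute one MB and one EV sample.
    """
    sel = samples[samples["treatment"] == treatment]
    subjects = sorted(sel["subject"].unique())
    mb_ids, ev_ids = [], []
    for s in subjects:
        for comp, bucket in zip(COMPARTMENTS, (mb_ids, ev_ids)):
            match = sel.index[(sel["subject"] == s) & (sel["compartment"] == comp)]
            if len(match) != 1:
                raise ValueError(
                    f"subject {s} has {len(match)} {comp} samples in {treatment}; need exactly 1"
                )
            bucket.append(match[0])
    if len(subjects) < 3:
        raise ValueError(f"need >=3 subject pairs, got {len(subjects)}")

    mirs = list(norm_counts.index) if mir_subset is None else list(mir_subset)
    rows = []
    for mir in mirs:
        x = norm_counts.loc[mir, mb_ids].to_numpy(dtype=float)
        y = norm_counts.loc[mir, ev_ids].to_numpy(dtype=float)
        r, p, flag = _pearson_with_p(x, y)
        rows.append((mir, r, r * r if np.isfinite(r) else np.nan, p, len(subjects), flag))
    return pd.DataFrame(
        rows, columns=["mir_id", "r", "r_squared", "p_value", "n_pairs", "flag"]
    ).set_index("mir_id")


def overlap_sets(named_sets: dict[str, set[str]]) -> dict[tuple[str, ...], set[str]]:
    """Exclusive Venn regions of 2–4 named sets.

    Region keys are sorted tuples of the set names whose intersection
    (minus all other sets) the region holds; the regions partition the
    union of all sets.
    """
    names = sorted(named_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError(f"overlap_sets supports 2-4 sets, got {len(names)}")
    regions: dict[tuple[str, ...], set[str]] = {}
    for k in range(len(names), 0, -1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set().union(*(named_sets[n] for n in names if n not in combo)) if k < len(names) else set()
            regions[combo] = inside - outside
    return regions


@dataclass
class PreferentialSet:
    """miRs preferentially expressed in one compartment.

    ``anova_p`` holds the repeated-measures across-treatment paired
    comparison p per miR (NaN where undefined); ``paired_t_p`` holds the
    per-treatment paired t p-values (rows miRs, columns treatments; NaN
    where not run or undefined).
    """

    compartment: str
    mir_ids: list[str]
    anova_p: pd.Series
    paired_t_p: pd.DataFrame


def _paired_t(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired t p-value; NaN when the differences have no variance."""
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        return np.nan
    t = d.mean() / (sd / np.sqrt(d.size))
    return float(2.0 * stats.t.sf(abs(t), d.size - 1))


def preferential_expression(
    joint_kept: set[str],
    mb_kept: set[str],
    ev_kept: set[str],
    raw_counts: MirCountMatrix,
    alpha: float = ALPHA,
) -> dict[str, PreferentialSet]:
    """Identify compartment-preferential miRs and test them on raw counts.

    A miR is MB-preferential when it passes the MB-only low-expressor
    filter but not the EV-only one (symmetrically for EV); miRs passing
    both compartment filters are never flagged. Each flagged miR gets a
    repeated-measures compartment comparison over subject × treatment
    units (paired t across all units); where that p < ``alpha``, paired
    t-tests MB vs EV within each treatment follow.
    """
    samples = raw_counts.samples
    treatments = sorted(samples["treatment"].unique())
    subjects = sorted(samples["subject"].unique())

    # subject × treatment paired sample ids
    units: list[tuple[str, str]] = []  # (mb_id, ev_id)
    unit_treatment: list[str] = []
    for t in treatments:
        for s in subjects:
            pair = []
            for comp in COMPARTMENTS:
                match = samples.index[
                    (samples["subject"] == s)
                    & (samples["treatment"] == t)
                    & (samples["compartment"] == comp)
                ]
                if len(match) != 1:
                    raise ValueError(f"subject {s}/{t} lacks a unique {comp} sample")
                pair.append(match[0])
            units.append((pair[0], pair[1]))
            unit_treatment.append(t)

    flagged = {
        "MB": sorted(mb_kept - ev_kept),
        "EV": sorted(ev_kept - mb_kept),
    }
    out: dict[str, PreferentialSet] = {}
    for comp, mirs in flagged.items():
        anova_p = pd.Series(np.nan, index=pd.Index(mirs, name="mir_id"), dtype=float)
        t_p = pd.DataFrame(np.nan, index=pd.Index(mirs, name="mir_id"), columns=treatments)
        for mir in mirs:
            row = raw_counts.counts.loc[mir]
            mb_all = np.array([row[m] for m, _ in units], dtype=float)
            ev_all = np.array([row[e] for _, e in units], dtype=float)
            anova_p[mir] = _paired_t(mb_all, ev_all)
            if np.isfinite(anova_p[mir]) and anova_p[mir] < alpha:
                for t in treatments:
                    idx = [i for i, ut in enumerate(unit_treatment) if ut == t]
                    t_p.loc[mir, t] = _paired_t(mb_all[idx], ev_all[idx])
        out[comp] = PreferentialSet(comp, mirs, anova_p, t_p)
    return out
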