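"""Paired-design negative-binomial differential expression with
quasi-likelihood F-tests.

Model
-----
Counts for miR g in sample j are modelled NB with mean
``mu_gj = exp(offset_j + x_j' beta_g)`` and dispersion ``phi_g``
(variance ``mu + phi mu^2``). Offsets are log effective library sizes
(library size × normalization factor). The design contains an
intercept, subject blocking indicators (the "within sample" pairing),
and group indicators; a contrast drops the group column(s) and compares
deviances.

Dispersion is estimated by maximizing the Cox–Reid adjusted profile
likelihood (APL): a common value over all miRs (log-spaced grid plus
golden-section refinement) and per-miR maximizers shrunk toward the
common value on the log scale with prior weight ``prior_df``.

The quasi-likelihood F-test scales the per-contrast deviance drop by an
empirical-Bayes-moderated quasi-dispersion (residual deviance over
residual df, squeezed toward the mean with ``prior_df``); p-values come
from an F distribution with (contrast df, residual df + prior df) and
are reported unadjusted (a Benjamini–Hochberg column is optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import COMPARTMENTS, TREATMENTS, MirCountMatrix
from .normalize import NormFactors, cpm, filter_low_expressors, tmm_factors

__all__ = [
    "build_design",
    "DispersionEstimates",
    "estimate_dispersions",
    "NBGLMFit",
    "fit_nb_glm",
    "ql_f_test",
    "run_all_contrasts",
    "AllContrastsResult",
]

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    samples: pd.DataFrame,
    group: str,
    levels: tuple[str, ...] | list[str] | None = None,
) -> pd.DataFrame:
    """Blocked design: intercept + subject indicators + group indicators.

    ``group`` names the metadata column carrying the factor of interest
    ("compartment" or "treatment"); ``levels`` fixes its level order,
    the first level being the baseline. Rows follow the sample sheet.
    """
    if group not in samples.columns:
        raise ValueError(f"sample sheet has no column {group!r}")
    subjects = sorted(samples["subject"].unique())
    if levels is None:
        levels = sorted(samples[group].unique())
    observed = set(samples[group])
    levels = [lv for lv in levels if lv in observed]
    if len(levels) < 2:
        raise ValueError(f"need >=2 {group} levels, got {levels}")
    if len(subjects) < 2:
        raise ValueError(f"need >=2 subjects, got {subjects}")
    unknown = observed - set(levels)
    if unknown:
        raise ValueError(f"{group} levels {sorted(unknown)} not in {levels}")

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(samples))}
    for s in subjects[1:]:
        cols[f"subject[{s}]"] = (samples["subject"] == s).to_numpy(dtype=float)
    for lv in levels[1:]:
        cols[f"{group}[{lv}]"] = (samples[group] == lv).to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=samples.index)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(
            f"design is rank deficient ({group} aliased with subject blocks)"
        )
    return design


def group_columns(design: pd.DataFrame, group: str) -> list[str]:
    """Names of the non-baseline indicator columns of ``group``."""
    return [c for c in design.columns if c.startswith(f"{group}[")]


# ---------------------------------------------------------------------------
# NB GLM via vectorized IRLS

_MAX_ITER = 50
_TOL = 1e-8


def _irls(
    y: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit one NB log-link GLM per gene, all genes in lockstep.

    y: (G, n); design: (n, p); offsets: (n,) or (G, n); phi: (G,).
    Returns (beta (G, p), mu (G, n), converged (G,)).
    """
    G, n = y.shape
    p = design.shape[1]
    o = np.broadcast_to(offsets, (G, n))
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))

    # small-count adjustment keeps the initial log well defined at y = 0
    mu = np.maximum(y, 0.125)
    eta = np.log(mu)
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)

    for _ in range(_MAX_ITER):
        w = mu / (1.0 + phi[:, None] * mu)
        z = (eta - o) + (y - mu) / mu
        xtwx = np.einsum("ni,gn,nj->gij", design, w, design, optimize=True)
        # tiny relative ridge keeps genes with an (almost) empty group solvable;
        # the pinned coefficient is degenerate there and the fit unaffected
        ridge = np.maximum(1e-10 * np.einsum("gii->g", xtwx) / p, 1e-30)
        xtwx += ridge[:, None, None] * np.eye(p)
        xtwz = np.einsum("ni,gn->gi", design, w * z, optimize=True)
        new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta) / (1.0 + np.abs(new_beta)), axis=1)
        beta = new_beta
        eta = np.clip(beta @ design.T + o, -30.0, 30.0)
        mu = np.exp(eta)
        newly = active & (delta < _TOL)
        converged |= newly
        active &= ~newly
        if not active.any():
            break
    return beta, mu, converged


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene residual deviance (Poisson limit at phi = 0)."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))[:, None]
    mu = np.maximum(mu, 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, 1e-10) / mu), 0.0)
    nb = np.where(
        phi > 0,
        (y + 1.0 / np.where(phi > 0, phi, 1.0))
        * np.log((1.0 + phi * y) / (1.0 + phi * mu)),
        y - mu,
    )
    return 2.0 * np.sum(ylogy - nb, axis=1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood (Poisson at phi = 0)."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))[:, None]
    mu = np.maximum(mu, 1e-10)
    poisson = y * np.log(mu) - mu - gammaln(y + 1.0)
    safe_phi = np.where(phi > 0, phi, 1.0)
    r = 1.0 / safe_phi
    nb = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return np.sum(np.where(phi > 0, nb, poisson), axis=1)


@dataclass
class NBGLMFit:
    """Per-miR NB GLM fits plus everything needed to refit reduced models."""

    counts: np.ndarray  # (G, n)
    design: pd.DataFrame  # (n, p)
    offsets: np.ndarray  # (n,)
    dispersion: np.ndarray  # (G,)
    mir_ids: list[str]
    coefficients: pd.DataFrame = field(init=False)  # (G, p)
    fitted: np.ndarray = field(init=False)  # (G, n)
    deviance: np.ndarray = field(init=False)  # (G,)
    converged: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        x = self.design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design matrix is rank deficient")
        beta, mu, conv = _irls(self.counts, x, self.offsets, self.dispersion)
        self.coefficients = pd.DataFrame(
            beta, index=self.mir_ids, columns=self.design.columns
        )
        self.fitted = mu
        self.deviance = nb_deviance(self.counts, mu, self.dispersion)
        self.converged = conv

    @property
    def residual_df(self) -> int:
        return self.design.shape[0] - self.design.shape[1]


def fit_nb_glm(
    counts: np.ndarray | pd.DataFrame,
    design: pd.DataFrame,
    offsets: np.ndarray,
    dispersion: float | np.ndarray,
) -> NBGLMFit:
    """Fit one NB log-link GLM per miR by IRLS."""
    if isinstance(counts, pd.DataFrame):
        mir_ids = list(counts.index)
        y = counts.to_numpy(dtype=float)
    else:
        y = np.asarray(counts, dtype=float)
        mir_ids = [f"g{i}" for i in range(y.shape[0])]
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],)).copy()
    return NBGLMFit(y, design, np.asarray(offsets, dtype=float), disp, mir_ids)


# ---------------------------------------------------------------------------
# dispersion estimation by Cox–Reid adjusted profile likelihood

_PHI_MIN, _PHI_MAX = 1e-6, 20.0


@dataclass
class DispersionEstimates:
    common: float
    tagwise: np.ndarray
    prior_df: float


def _apl(
    y: np.ndarray, x: np.ndarray, offsets: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Cox–Reid adjusted profile log-likelihood per gene at dispersion phi."""
    beta, mu, _ = _irls(y, x, offsets, phi)
    ll = nb_loglik(y, mu, phi)
    w = mu / (1.0 + np.broadcast_to(phi, (y.shape[0],))[:, None] * mu)
    xtwx = np.einsum("ni,gn,nj->gij", x, w, x, optimize=True)
    sign, logdet = np.linalg.slogdet(xtwx)
    return ll - 0.5 * logdet


def _golden_max(f, lo: np.ndarray, hi: np.ndarray, iters: int = 35) -> np.ndarray:
    """Vectorized golden-section maximization of f over [lo, hi] per gene.

    One f evaluation per iteration on the vector of per-gene probe
    points; all genes iterate in lockstep.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.asarray(lo, dtype=float).copy()
    b = np.asarray(hi, dtype=float).copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        left = fc >= fd  # keep [a, d]; otherwise keep [c, b]
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        surv = np.where(left, c, d)  # interior point that survives the cut
        f_surv = np.where(left, fc, fd)
        c_new = b - invphi * (b - a)
        d_new = a + invphi * (b - a)
        probe = np.where(left, c_new, d_new)
        f_probe = f(probe)
        c = np.where(left, c_new, surv)
        d = np.where(left, surv, d_new)
        fc = np.where(left, f_probe, f_surv)
        fd = np.where(left, f_surv, f_probe)
    return (a + b) / 2.0


def estimate_dispersions(
    counts: np.ndarray | pd.DataFrame,
    design: pd.DataFrame,
    offsets: np.ndarray,
    prior_df: float = 10.0,
    grid_size: int = 21,
) -> DispersionEstimates:
    """Common and tagwise NB dispersions by Cox–Reid APL.

    The common value maximizes the summed APL over a log-spaced grid on
    [1e-6, 20] refined by golden section. Tagwise values are per-miR APL
    maximizers shrunk toward the common value on the log scale with
    weight ``prior_df`` against the per-miR residual df.
    """
    y = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    if (y.sum(axis=1) == 0).any():
        raise ValueError("all-zero miR rows present; filter before dispersion estimation")
    x = design.to_numpy(dtype=float)
    G = y.shape[0]
    grid = np.logspace(np.log10(_PHI_MIN), np.log10(_PHI_MAX), grid_size)
    apl_grid = np.stack([_apl(y, x, offsets, np.full(G, g)) for g in grid])  # (grid, G)

    # common: bracket around the grid argmax of the summed APL, then refine
    total = apl_grid.sum(axis=1)
    k = int(np.argmax(total))
    lo = np.log(grid[max(k - 1, 0)])
    hi = np.log(grid[min(k + 1, grid_size - 1)])

    def f_common(logphi: np.ndarray) -> np.ndarray:
        out = np.empty_like(logphi)
        for i, lp in enumerate(np.atleast_1d(logphi)):
            out[i] = _apl(y, x, offsets, np.full(G, np.exp(lp))).sum()
        return out

    common = float(np.exp(_golden_max(f_common, np.array([lo]), np.array([hi]))[0]))

    # per-gene maximizers: per-gene bracket from the grid, lockstep refinement
    kg = np.argmax(apl_grid, axis=0)
    lo_g = np.log(grid[np.maximum(kg - 1, 0)])
    hi_g = np.log(grid[np.minimum(kg + 1, grid_size - 1)])

    def f_gene(logphi: np.ndarray) -> np.ndarray:
        return _apl(y, x, offsets, np.exp(logphi))

    phi_g = np.exp(_golden_max(f_gene, lo_g, hi_g))

    d = max(design.shape[0] - design.shape[1], 1)
    log_tag = (d * np.log(phi_g) + prior_df * np.log(common)) / (d + prior_df)
    tagwise = np.clip(np.exp(log_tag), _PHI_MIN, _PHI_MAX)
    return DispersionEstimates(common=common, tagwise=tagwise, prior_df=prior_df)


# ---------------------------------------------------------------------------
# quasi-likelihood F-test


def ql_f_test(
    fit: NBGLMFit,
    contrast: str | list[str],
    prior_df: float = 10.0,
    fdr: bool = False,
) -> pd.DataFrame:
    """Quasi-likelihood F-test for dropping the contrast column(s).

    Returns a table indexed by mir_id with columns log2_fc (single-
    coefficient contrasts; the first named coefficient otherwise),
    ave_log2_cpm, f_stat, p_value and optionally fdr (Benjamini–
    Hochberg, off by default to match the unadjusted-p design).
    """
    drop = [contrast] if isinstance(contrast, str) else list(contrast)
    missing = [c for c in drop if c not in fit.design.columns]
    if missing:
        raise ValueError(f"contrast columns not in design: {missing}")
    d = fit.residual_df
    if d <= 0:
        raise ValueError("residual df <= 0: design saturates the data")

    reduced_design = fit.design.drop(columns=drop)
    reduced = NBGLMFit(
        fit.counts, reduced_design, fit.offsets, fit.dispersion, fit.mir_ids
    )
    df1 = len(drop)
    drop_dev = np.maximum(reduced.deviance - fit.deviance, 0.0)
    # deviances carry IRLS convergence noise ~1e-8; treat smaller drops as zero
    drop_dev[drop_dev < 1e-8 * (1.0 + np.abs(fit.deviance))] = 0.0

    s2 = fit.deviance / d  # quasi-dispersion
    s2_prior = float(np.mean(s2))
    # floor far below any real quasi-dispersion, protecting saturated fits
    s2_post = np.maximum((prior_df * s2_prior + d * s2) / (prior_df + d), 1e-6)
    f_stat = (drop_dev / df1) / s2_post
    p = stats.f.sf(f_stat, df1, d + prior_df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    lib = np.exp(fit.offsets)
    ave = np.log2(np.mean((fit.counts + 0.5) / lib, axis=1) * 1e6)
    table = pd.DataFrame(
        {
            "log2_fc": fit.coefficients[drop[0]].to_numpy() / LN2,
            "ave_log2_cpm": ave,
            "f_stat": f_stat,
            "p_value": p,
        },
        index=pd.Index(fit.mir_ids, name="mir_id"),
    )
    ok = fit.converged & reduced.converged
    if not ok.all():
        table = table.loc[ok]
    if fdr:
        table["fdr"] = stats.false_discovery_control(table["p_value"], method="bh")
    return table


# ---------------------------------------------------------------------------
# the dual-normalization contrast plan


@dataclass
class AllContrastsResult:
    """All differential-expression tables plus the filtered-id sets.

    ``within_treatment`` maps treatment → MB-vs-EV table (positive
    log2_fc = higher in myobundles). ``between_treatment`` maps
    (compartment, "AvsB") → table. The three kept-id sets record which
    miRs survived low-expressor filtering on the joint, MB-only and
    EV-only matrices — the inputs of the preferential-expression stage.
    """

    within_treatment: dict[str, pd.DataFrame]
    between_treatment: dict[tuple[str, str], pd.DataFrame]
    joint_kept: set[str]
    mb_kept: set[str]
    ev_kept: set[str]
    joint_matrix: MirCountMatrix
    joint_factors: NormFactors
    anova_like: dict[str, pd.DataFrame] = field(default_factory=dict)


def _de_for_subset(
    matrix: MirCountMatrix,
    factors: NormFactors,
    sample_ids: list[str],
    group: str,
    levels: tuple[str, ...],
    prior_df: float,
    fdr: bool,
) -> pd.DataFrame:
    sub = matrix.subset_samples(sample_ids)
    design = build_design(sub.samples, group, levels)
    offsets = np.log(factors.effective_lib_sizes.loc[sample_ids].to_numpy(dtype=float))
    keep = sub.counts.sum(axis=1) > 0  # subsetting can create all-zero rows
    counts = sub.counts.loc[keep]
    disp = estimate_dispersions(counts, design, offsets, prior_df=prior_df)
    fit = fit_nb_glm(counts, design, offsets, disp.tagwise)
    cols = group_columns(design, group)
    return ql_f_test(fit, cols, prior_df=prior_df, fdr=fdr)


def run_all_contrasts(
    counts: MirCountMatrix,
    cpm_threshold: float = 0.5,
    min_samples_exceeding: int = 2,
    prior_df: float = 10.0,
    fdr: bool = False,
    all_groups_f: bool = False,
) -> AllContrastsResult:
    """Run the full dual-normalization contrast plan.

    Within-treatment MB-vs-EV contrasts use filtering and TMM on the
    joint matrix; between-treatment contrasts use filtering and TMM
    separately on the MB-only and EV-only matrices. With
    ``all_groups_f`` an across-all-treatments F-test per compartment is
    added under ``anova_like``.
    """
    treatments = [t for t in TREATMENTS if t in set(counts.samples["treatment"])]
    if len(treatments) < 2 or set(counts.samples["compartment"]) != set(COMPARTMENTS):
        raise ValueError("need both compartments and >=2 treatments")

    joint, _ = filter_low_expressors(counts, cpm_threshold, min_samples_exceeding)
    joint_factors = tmm_factors(joint)
    within: dict[str, pd.DataFrame] = {}
    for t in treatments:
        ids = list(joint.samples.index[joint.samples["treatment"] == t])
        within[t] = _de_for_subset(
            joint, joint_factors, ids, "compartment", ("EV", "MB"), prior_df, fdr
        )

    between: dict[tuple[str, str], pd.DataFrame] = {}
    anova_like: dict[str, pd.DataFrame] = {}
    kept: dict[str, set[str]] = {}
    pairs = [(b, a) for i, a in enumerate(treatments) for b in treatments[i + 1:]]
    for comp in COMPARTMENTS:
        comp_matrix, _ = filter_low_expressors(
            counts.select(compartment=comp), cpm_threshold, min_samples_exceeding
        )
        kept[comp] = set(comp_matrix.mir_ids)
        comp_factors = tmm_factors(comp_matrix)
        for hi, lo in pairs:
            ids = list(
                comp_matrix.samples.index[comp_matrix.samples["treatment"].isin([hi, lo])]
            )
            between[(comp, f"{hi}vs{lo}")] = _de_for_subset(
                comp_matrix, comp_factors, ids, "treatment", (lo, hi), prior_df, fdr
            )
        if all_groups_f:
            ids = list(comp_matrix.samples.index)
            anova_like[comp] = _de_for_subset(
                comp_matrix, comp_factors, ids, "treatment", tuple(treatments), prior_df, fdr
            )

    return AllContrastsResult(
        within_treatment=within,
        between_treatment=between,
        joint_kept=set(joint.mir_ids),
        mb_kept=kept["MB"],
        ev_kept=kept["EV"],
        joint_matrix=joint,
        joint_factors=joint_factors,
        anova_like=anova_like,
    )
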