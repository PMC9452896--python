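"""Synthetic data for every pipeline stage.

Two generators:

* :func:`simulate_counts` draws NB miR × sample count matrices under the
  study design — subjects × two compartments (myobundle tissue, MB, and
  secreted extracellular vesicles, EV) × three electrical-stimulation
  treatments (CTL, CLFS, IHFS) — with planted treatment and compartment
  fold changes, compartment-exclusive miRs (informative missingness),
  and MB–EV correlation induced by shared per-subject effects.
* :func:`simulate_alignments` writes toy SAM + GFF3 fixtures whose reads
  exercise every read-assignment outcome (multimapping beyond the cap,
  5'-anchor shifts, 3'-end variation inside and outside the tolerance,
  strand flips, PCR-duplicate UMIs) together with the true molecule
  counts obtained by a deliberately naive, independent application of
  the counting rules.

:func:`calibration_experiment` runs type-I, power, fold-change-recovery
and correlation-recovery simulations through the real pipeline stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import COMPARTMENTS, TREATMENTS, MatureMirRecord, MirCountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "SimulatedAlignments",
    "simulate_alignments",
    "calibration_experiment",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the count simulator.

    ``mean_log_expression`` are natural-log mean/sd of the log-normal
    per-miR baseline, interpreted as expected counts at reference depth;
    ``lib_size_range`` bounds the uniform per-sample depth multipliers
    (relative to the geometric mean of the range). Fractions partition
    the miRs into disjoint planted classes.
    """

    seed: int = 0
    n_subjects: int = 3
    treatments: tuple[str, ...] = TREATMENTS
    n_mirs: int = 991
    mean_log_expression: tuple[float, float] = (math.log(30.0), 1.5)
    dispersion: float = 0.1
    lib_size_range: tuple[int, int] = (800_000, 1_600_000)
    frac_de: float = 0.0  # treatment effects, one (treatment, compartment) each
    frac_compartment_de: float = 0.0  # MB-vs-EV effects across all treatments
    planted_log2fc: float = 2.0
    frac_mb_exclusive: float = 0.0
    frac_ev_exclusive: float = 0.0
    exclusive_leak: float = 0.0  # 0 = hard zeroing; >0 = tiny leaky mean fraction
    planted_corr: float = 0.0  # shared-subject fraction of biological variance
    bio_sd: float = 0.0  # per-(miR, sample) biological log-sd; must be > 0 to plant correlation

    def __post_init__(self) -> None:
        fracs = (
            self.frac_de
            + self.frac_compartment_de
            + self.frac_mb_exclusive
            + self.frac_ev_exclusive
        )
        if fracs > 1.0 + 1e-12:
            raise ValueError(f"planted fractions sum to {fracs} > 1")
        if not 0.0 <= self.planted_corr <= 1.0:
            raise ValueError("planted_corr must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_subjects < 2:
            raise ValueError("need >= 2 subjects")
        if self.planted_corr > 0 and self.bio_sd <= 0:
            raise ValueError("planting MB-EV correlation requires bio_sd > 0")


@dataclass
class SimTruth:
    """Planted parameters paired with a simulated dataset.

    ``per_mir`` has columns true_log2fc, exclusivity (none/MB/EV),
    corr_group; ``de_flags`` is a boolean miR × contrast table (columns
    like ``MBvsEV`` and ``MB_CLFSvsCTL``).
    """

    config: SimConfig
    per_mir: pd.DataFrame
    de_flags: pd.DataFrame


def simulate_counts(config: SimConfig) -> tuple[MirCountMatrix, pd.DataFrame, SimTruth]:
    """Draw one NB count matrix under the study design.

    Returns (matrix, sample sheet, truth); the same seed reproduces the
    same output exactly.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    subjects = [f"S{i + 1}" for i in range(config.n_subjects)]
    rows = [
        (f"{s}_{c}_{t}", s, c, t)
        for t in config.treatments
        for c in COMPARTMENTS
        for s in subjects
    ]
    samples = pd.DataFrame(
        rows, columns=["sample_id", "subject", "compartment", "treatment"]
    ).set_index("sample_id")
    mir_ids = [f"sim-miR-{i + 1}" for i in range(config.n_mirs)]
    G, n = config.n_mirs, len(samples)

    mu_log, sd_log = config.mean_log_expression
    baseline = rng.lognormal(mu_log, sd_log, size=G)

    # planted classes: disjoint, assigned from a seeded permutation
    perm = rng.permutation(G)
    n_de = round(config.frac_de * G)
    n_cde = round(config.frac_compartment_de * G)
    n_mbx = round(config.frac_mb_exclusive * G)
    n_evx = round(config.frac_ev_exclusive * G)
    idx_de = perm[:n_de]
    idx_cde = perm[n_de : n_de + n_cde]
    idx_mbx = perm[n_de + n_cde : n_de + n_cde + n_mbx]
    idx_evx = perm[n_de + n_cde + n_mbx : n_de + n_cde + n_mbx + n_evx]

    exclusivity = np.array(["none"] * G, dtype=object)
    exclusivity[idx_mbx] = "MB"
    exclusivity[idx_evx] = "EV"
    true_lfc = np.zeros(G)
    true_lfc[idx_de] = config.planted_log2fc
    true_lfc[idx_cde] = config.planted_log2fc

    non_ctl = [t for t in config.treatments if t != "CTL"] or list(config.treatments)
    contrasts = ["MBvsEV"] + [
        f"{c}_{t}vsCTL" for c in COMPARTMENTS for t in non_ctl if t != "CTL"
    ]
    de_flags = pd.DataFrame(False, index=pd.Index(mir_ids, name="mir_id"), columns=contrasts)

    # treatment-DE miRs: one random (non-CTL treatment, compartment) each
    de_treat = rng.choice(non_ctl, size=n_de) if n_de else np.array([], dtype=object)
    de_comp = rng.choice(COMPARTMENTS, size=n_de) if n_de else np.array([], dtype=object)
    for i, t, c in zip(idx_de, de_treat, de_comp):
        if t != "CTL":
            de_flags.iloc[i, de_flags.columns.get_loc(f"{c}_{t}vsCTL")] = True
    # compartment-DE miRs: random direction, active in every treatment
    cde_comp = rng.choice(COMPARTMENTS, size=n_cde) if n_cde else np.array([], dtype=object)
    de_flags.iloc[idx_cde, de_flags.columns.get_loc("MBvsEV")] = True

    # biological effects: shared-subject component induces MB–EV correlation
    rho = config.planted_corr
    z_subject = rng.normal(size=(G, config.n_subjects))
    z_sample = rng.normal(size=(G, n))
    subj_idx = np.array([subjects.index(s) for s in samples["subject"]])
    log_bio = config.bio_sd * (
        math.sqrt(rho) * z_subject[:, subj_idx] + math.sqrt(1.0 - rho) * z_sample
    )

    depth = rng.integers(config.lib_size_range[0], config.lib_size_range[1] + 1, size=n)
    depth_ref = math.sqrt(config.lib_size_range[0] * config.lib_size_range[1])
    scale = depth / depth_ref

    mu = baseline[:, None] * np.exp(log_bio) * scale[None, :]
    comp = samples["compartment"].to_numpy()
    treat = samples["treatment"].to_numpy()
    fold = 2.0 ** config.planted_log2fc
    for i, t, c in zip(idx_de, de_treat, de_comp):
        mu[i, (treat == t) & (comp == c)] *= fold
    for i, c in zip(idx_cde, cde_comp):
        mu[i, comp == c] *= fold
    leak = config.exclusive_leak
    mu[np.ix_(idx_mbx, np.flatnonzero(comp == "EV"))] *= leak
    mu[np.ix_(idx_evx, np.flatnonzero(comp == "MB"))] *= leak

    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=mu.shape) * config.dispersion * mu, 0.0)
    else:
        lam = mu
    counts = rng.poisson(lam)

    matrix = MirCountMatrix(
        pd.DataFrame(counts, index=pd.Index(mir_ids, name="mir_id"), columns=samples.index),
        samples,
    )
    per_mir = pd.DataFrame(
        {
            "true_log2fc": true_lfc,
            "exclusivity": exclusivity,
            "corr_group": rho > 0,
        },
        index=pd.Index(mir_ids, name="mir_id"),
    )
    # record the planted direction for compartment-DE miRs as a signed log2FC
    for i, c in zip(idx_cde, cde_comp):
        per_mir.iloc[i, 0] = config.planted_log2fc if c == "MB" else -config.planted_log2fc
    return matrix, samples, SimTruth(config, per_mir, de_flags)


# ---------------------------------------------------------------------------
# toy alignments


@dataclass
class SimulatedAlignments:
    sam_text: str
    gff_text: str
    truth: pd.Series  # deduplicated molecule count per mir_id
    loci: list[MatureMirRecord]


def simulate_alignments(
    n_loci: int = 10,
    n_reads: int = 200,
    p_multimap: float = 0.1,
    p_shift3: float = 0.2,
    p_shift5: float = 0.1,
    p_dup_umi: float = 0.2,
    p_strand_flip: float = 0.05,
    seed: int = 0,
    max_hits: int = 13,
    max_3p_var: int = 2,
) -> SimulatedAlignments:
    """Generate a toy SAM + GFF3 fixture with known true counts.

    Corruption probabilities control how many reads multimap (NH drawn
    from 2–20, so some exceed the cap), carry a shifted 5' terminus,
    vary at the 3' end by 1–4 nt, flip strand, or duplicate the
    previous read's coordinates and UMI. The bundled truth applies the
    counting rules by naive exhaustive enumeration, independent of the
    quantification module.
    """
    for p in (p_multimap, p_shift3, p_shift5, p_dup_umi, p_strand_flip):
        if not 0.0 <= p <= 1.0:
            raise ValueError("corruption rates must be in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    chroms = ["chr1", "chr2", "chr3"]

    loci: list[MatureMirRecord] = []
    for k in range(n_loci):
        chrom = chroms[k % len(chroms)]
        start = 1_000 + (k // len(chroms)) * 500
        length = int(rng.integers(20, 27))
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(
            MatureMirRecord.from_locus(f"sim-miR-{k + 1}", chrom, strand, start, start + length - 1)
        )

    bases = "ACGT"
    reads: list[tuple[str, str, str, int, int, str, int]] = []
    # (read_id, umi, chrom, start, end, strand, n_hits)
    for i in range(n_reads):
        if reads and rng.random() < p_dup_umi:
            prev = reads[-1]
            reads.append((f"R{i + 1}", prev[1], prev[2], prev[3], prev[4], prev[5], prev[6]))
            continue
        locus = loci[int(rng.integers(len(loci)))]
        start, end, strand = locus.start, locus.end, locus.strand
        if rng.random() < p_shift3:
            delta = int(rng.integers(1, max_3p_var + 3)) * (1 if rng.random() < 0.5 else -1)
            if strand == "+":
                end = max(end + delta, start + 1)
            else:
                start = min(start - delta, end - 1)
        if rng.random() < p_shift5:
            delta = int(rng.integers(1, 4))
            if strand == "+":
                start = min(start + delta, end)
            else:
                end = max(end - delta, start)
        if rng.random() < p_strand_flip:
            strand = "-" if strand == "+" else "+"
        n_hits = int(rng.integers(2, 21)) if rng.random() < p_multimap else 1
        umi = "".join(bases[b] for b in rng.integers(0, 4, size=6))
        reads.append((f"R{i + 1}", umi, locus.chrom, start, end, strand, n_hits))

    gff_lines = ["##gff-version 3"]
    for m in loci:
        gff_lines.append(
            f"{m.chrom}\t.\tmiRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={m.mir_id};Name={m.mir_id}"
        )
    sam_lines = ["@HD\tVN:1.6\tSO:unsorted"] + [f"@SQ\tSN:{c}\tLN:1000000" for c in chroms]
    for read_id, umi, chrom, start, end, strand, n_hits in reads:
        length = end - start + 1
        sam_lines.append(
            "\t".join(
                [
                    f"{read_id}_{umi}",
                    "16" if strand == "-" else "0",
                    chrom,
                    str(start),
                    "255",
                    f"{length}M",
                    "*",
                    "0",
                    "0",
                    "A" * length,
                    "*",
                    f"NH:i:{n_hits}",
                ]
            )
        )

    truth = _brute_force_counts(reads, loci, max_hits, max_3p_var)
    return SimulatedAlignments(
        sam_text="\n".join(sam_lines) + "\n",
        gff_text="\n".join(gff_lines) + "\n",
        truth=truth,
        loci=loci,
    )


def _brute_force_counts(
    reads: list[tuple[str, str, str, int, int, str, int]],
    loci: list[MatureMirRecord],
    max_hits: int,
    max_3p_var: int,
) -> pd.Series:
    """Naive, exhaustive application of the counting rules (the oracle)."""
    counts: dict[str, set[tuple]] = {m.mir_id: set() for m in loci}
    for _read_id, umi, chrom, start, end, strand, n_hits in reads:
        if n_hits > max_hits:
            continue
        for m in loci:
            if m.chrom != chrom or m.strand != strand:
                continue
            if end < m.start or start > m.end:
                continue
            read_5p = start if strand == "+" else end
            read_3p = end if strand == "+" else start
            mir_5p = m.start if m.strand == "+" else m.end
            mir_3p = m.end if m.strand == "+" else m.start
            if read_5p != mir_5p:
                continue
            if abs(read_3p - mir_3p) > max_3p_var:
                continue
            counts[m.mir_id].add((chrom, strand, start, end, umi))
    return pd.Series(
        {m.mir_id: len(counts[m.mir_id]) for m in loci}, name="count", dtype="int64"
    )


# ---------------------------------------------------------------------------
# calibration experiments


def _null_layout(config: SimConfig) -> SimConfig:
    """Single-treatment 3 subjects × 2 compartments layout for calibration."""
    return replace(config, treatments=("CTL",))


def _de_mb_vs_ev(matrix: MirCountMatrix, prior_df: float = 10.0) -> pd.DataFrame:
    """Filter + TMM + dispersion + QL F-test of MB vs EV on one matrix."""
    from .differential import build_design, estimate_dispersions, fit_nb_glm, ql_f_test
    from .normalize import filter_low_expressors, tmm_factors

    kept, _ = filter_low_expressors(matrix)
    factors = tmm_factors(kept)
    design = build_design(kept.samples, "compartment", ("EV", "MB"))
    offsets = np.log(factors.effective_lib_sizes.to_numpy(dtype=float))
    disp = estimate_dispersions(kept.counts, design, offsets, prior_df=prior_df)
    fit = fit_nb_glm(kept.counts, design, offsets, disp.tagwise)
    return ql_f_test(fit, "compartment[MB]", prior_df=prior_df)


def calibration_experiment(
    kind: str,
    config: SimConfig | None = None,
    n_reps: int = 1,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Run a calibration simulation through the real pipeline stages.

    kinds: ``type1`` (null rejection rate and p-value uniformity),
    ``power`` (detection rate of planted effects), ``fc_recovery``
    (median estimated log2FC of planted miRs), ``corr_recovery`` (mean
    Pearson r on length-50 pairs with planted r = 0.9). Monte-Carlo
    standard errors accompany the rates.
    """
    from scipy import stats as sps

    if kind == "type1":
        config = config or SimConfig(n_mirs=2000, dispersion=0.1)
        config = _null_layout(replace(config, frac_de=0.0, frac_compartment_de=0.0))
        pvals = []
        for rep in range(n_reps):
            matrix, _, _ = simulate_counts(replace(config, seed=config.seed + rep))
            pvals.append(_de_mb_vs_ev(matrix)["p_value"].to_numpy())
        p = np.concatenate(pvals)
        rate = float(np.mean(p < alpha))
        ks = float(sps.kstest(p, "uniform").statistic)
        return {
            "rejection_rate": rate,
            "mc_se": float(np.sqrt(rate * (1 - rate) / p.size)),
            "ks_distance": ks,
            "n_tests": float(p.size),
        }

    if kind in ("power", "fc_recovery"):
        config = config or SimConfig(
            n_mirs=2000,
            mean_log_expression=(math.log(100.0), 0.25),
            dispersion=0.05,
            frac_compartment_de=0.25,
            planted_log2fc=2.0,
        )
        config = _null_layout(config)
        detected, errors = [], []
        for rep in range(n_reps):
            matrix, _, truth = simulate_counts(replace(config, seed=config.seed + rep))
            table = _de_mb_vs_ev(matrix)
            planted = truth.de_flags.index[truth.de_flags["MBvsEV"]]
            planted = [m for m in planted if m in table.index]
            sub = table.loc[planted]
            signed = truth.per_mir.loc[planted, "true_log2fc"]
            detected.append((sub["p_value"] < alpha).to_numpy())
            errors.append((sub["log2_fc"] - signed).to_numpy())
        det = np.concatenate(detected)
        err = np.concatenate(errors)
        rate = float(det.mean())
        return {
            "detection_rate": rate,
            "mc_se": float(np.sqrt(rate * (1 - rate) / det.size)),
            "median_log2fc_error": float(np.median(err)),
            "n_planted": float(det.size),
        }

    if kind == "corr_recovery":
        config = config or SimConfig()
        rng = np.random.Generator(np.random.PCG64(config.seed))
        rho, n = 0.9, 50
        # shared + independent components: corr = 1 / (1 + s^2) with s the
        # independent-noise scale, so s = sqrt(1/rho - 1)
        noise = math.sqrt(1.0 / rho - 1.0)
        rs = []
        for _ in range(max(n_reps, 1)):
            z = rng.normal(size=n)
            x = z + rng.normal(scale=noise, size=n)
            y = z + rng.normal(scale=noise, size=n)
            rs.append(float(np.corrcoef(x, y)[0, 1]))
        rs = np.asarray(rs)
        return {
            "mean_r": float(rs.mean()),
            "mc_se": float(rs.std(ddof=1) / np.sqrt(rs.size)) if rs.size > 1 else 0.0,
            "planted_r": rho,
            "n_reps": float(rs.size),
        }

    raise ValueError(f"unknown calibration kind {kind!r}")
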