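"""Independent brute-force oracles used only by the tests.

Each oracle is deliberately naive (explicit loops, exhaustive
enumeration, closed forms) and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

import itertools
import math


def brute_force_quantify(reads, loci, max_hits=13, max_3p_var=2):
    """Exhaustive per-read rule evaluation + tuple dedup.

    ``reads``: iterables with attributes (umi, chrom, strand, start, end,
    n_hits); ``loci``: records with (mir_id, chrom, strand, start, end).
    Returns dict mir_id -> molecule count.
    """
    molecules = {m.mir_id: set() for m in loci}
    for r in reads:
        if r.n_hits > max_hits:
            continue
        for m in loci:
            if m.chrom != r.chrom or m.strand != r.strand:
                continue
            if r.end < m.start or r.start > m.end:
                continue
            r5 = r.start if r.strand == "+" else r.end
            r3 = r.end if r.strand == "+" else r.start
            m5 = m.start if m.strand == "+" else m.end
            m3 = m.end if m.strand == "+" else m.start
            if r5 != m5 or abs(r3 - m3) > max_3p_var:
                continue
            molecules[m.mir_id].add((r.chrom, r.strand, r.start, r.end, r.umi))
    return {mid: len(s) for mid, s in molecules.items()}


def _avg_ranks(values):
    """Average ranks (1-based) with ties, by explicit sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_oracle(counts, trim_m=0.3, trim_a=0.05):
    """Direct loop evaluation of the doubly-trimmed weighted mean of
    M-values; ``counts`` is a list of per-gene lists (genes x samples).
    Returns the list of per-sample factors, geometric mean 1."""
    n_samples = len(counts[0])
    lib = [sum(row[j] for row in counts) for j in range(n_samples)]
    # reference: upper quartile of scaled counts closest to the mean
    uqs = []
    for j in range(n_samples):
        scaled = sorted(row[j] / lib[j] for row in counts)
        # linear-interpolation 75th percentile, matching numpy's default
        h = (len(scaled) - 1) * 0.75
        lo = math.floor(h)
        uqs.append(scaled[lo] + (h - lo) * (scaled[min(lo + 1, len(scaled) - 1)] - scaled[lo]))
    mean_uq = sum(uqs) / n_samples
    ref = min(range(n_samples), key=lambda j: abs(uqs[j] - mean_uq))

    log_factors = []
    for j in range(n_samples):
        if j == ref:
            log_factors.append(0.0)
            continue
        ms, As, ws = [], [], []
        for row in counts:
            o, r = row[j], row[ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                ms.append(math.log2(po / pr))
                As.append(0.5 * math.log2(po * pr))
                ws.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        n = len(ms)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = _avg_ranks(ms)
        ra = _avg_ranks(As)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += ms[i] / ws[i]
                den += 1.0 / ws[i]
        f = num / den if den > 0 else 0.0
        if abs(f) < 1e-10:
            f = 0.0
        log_factors.append(f)
    factors = [2.0**f for f in log_factors]
    geo = math.exp(sum(math.log(f) for f in factors) / n_samples)
    return [f / geo for f in factors]


def hypergeom_enumeration(universe, pathway, hits_size, observed):
    """P(X >= observed) by exhaustive enumeration of all hit subsets.

    Feasible for |universe| <= 15. ``pathway`` is a subset of ``universe``.
    """
    universe = sorted(universe)
    pathway = set(pathway)
    total = success = 0
    for combo in itertools.combinations(universe, hits_size):
        total += 1
        if len(pathway & set(combo)) >= observed:
            success += 1
    return success / total
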