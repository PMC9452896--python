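"""Over-representation analysis of a significant-miR set against
pathway→miR sets by the one-sided (upper-tail) hypergeometric test.

The universe is the pre-filtering miR catalogue; pathway sets are
intersected with it before testing. Pathways are ranked by observed hit
count (ties broken by ascending p), and p-values are reported
unadjusted by default.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = ["ora_hypergeometric"]


def ora_hypergeometric(
    hits: Iterable[str],
    universe: Iterable[str],
    pathways: Mapping[str, Iterable[str]],
    fdr: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each pathway.

    For a pathway with k members inside the universe of size M and a
    hit set of size N, observed = |hits ∩ pathway| and
    p = P(X >= observed) for X ~ Hypergeom(M, k, N); expected = N*k/M.
    Returns a table sorted by observed (descending), ties by ascending p.
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    stray = sorted(hits - universe)
    if stray:
        raise ValueError(f"hits outside the universe: {stray}")

    rows = []
    for name, members in pathways.items():
        inside = set(members) & universe
        observed = len(hits & inside)
        expected = len(hits) * len(inside) / len(universe)
        p = float(stats.hypergeom.sf(observed - 1, len(universe), len(inside), len(hits)))
        rows.append((name, observed, len(inside), expected, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["pathway", "observed", "pathway_size", "expected", "p_value"]
    )
    table = table.sort_values(
        ["observed", "p_value", "pathway"], ascending=[False, True, True]
    ).set_index("pathway")
    if fdr:
        table["fdr"] = stats.false_discovery_control(table["p_value"], method="bh")
    return table
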