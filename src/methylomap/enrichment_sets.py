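"""Set-overlap significance and gene-set over-representation analysis.

The overlap test asks: drawing |b| items from a universe of size M of which
|a| are marked, how often do at least the observed number land in the marked
set?  That one-sided hypergeometric tail is identical to a one-sided
Fisher's exact test on the corresponding 2x2 table.  ORA applies the same
test per gene set with Benjamini-Hochberg correction across sets.

The universe must always be supplied explicitly: an overlap p-value is
meaningless without saying what could have been drawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class OverlapTest:
    n_universe: int
    n_a: int
    n_b: int
    overlap: int
    p_value: float


def _check_subset(name: str, s: set, universe: set) -> None:
    extra = s - universe
    if extra:
        shown = sorted(extra)[:10]
        raise ValueError(
            f"{name} not a subset of the universe; offenders include {shown}"
        )


def hypergeom_overlap(
    a: Iterable[str], b: Iterable[str], universe: Iterable[str]
) -> OverlapTest:
    """One-sided (enrichment) hypergeometric tail for the overlap of two sets.

    p = P[X >= |a ∩ b|] with X ~ Hypergeometric(M=|universe|, K=|a|, n=|b|).
    """
    a, b, universe = set(a), set(b), set(universe)
    _check_subset("set_a", a, universe)
    _check_subset("set_b", b, universe)
    k = len(a & b)
    M, K, n = len(universe), len(a), len(b)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    return OverlapTest(M, K, n, k, min(p, 1.0))


def ora(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of *query* in each gene set, BH-corrected.

    Gene sets are intersected with the universe before testing.  Returns a
    DataFrame sorted by p with columns: set_name, set_size, overlap,
    expected, p_value, bh_q.
    """
    query, universe = set(query), set(universe)
    if not query:
        raise ValueError("empty query set")
    _check_subset("query", query, universe)

    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        test = hypergeom_overlap(query, members, universe)
        expected = len(query) * len(members) / len(universe)
        rows.append(
            {
                "set_name": name,
                "set_size": len(members),
                "overlap": test.overlap,
                "expected": expected,
                "p_value": test.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        _, q, _, _ = multipletests(out["p_value"], method="fdr_bh")
        out["bh_q"] = q
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out
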