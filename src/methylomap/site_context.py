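"""Site-context statistics: phospho-proximity with a resampled arginine
null, and cancer-mutation enrichment at or near methyl sites.

Two-sided Fisher's exact p-values are computed by exact integer arithmetic
over the hypergeometric distribution of tables with fixed margins: the
p-value is the summed probability of every table whose point probability is
at most the observed table's.  Working in integers avoids tie-breaking
artifacts from floating-point point-probability comparisons.

The mutation table is collapsed to a binary "position mutated at least
once" indicator for rate computation; raw counts are kept for reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ProteomeDB
from .sequence_context import all_arginine_sites

logger = logging.getLogger(__name__)

PROXIMITY_BINS = ("0", "1", "2", "3", "4+")


# ---------------------------------------------------------------------------
# exact tests


def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table ``[[a, b], [c, d]]``.

    Returns ``(odds_ratio, p)``.  The p-value sums, over all tables with the
    observed margins, the probabilities of tables whose point probability
    does not exceed the observed one; the comparison is done on exact
    integer weights.  A zero margin is degenerate: p = 1 and the odds ratio
    is NaN.  The odds ratio is a*d / (b*c), infinite when b*c = 0.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"counts must be non-negative integers, got {x}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        logger.warning("degenerate 2x2 margins; p = 1, odds ratio undefined")
        return float("nan"), 1.0
    odds = math.inf if b * c == 0 else (a * d) / (b * c)

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    # integer weights proportional to the hypergeometric point probabilities
    weights = [
        math.comb(c1, x) * math.comb(n - c1, r1 - x) for x in range(lo, hi + 1)
    ]
    observed = weights[a - lo]
    numer = sum(w for w in weights if w <= observed)
    p = numer / sum(weights)
    return odds, min(float(p), 1.0)


@dataclass(frozen=True)
class EnrichmentResult:
    rate_fg: float
    rate_bg: float
    odds_ratio: float
    p_value: float
    table: tuple[int, int, int, int]  # a=fg mutated, b=fg not, c=bg mutated, d=bg not


# ---------------------------------------------------------------------------
# phospho proximity


@dataclass
class PhosphoProximityResult:
    per_site: pd.DataFrame  # protein, position, n_phospho
    bin_fractions: dict[str, float]
    frac_ge1: float


def _bin_fractions(counts: np.ndarray) -> dict[str, float]:
    n = float(len(counts))
    out = {
        "0": float((counts == 0).sum()) / n,
        "1": float((counts == 1).sum()) / n,
        "2": float((counts == 2).sum()) / n,
        "3": float((counts == 3).sum()) / n,
        "4+": float((counts >= 4).sum()) / n,
    }
    return out


def phospho_proximity(
    methyl_sites: Iterable[tuple[str, int]],
    phospho_sites: pd.DataFrame,
    half_width: int = 3,
    known_proteins: set[str] | None = None,
) -> PhosphoProximityResult:
    """Count phosphosites within ±half_width of each methyl-arginine.

    The methyl position itself is excluded (an arginine cannot carry a
    phosphate).  Phosphosites on proteins absent from *known_proteins* are
    ignored with a warning.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    sites = list(methyl_sites)
    phos: dict[str, np.ndarray] = {}
    groups = phospho_sites.groupby("protein") if len(phospho_sites) else []
    for pid, grp in groups:
        if known_proteins is not None and pid not in known_proteins:
            logger.warning("phosphosites on unknown protein %r ignored", pid)
            continue
        phos[pid] = grp["position"].astype(int).to_numpy()
    counts = np.zeros(len(sites), dtype=int)
    for i, (pid, pos) in enumerate(sites):
        pp = phos.get(pid)
        if pp is None:
            continue
        counts[i] = int(
            ((np.abs(pp - pos) <= half_width) & (pp != pos)).sum()
        )
    per_site = pd.DataFrame(
        {
            "protein": [s[0] for s in sites],
            "position": [s[1] for s in sites],
            "n_phospho": counts,
        }
    )
    fractions = _bin_fractions(counts) if len(sites) else dict.fromkeys(PROXIMITY_BINS, np.nan)
    frac_ge1 = float((counts >= 1).mean()) if len(sites) else float("nan")
    return PhosphoProximityResult(per_site, fractions, frac_ge1)


@dataclass
class PhosphoBackgroundResult:
    bin_mean: dict[str, float]
    bin_sd: dict[str, float]
    frac_ge1_bg: np.ndarray  # one value per resample
    p_value: float
    n_resamples: int
    seed: int


def phospho_background(
    proteome: ProteomeDB,
    phospho_sites: pd.DataFrame,
    n_fg: int,
    observed_frac_ge1: float,
    half_width: int = 3,
    n_resamples: int = 999,
    seed: int = 0,
) -> PhosphoBackgroundResult:
    """Resampled arginine null for the "≥1 phospho in proximity" fraction.

    Each resample draws *n_fg* arginine positions uniformly without
    replacement from the proteome and records its proximity-count bin
    distribution.  The empirical p-value for the observed foreground "≥1"
    fraction uses the add-one correction:
    p = (1 + #{resamples with fraction >= observed}) / (1 + n_resamples).
    """
    arg_sites = all_arginine_sites(proteome)
    if len(arg_sites) < n_fg:
        raise ValueError(
            f"proteome has {len(arg_sites)} arginines, fewer than n_fg={n_fg}"
        )
    phos: dict[str, np.ndarray] = (
        {
            pid: grp["position"].astype(int).to_numpy()
            for pid, grp in phospho_sites.groupby("protein")
        }
        if len(phospho_sites)
        else {}
    )
    # precompute the proximity count for every arginine once
    counts_all = np.zeros(len(arg_sites), dtype=np.int32)
    for i, (pid, pos) in enumerate(arg_sites):
        pp = phos.get(pid)
        if pp is None:
            continue
        counts_all[i] = int(((np.abs(pp - pos) <= half_width) & (pp != pos)).sum())

    rng = np.random.default_rng(seed)
    n_arg = len(arg_sites)
    frac_ge1 = np.empty(n_resamples)
    bins = np.zeros((n_resamples, len(PROXIMITY_BINS)))
    for r in range(n_resamples):
        idx = rng.choice(n_arg, size=n_fg, replace=False)
        c = counts_all[idx]
        frac_ge1[r] = (c >= 1).mean()
        f = _bin_fractions(c)
        bins[r] = [f[k] for k in PROXIMITY_BINS]
    p = (1 + int((frac_ge1 >= observed_frac_ge1).sum())) / (1 + n_resamples)
    return PhosphoBackgroundResult(
        bin_mean=dict(zip(PROXIMITY_BINS, bins.mean(axis=0))),
        bin_sd=dict(zip(PROXIMITY_BINS, bins.std(axis=0))),
        frac_ge1_bg=frac_ge1,
        p_value=float(p),
        n_resamples=n_resamples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# mutation rates


def _mutated_set(mutations: pd.DataFrame) -> set[tuple[str, int]]:
    if len(mutations) == 0:
        return set()
    return {
        (pid, int(pos))
        for pid, pos, cnt in zip(
            mutations["protein"], mutations["position"], mutations["count"]
        )
        if cnt >= 1
    }


def _vicinity_positions(
    positions: Iterable[tuple[str, int]],
    half_width: int,
    proteome: ProteomeDB | None,
) -> set[tuple[str, int]]:
    out: set[tuple[str, int]] = set()
    for pid, pos in positions:
        length = len(proteome[pid]) if proteome is not None and pid in proteome else None
        lo = max(1, pos - half_width)
        hi = pos + half_width if length is None else min(length, pos + half_width)
        for p in range(lo, hi + 1):
            out.add((pid, p))
    return out


def mutation_rate(
    positions: Iterable[tuple[str, int]],
    mutations: pd.DataFrame,
    half_width: int = 5,
    mode: str = "at_site",
    proteome: ProteomeDB | None = None,
) -> tuple[float, int, int]:
    """Fraction of considered residue positions carrying >= 1 somatic mutation.

    ``mode='at_site'`` considers the sites themselves; ``mode='vicinity'``
    the deduplicated union of ±half_width residues around each site (centre
    included), clipped to the protein bounds when a proteome is supplied.
    Returns ``(rate, n_mutated, n_considered)``.
    """
    if mode not in ("at_site", "vicinity"):
        raise ValueError(f"mode must be 'at_site' or 'vicinity', got {mode!r}")
    positions = set(positions)
    if mode == "vicinity":
        considered = _vicinity_positions(positions, half_width, proteome)
    else:
        considered = positions
    mutated_positions = _mutated_set(mutations)
    n_mut = len(considered & mutated_positions)
    n_tot = len(considered)
    rate = n_mut / n_tot if n_tot else float("nan")
    return rate, n_mut, n_tot


def mutation_enrichment(
    fg_sites: Iterable[tuple[str, int]],
    bg_sites: Iterable[tuple[str, int]],
    mutations: pd.DataFrame,
    half_width: int = 5,
    mode: str = "at_site",
    proteome: ProteomeDB | None = None,
) -> EnrichmentResult:
    """Fisher's exact comparison of mutation rates at fg vs bg positions.

    Foreground positions are removed from the background so the two rows of
    the 2x2 table are disjoint (pass all proteome arginines as *bg_sites*
    and the exclusion happens automatically).
    """
    fg, bg = set(fg_sites), set(bg_sites) - set(fg_sites)
    if mode == "vicinity":
        fg_pos = _vicinity_positions(fg, half_width, proteome)
        bg_pos = _vicinity_positions(bg, half_width, proteome) - fg_pos
    else:
        fg_pos, bg_pos = fg, bg
    mutated = _mutated_set(mutations)
    a = len(fg_pos & mutated)
    b = len(fg_pos) - a
    c = len(bg_pos & mutated)
    d = len(bg_pos) - c
    odds, p = fisher_exact([[a, b], [c, d]])
    rate_fg = a / len(fg_pos) if fg_pos else float("nan")
    rate_bg = c / len(bg_pos) if bg_pos else float("nan")
    return EnrichmentResult(rate_fg, rate_bg, odds, p, (a, b, c, d))
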