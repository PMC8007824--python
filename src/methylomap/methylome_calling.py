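"""SILAC-based PRMT substrate calling.

The experiment compares control cells (light channel) with PRMT-knockdown or
inhibitor-treated cells (heavy channel).  A methyl site whose heavy/light
ratio drops at least ``fold_change``-fold (ratio_HL <= 1/fold_change,
boundary inclusive) is called *decreased*; a site detected in the light
channel with no heavy signal at all is *abolished* (and counts as decreased
in every tally).  Sites whose decrease is explained by a matching drop in
protein abundance are flagged ``protein_explained`` and excluded from the
methylome, but never deleted from the report.

Status vocabulary: ``not_quantified``, ``unchanged``, ``decreased``,
``abolished``, ``increased``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment_sets import hypergeom_overlap

logger = logging.getLogger(__name__)

STATUS_NOT_QUANTIFIED = "not_quantified"
STATUS_UNCHANGED = "unchanged"
STATUS_DECREASED = "decreased"
STATUS_ABOLISHED = "abolished"
STATUS_INCREASED = "increased"

#: antibody panels used for immuno-enrichment, per enzyme class:
#: PRMT4 (type I) produces MMA+aDMA, PRMT5 (type II) MMA+sDMA,
#: PRMT7 (type III, the only one) MMA only.
DEFAULT_MODALITIES: dict[str, frozenset[str]] = {
    "PRMT4": frozenset({"MMA", "aDMA"}),
    "PRMT5": frozenset({"MMA", "sDMA"}),
    "PRMT7": frozenset({"MMA"}),
}

DEFAULT_FOLD_CHANGE = 2.0


def _check_fold_change(fold_change: float) -> float:
    if not fold_change > 1:
        raise ValueError(f"fold_change must be > 1, got {fold_change}")
    return float(fold_change)


@dataclass
class Methylome:
    """The called substrate set for one PRMT perturbation.

    ``sites`` holds one row per decreased/abolished, not protein-explained
    site with columns: protein, position, methyl_type, ratio_HL,
    normalized_ratio, status, protein_explained.
    """

    prmt_label: str
    sites: pd.DataFrame

    @property
    def proteins(self) -> set[str]:
        return set(self.sites["protein"])

    @property
    def site_keys(self) -> set[tuple[str, int]]:
        """Position-level keys (protein, position); methyl type collapsed."""
        return set(
            zip(self.sites["protein"], self.sites["position"].astype(int))
        )

    def __len__(self) -> int:
        return len(self.sites)


def compute_site_ratio(
    intensity_L: float | None, intensity_H: float | None
) -> tuple[float, float]:
    """Heavy/light ratio and its log2 for one site; NaN marks absent.

    Zero intensity is coerced to absent: an intensity of exactly zero is
    below the detector floor, which is what "abolished" means for the heavy
    channel.
    """
    L = np.nan if intensity_L is None or not intensity_L > 0 else float(intensity_L)
    H = np.nan if intensity_H is None or not intensity_H > 0 else float(intensity_H)
    if math.isnan(L) or math.isnan(H):
        return np.nan, np.nan
    ratio = H / L
    return ratio, math.log2(ratio)


def classify_site(
    intensity_L: float | None,
    intensity_H: float | None,
    fold_change: float = DEFAULT_FOLD_CHANGE,
) -> str:
    """Total classification of one quantified (or not) site.

    Light absent -> not_quantified; heavy absent with light present ->
    abolished; ratio <= 1/fold_change -> decreased (inclusive boundary);
    ratio >= fold_change -> increased; otherwise unchanged.
    """
    t = _check_fold_change(fold_change)
    L = np.nan if intensity_L is None or not intensity_L > 0 else float(intensity_L)
    H = np.nan if intensity_H is None or not intensity_H > 0 else float(intensity_H)
    if math.isnan(L):
        return STATUS_NOT_QUANTIFIED
    if math.isnan(H):
        return STATUS_ABOLISHED
    ratio = H / L
    if ratio <= 1.0 / t:
        return STATUS_DECREASED
    if ratio >= t:
        return STATUS_INCREASED
    return STATUS_UNCHANGED


def normalize_to_protein(
    ratio_HL: float,
    protein_ratio: float | None,
    status: str,
    fold_change: float = DEFAULT_FOLD_CHANGE,
) -> tuple[float, bool]:
    """Protein-abundance control for one quantified site.

    Returns ``(normalized_ratio, protein_explained)``.  A site is
    protein-explained when its raw call is *decreased* but the ratio divided
    by the protein-abundance ratio no longer clears the fold-change cut —
    i.e. the methylation change just tracks a change in protein amount.
    Sites without protein quantification are retained un-normalized.
    """
    t = _check_fold_change(fold_change)
    if (
        protein_ratio is None
        or (isinstance(protein_ratio, float) and math.isnan(protein_ratio))
    ):
        return np.nan, False
    if protein_ratio == 0:
        logger.warning("protein ratio of zero; normalized ratio left absent")
        return np.nan, False
    if isinstance(ratio_HL, float) and math.isnan(ratio_HL):
        return np.nan, False
    normalized = ratio_HL / protein_ratio
    explained = status == STATUS_DECREASED and normalized > 1.0 / t
    return normalized, explained


def _protein_ratio_map(protein_table: pd.DataFrame | None) -> pd.Series:
    if protein_table is None or len(protein_table) == 0:
        return pd.Series(dtype=float)
    L = protein_table["intensity_L"].astype(float).to_numpy()
    H = protein_table["intensity_H"].astype(float).to_numpy()
    L = np.where(L > 0, L, np.nan)
    H = np.where(H > 0, H, np.nan)
    return pd.Series(H / L, index=protein_table["protein"].to_numpy())


def call_methylome(
    site_table: pd.DataFrame,
    protein_table: pd.DataFrame | None,
    prmt_label: str,
    modality_filter: Iterable[str] | None = None,
    fold_change: float = DEFAULT_FOLD_CHANGE,
) -> tuple[Methylome, dict]:
    """Run the full calling cascade on one perturbation's site table.

    Steps: restrict to the antibody modalities, deduplicate identical sites
    recovered from multiple enrichment experiments (key = protein +
    position + methyl type), compute ratios, classify, apply the
    protein-abundance control, and collect decreased/abolished,
    not-protein-explained sites into the methylome.

    Returns the :class:`Methylome` and a tally dict with site- and
    protein-level counts for: detected, quantified (both conventions: with
    and without abolished sites), decreased (abolished included) and
    abolished, plus protein_explained counts.
    """
    t = _check_fold_change(fold_change)
    df = site_table.copy()
    if modality_filter is not None:
        allowed = set(modality_filter)
        df = df[df["methyl_type"].isin(allowed)]
    if len(df) == 0:
        logger.warning("empty site table for %s", prmt_label)
        empty = pd.DataFrame(
            columns=[
                "protein",
                "position",
                "methyl_type",
                "ratio_HL",
                "normalized_ratio",
                "status",
                "protein_explained",
            ]
        )
        tally = {k: 0 for k in _TALLY_KEYS}
        return Methylome(prmt_label, empty), tally

    df = df.drop_duplicates(subset=["protein", "position", "methyl_type"])
    df = df.reset_index(drop=True)

    L = df["intensity_L"].astype(float).to_numpy()
    H = df["intensity_H"].astype(float).to_numpy()
    L = np.where(L > 0, L, np.nan)
    H = np.where(H > 0, H, np.nan)
    ratio = np.where(np.isnan(L) | np.isnan(H), np.nan, H / L)

    status = np.full(len(df), STATUS_UNCHANGED, dtype=object)
    status[np.isnan(L)] = STATUS_NOT_QUANTIFIED
    status[~np.isnan(L) & np.isnan(H)] = STATUS_ABOLISHED
    with np.errstate(invalid="ignore"):
        status[ratio <= 1.0 / t] = STATUS_DECREASED
        status[ratio >= t] = STATUS_INCREASED

    pratio = _protein_ratio_map(protein_table)
    prot_r = (
        df["protein"].map(pratio).astype(float).to_numpy()
        if len(pratio)
        else np.full(len(df), np.nan)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(
            np.isnan(prot_r) | (prot_r == 0), np.nan, ratio / prot_r
        )
    explained = (status == STATUS_DECREASED) & (normalized > 1.0 / t)

    calls = pd.DataFrame(
        {
            "protein": df["protein"].to_numpy(),
            "position": df["position"].astype(int).to_numpy(),
            "methyl_type": df["methyl_type"].to_numpy(),
            "ratio_HL": ratio,
            "normalized_ratio": normalized,
            "status": status,
            "protein_explained": explained,
        }
    )

    is_abolished = calls["status"] == STATUS_ABOLISHED
    is_decreased = is_abolished | (calls["status"] == STATUS_DECREASED)
    is_quantified = ~np.isnan(ratio)
    in_methylome = is_decreased & ~calls["protein_explained"]

    def _nprot(mask) -> int:
        return int(calls.loc[mask, "protein"].nunique())

    tally = {
        "sites_detected": int(len(calls)),
        "sites_quantified": int(is_quantified.sum()),
        "sites_quantified_incl_abolished": int(
            (is_quantified | is_abolished).sum()
        ),
        "sites_decreased": int(is_decreased.sum()),
        "sites_abolished": int(is_abolished.sum()),
        "sites_protein_explained": int(calls["protein_explained"].sum()),
        "proteins_detected": _nprot(np.ones(len(calls), dtype=bool)),
        "proteins_quantified": _nprot(is_quantified),
        "proteins_quantified_incl_abolished": _nprot(
            is_quantified | is_abolished
        ),
        "proteins_decreased": _nprot(is_decreased),
        "proteins_abolished": _nprot(is_abolished),
        "proteins_protein_explained": _nprot(calls["protein_explained"]),
        "proteins_in_methylome": _nprot(in_methylome),
        "sites_in_methylome": int(in_methylome.sum()),
    }

    methylome = Methylome(prmt_label, calls[in_methylome].reset_index(drop=True))
    return methylome, tally


_TALLY_KEYS = [
    "sites_detected",
    "sites_quantified",
    "sites_quantified_incl_abolished",
    "sites_decreased",
    "sites_abolished",
    "sites_protein_explained",
    "proteins_detected",
    "proteins_quantified",
    "proteins_quantified_incl_abolished",
    "proteins_decreased",
    "proteins_abolished",
    "proteins_protein_explained",
    "proteins_in_methylome",
    "sites_in_methylome",
]


@dataclass
class IntersectionResult:
    """Partition of substrates by how many PRMTs regulate them."""

    level: str
    labels: tuple[str, ...]
    membership: dict = field(default_factory=dict)  # key -> frozenset(labels)

    @property
    def classes(self) -> dict[int, set]:
        out: dict[int, set] = {n: set() for n in range(1, len(self.labels) + 1)}
        for key, labs in self.membership.items():
            out[len(labs)].add(key)
        return out

    def class_counts(self) -> dict[int, int]:
        return {n: len(keys) for n, keys in self.classes.items()}


def intersect_methylomes(
    methylomes: Sequence[Methylome], level: str = "protein"
) -> IntersectionResult:
    """Partition substrates into regulated-by-1 / by-2 / ... classes.

    ``level='protein'`` keys on protein IDs; ``level='position'`` keys on
    (protein, position), ignoring methyl type — the same arginine can carry
    me1/me2a/me2s depending on which PRMT acts on it.
    """
    if len(methylomes) < 2:
        raise ValueError("need at least two methylomes to intersect")
    labels = [m.prmt_label for m in methylomes]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate prmt_label in {labels}")
    if level not in ("protein", "position"):
        raise ValueError(f"level must be 'protein' or 'position', got {level!r}")

    membership: dict = {}
    for m in methylomes:
        keys = m.proteins if level == "protein" else m.site_keys
        for key in keys:
            membership.setdefault(key, set()).add(m.prmt_label)
    membership = {k: frozenset(v) for k, v in membership.items()}
    return IntersectionResult(level=level, labels=tuple(labels), membership=membership)


def sites_per_protein(methylome: Methylome) -> dict[int, float]:
    """Fraction of substrate proteins carrying each number of called sites."""
    if len(methylome) == 0:
        raise ValueError("empty methylome")
    counts = methylome.sites.groupby("protein")["position"].nunique()
    hist = counts.value_counts().sort_index()
    total = float(hist.sum())
    return {int(k): float(v) / total for k, v in hist.items()}


def crossvalidate_calls(
    methylome_a: Methylome,
    methylome_b: Methylome,
    universe: set[str],
) -> tuple[float, float]:
    """Protein-level agreement between two perturbations of the same enzyme.

    Returns ``(fraction, p)`` where fraction = |A∩B| / |A| and p is the
    one-sided hypergeometric overlap tail over *universe* (for example, all
    proteins detected in both experiments).
    """
    a, b = methylome_a.proteins, methylome_b.proteins
    if not (a | b) <= universe:
        raise ValueError("universe smaller than the union of the methylomes")
    if not a:
        return float("nan"), 1.0
    test = hypergeom_overlap(a, b, universe)
    return len(a & b) / len(a), test.p_value
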