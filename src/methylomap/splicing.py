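"""PSI-based differential alternative-splicing calls and cross-PRMT
concordance.

PSI (percent spliced in) is the fraction of transcripts including the
alternative element, estimated from junction counts with effective-length
normalization:

    psi = (inc/inc_len) / (inc/inc_len + skip/skip_len)

With equal effective lengths this reduces to inc / (inc + skip), the plain
isoform-ratio definition.  An event is differential when
|ΔPSI| = |PSI(control) − PSI(knockdown)| >= 0.5 (inclusive), and the
direction names the change the knockdown *induces*: EI (exon inclusion,
PSI rises upon knockdown) or ES (exon skipping, PSI falls).

Event types: SE (cassette exon), IR (intron retention), MXE (mutually
exclusive exons), A5SS / A3SS (alternative 5'/3' splice sites).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SPLICE_EVENT_TYPES

DIRECTION_EI = "EI"
DIRECTION_ES = "ES"
DIRECTION_NONE = "none"

DEFAULT_DELTA_PSI = 0.5
DEFAULT_MIN_TOTAL = 10


def compute_psi(
    inc_count: int,
    skip_count: int,
    inc_len: float = 1.0,
    skip_len: float = 1.0,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> float:
    """Length-normalized PSI, or NaN when coverage is below *min_total*."""
    if inc_count < 0 or skip_count < 0:
        raise ValueError("junction counts must be non-negative")
    if inc_len <= 0 or skip_len <= 0:
        raise ValueError("effective lengths must be positive")
    if inc_count + skip_count < min_total or inc_count + skip_count == 0:
        return float("nan")
    inc_norm = inc_count / inc_len
    skip_norm = skip_count / skip_len
    return inc_norm / (inc_norm + skip_norm)


@dataclass(frozen=True)
class DeltaPsiCall:
    event_id: str
    event_type: str
    psi_ctl: float
    psi_kd: float
    delta_psi: float  # psi_ctl - psi_kd
    differential: bool
    direction: str  # EI / ES / none


def call_delta_psi(
    psi_ctl: float,
    psi_kd: float,
    threshold: float = DEFAULT_DELTA_PSI,
    event_id: str = "",
    event_type: str = "SE",
) -> DeltaPsiCall | None:
    """Differential call for one event; None when either PSI is absent."""
    if math.isnan(psi_ctl) or math.isnan(psi_kd):
        return None
    delta = psi_ctl - psi_kd
    differential = abs(delta) >= threshold
    if not differential:
        direction = DIRECTION_NONE
    elif psi_kd > psi_ctl:
        direction = DIRECTION_EI
    else:
        direction = DIRECTION_ES
    return DeltaPsiCall(
        event_id, event_type, psi_ctl, psi_kd, delta, differential, direction
    )


def psi_table(
    counts: pd.DataFrame, min_total: int = DEFAULT_MIN_TOTAL
) -> pd.DataFrame:
    """Wide per-event PSI table from a long splice-counts table.

    Input columns: event_id, event_type, condition, inc_count, skip_count,
    inc_len, skip_len.  Output: one row per event with a ``psi_<condition>``
    column per condition (NaN where coverage is insufficient).
    """
    rows: dict[str, dict] = {}
    for rec in counts.itertuples(index=False):
        entry = rows.setdefault(
            rec.event_id, {"event_id": rec.event_id, "event_type": rec.event_type}
        )
        entry[f"psi_{rec.condition}"] = compute_psi(
            int(rec.inc_count),
            int(rec.skip_count),
            float(rec.inc_len),
            float(rec.skip_len),
            min_total,
        )
    return pd.DataFrame(list(rows.values()))


def call_events(
    counts: pd.DataFrame,
    ctl_condition: str,
    kd_condition: str,
    threshold: float = DEFAULT_DELTA_PSI,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> pd.DataFrame:
    """ΔPSI calls for every event testable in both conditions.

    Returns one row per event: event_id, event_type, psi_ctl, psi_kd,
    delta_psi, differential, direction, testable.  Events with absent PSI
    in either condition are kept with ``testable=False`` and direction
    ``none`` so that "not testable" is reported rather than dropped.
    """
    wide = psi_table(counts, min_total=min_total)
    ctl_col, kd_col = f"psi_{ctl_condition}", f"psi_{kd_condition}"
    for col in (ctl_col, kd_col):
        if col not in wide.columns:
            raise ValueError(f"condition {col[4:]!r} missing from counts table")
    out = []
    for rec in wide.to_dict("records"):
        psi_ctl = rec.get(ctl_col, float("nan"))
        psi_kd = rec.get(kd_col, float("nan"))
        psi_ctl = float("nan") if psi_ctl is None else float(psi_ctl)
        psi_kd = float("nan") if psi_kd is None else float(psi_kd)
        call = call_delta_psi(
            psi_ctl, psi_kd, threshold, rec["event_id"], rec["event_type"]
        )
        if call is None:
            out.append(
                {
                    "event_id": rec["event_id"],
                    "event_type": rec["event_type"],
                    "psi_ctl": psi_ctl,
                    "psi_kd": psi_kd,
                    "delta_psi": float("nan"),
                    "differential": False,
                    "direction": DIRECTION_NONE,
                    "testable": False,
                }
            )
        else:
            out.append(
                {
                    "event_id": call.event_id,
                    "event_type": call.event_type,
                    "psi_ctl": call.psi_ctl,
                    "psi_kd": call.psi_kd,
                    "delta_psi": call.delta_psi,
                    "differential": call.differential,
                    "direction": call.direction,
                    "testable": True,
                }
            )
    return pd.DataFrame(out)


def summarize_events(calls: pd.DataFrame) -> dict:
    """Differential-event counts per type and direction.

    Returns ``{event_type: {"EI": n, "ES": n, "differential": n}}`` plus a
    ``"total"`` entry, over testable differential events only.
    """
    diff = calls[calls["differential"]]
    out: dict = {}
    for etype in SPLICE_EVENT_TYPES:
        sub = diff[diff["event_type"] == etype]
        out[etype] = {
            "EI": int((sub["direction"] == DIRECTION_EI).sum()),
            "ES": int((sub["direction"] == DIRECTION_ES).sum()),
            "differential": int(len(sub)),
        }
    out["total"] = {
        "EI": int((diff["direction"] == DIRECTION_EI).sum()),
        "ES": int((diff["direction"] == DIRECTION_ES).sum()),
        "differential": int(len(diff)),
    }
    return out


@dataclass
class ConcordanceSummary:
    """Cross-regulator partition and direction agreement.

    ``per_event``: one row per event differential for >= 1 regulator, with
    the per-regulator direction, regulator count class, and a concordant
    flag for shared events.  ``concordance_fraction`` is over shared
    (class >= 2) events.
    """

    per_event: pd.DataFrame
    labels: tuple[str, ...]
    class_counts: dict[int, int]
    n_concordant: int
    n_discordant: int

    @property
    def concordance_fraction(self) -> float:
        shared = self.n_concordant + self.n_discordant
        return self.n_concordant / shared if shared else float("nan")


def concordance_analysis(
    calls_by_prmt: Mapping[str, pd.DataFrame]
) -> ConcordanceSummary:
    """Partition differential events by regulator count; check directions.

    All call tables must cover the same event universe (same testable set
    of event IDs); a mismatch is an error listing the missing IDs, since a
    by-2/by-3 partition over unequal universes would conflate "not
    regulated" with "not measured".
    """
    labels = tuple(calls_by_prmt)
    if len(labels) < 2:
        raise ValueError("need calls from at least two regulators")
    universes = {lab: set(df["event_id"]) for lab, df in calls_by_prmt.items()}
    reference = universes[labels[0]]
    for lab in labels[1:]:
        if universes[lab] != reference:
            missing = sorted(reference ^ universes[lab])[:10]
            raise ValueError(
                f"event universes differ between {labels[0]!r} and {lab!r}; "
                f"mismatched IDs include {missing}"
            )

    directions: dict[str, dict[str, str]] = {}
    etypes: dict[str, str] = {}
    for lab, df in calls_by_prmt.items():
        for rec in df.itertuples(index=False):
            etypes[rec.event_id] = rec.event_type
            if rec.differential:
                directions.setdefault(rec.event_id, {})[lab] = rec.direction

    rows = []
    n_conc = n_disc = 0
    class_counts = {n: 0 for n in range(1, len(labels) + 1)}
    for event_id, dirs in directions.items():
        n_reg = len(dirs)
        class_counts[n_reg] += 1
        concordant = None
        if n_reg >= 2:
            concordant = len(set(dirs.values())) == 1
            if concordant:
                n_conc += 1
            else:
                n_disc += 1
        row = {
            "event_id": event_id,
            "event_type": etypes[event_id],
            "n_regulators": n_reg,
            "concordant": concordant,
        }
        for lab in labels:
            row[f"direction_{lab}"] = dirs.get(lab, DIRECTION_NONE)
        rows.append(row)
    per_event = pd.DataFrame(rows)
    return ConcordanceSummary(per_event, labels, class_counts, n_conc, n_disc)


# ---------------------------------------------------------------------------
# expression filter


@dataclass(frozen=True)
class GeneExpression:
    gene: str
    exonic_length_bp: float
    mapped_reads_on_exons: float
    total_mapped_reads: float
    fpkm: float


def fpkm(
    mapped_reads_on_exons: float,
    exonic_length_bp: float,
    total_mapped_reads: float,
) -> float:
    """Fragments per kilobase of exon per million mapped reads."""
    if exonic_length_bp <= 0 or total_mapped_reads <= 0:
        raise ValueError("exonic length and total mapped reads must be > 0")
    if mapped_reads_on_exons < 0:
        raise ValueError("read count must be non-negative")
    return (
        mapped_reads_on_exons
        / (exonic_length_bp / 1_000.0)
        / (total_mapped_reads / 1_000_000.0)
    )


def expressed_filter(
    fpkm_by_condition: Mapping[str, float], keep_threshold: float = 0.5
) -> bool:
    """Keep a gene iff FPKM is strictly greater than the threshold in at
    least one condition."""
    return any(v > keep_threshold for v in fpkm_by_condition.values())


# ---------------------------------------------------------------------------
# central motif-position enrichment (upstream of alternative exons)

_IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "[TU]",
    "U": "[TU]",
    "R": "[AG]",
    "Y": "[CTU]",
    "S": "[CG]",
    "W": "[ATU]",
    "K": "[GTU]",
    "M": "[AC]",
    "B": "[CGTU]",
    "D": "[AGTU]",
    "H": "[ACTU]",
    "V": "[ACG]",
    "N": "[ACGTU]",
}


def _iupac_regex(motif: str) -> re.Pattern:
    try:
        return re.compile("".join(_IUPAC[c] for c in motif.upper()))
    except KeyError as exc:
        raise ValueError(f"illegal IUPAC symbol in motif {motif!r}") from exc


@dataclass(frozen=True)
class CentralMotifResult:
    n_matches: int
    n_in_window: int
    p0: float  # expected in-window fraction under uniform placement
    p_value: float  # one-sided binomial tail


def central_motif_enrichment(
    sequences: Sequence[str],
    motif: str,
    center_window: int = 100,
) -> CentralMotifResult:
    """Test whether motif matches prefer the centre of the input sequences.

    Match start positions falling within a *center_window*-wide interval
    centred on the midpoint of each sequence's usable start range are
    "central".  Under uniform placement the central fraction is
    p0 = (window starts) / (usable starts); the one-sided binomial tail
    P[X >= observed] with X ~ Binomial(n_matches, p0) scores the excess.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    pattern = _iupac_regex(motif)
    m = len(motif)
    n_matches = 0
    n_in = 0
    total_usable = 0
    total_window = 0
    for seq in sequences:
        seq = seq.upper()
        usable = len(seq) - m + 1
        if usable < 1:
            raise ValueError("motif longer than a sequence")
        mid = (usable - 1) / 2.0
        half = center_window / 2.0
        lo, hi = mid - half, mid + half
        n_window_starts = sum(1 for s in range(usable) if lo <= s <= hi)
        total_usable += usable
        total_window += n_window_starts
        # overlapping matches counted via lookahead-free scan
        start = 0
        while True:
            hit = pattern.search(seq, start)
            if hit is None:
                break
            s = hit.start()
            n_matches += 1
            if lo <= s <= hi:
                n_in += 1
            start = s + 1
    p0 = total_window / total_usable
    if n_matches == 0:
        p = 1.0
    else:
        p = float(stats.binom.sf(n_in - 1, n_matches, p0))
    return CentralMotifResult(n_matches, n_in, p0, min(p, 1.0))
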