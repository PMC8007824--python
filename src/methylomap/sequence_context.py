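"""Residue context around methyl-arginines: windows, motif classes, and
position-specific residue enrichment against a proteome background.

A methyl-site window is the 2k+1 residues centred on the modified arginine
(default k=5, an 11-residue window), padded with ``-`` past the protein
termini.  Motif classes follow the field's vocabulary: GAR (glycine/arginine
rich, an RG/RGG context — glycine immediately next to the arginine) and RXR
(a second arginine two residues away).  When both patterns apply (e.g. RGR)
GAR takes precedence, so the two classes are disjoint.

The positional enrichment statistic mirrors the sampling approach of
sequence-logo tools: draw many random arginine-centred window sets of the
same size from the proteome, record the per-offset residue frequencies, and
score the foreground frequency as a Z value against the sampled mean and
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ProteomeDB

PAD = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_PAD_CODE = len(AMINO_ACIDS)

MOTIF_GAR = "GAR"
MOTIF_RXR = "RXR"
MOTIF_OTHER = "other"


@dataclass(frozen=True)
class SequenceWindow:
    protein: str
    center_position: int  # 1-based
    residues: str

    @property
    def k(self) -> int:
        return (len(self.residues) - 1) // 2

    def at(self, offset: int) -> str:
        """Residue at a signed offset from the centre arginine."""
        return self.residues[self.k + offset]


def extract_window(
    proteome: ProteomeDB, protein: str, position: int, k: int = 5
) -> SequenceWindow:
    """Extract the 2k+1 residue window centred at a 1-based position.

    The centre residue must be an arginine; anything else indicates a
    coordinate bug upstream and is a hard error.
    """
    if protein not in proteome:
        raise KeyError(f"protein {protein!r} not in proteome")
    seq = proteome[protein]
    if not 1 <= position <= len(seq):
        raise ValueError(
            f"position {position} out of range for {protein!r} "
            f"(length {len(seq)})"
        )
    center = seq[position - 1]
    if center != "R":
        raise ValueError(
            f"center not R: {protein!r} position {position} is {center!r}"
        )
    lo, hi = position - 1 - k, position - 1 + k + 1
    left_pad = PAD * max(0, -lo)
    right_pad = PAD * max(0, hi - len(seq))
    window = left_pad + seq[max(0, lo) : min(len(seq), hi)] + right_pad
    return SequenceWindow(protein, position, window)


def classify_motif(window: SequenceWindow) -> str:
    """GAR / RXR / other for one window (GAR wins on overlap).

    GAR: glycine at offset -1 or +1 (covers RG, GR and RGG contexts).
    RXR: another arginine at offset -2 or +2.
    """
    if window.k < 2:
        raise ValueError("motif classification needs a window with k >= 2")
    if window.at(-1) == "G" or window.at(+1) == "G":
        return MOTIF_GAR
    if window.at(-2) == "R" or window.at(+2) == "R":
        return MOTIF_RXR
    return MOTIF_OTHER


def motif_fractions(windows: Sequence[SequenceWindow]) -> dict[str, float]:
    if not windows:
        raise ValueError("no windows supplied")
    labels = [classify_motif(w) for w in windows]
    n = float(len(labels))
    return {
        m: labels.count(m) / n for m in (MOTIF_GAR, MOTIF_RXR, MOTIF_OTHER)
    }


@dataclass
class PositionalEnrichment:
    """Per (offset, residue) foreground-vs-background comparison.

    ``table`` columns: offset, residue, fg_freq, bg_mean, bg_sd, z, p_value,
    pct_diff, flagged.  Frequencies exclude the pad character from the
    denominator at each offset.
    """

    table: pd.DataFrame
    k: int
    n_foreground: int
    n_samples: int
    sample_size: int
    seed: int
    alpha: float

    def cell(self, offset: int, residue: str) -> pd.Series:
        t = self.table
        row = t[(t["offset"] == offset) & (t["residue"] == residue)]
        return row.iloc[0]


def _encode_windows(windows: Iterable[str]) -> np.ndarray:
    rows = []
    for w in windows:
        rows.append([_AA_INDEX.get(c, _PAD_CODE) for c in w])
    return np.asarray(rows, dtype=np.int8)


def _freq_matrix(codes: np.ndarray) -> np.ndarray:
    """(width, 20) residue frequencies, pads excluded from the denominator."""
    width = codes.shape[1]
    out = np.zeros((width, len(AMINO_ACIDS)))
    for j in range(width):
        col = codes[:, j]
        col = col[col != _PAD_CODE]
        if len(col):
            counts = np.bincount(col, minlength=len(AMINO_ACIDS))
            out[j] = counts[: len(AMINO_ACIDS)] / len(col)
    return out


def all_arginine_sites(proteome: ProteomeDB) -> list[tuple[str, int]]:
    """Every (protein, 1-based position) with an arginine residue."""
    sites = []
    for pid, seq in proteome.items():
        start = 0
        while True:
            i = seq.find("R", start)
            if i < 0:
                break
            sites.append((pid, i + 1))
            start = i + 1
    return sites


def positional_enrichment(
    foreground: Sequence[SequenceWindow],
    proteome: ProteomeDB,
    n_samples: int = 1000,
    sample_size: int | None = None,
    seed: int = 0,
    alpha: float = 0.01,
) -> PositionalEnrichment:
    """iceLogo-style sampled-background residue enrichment.

    For each of *n_samples* rounds, *sample_size* arginine-centred windows
    are drawn uniformly (without replacement) from the proteome and their
    per-offset residue frequencies recorded.  Each foreground cell is scored
    Z = (f_fg - mean_bg) / sd_bg with a two-sided normal p-value and a
    percent difference (f_fg - mean_bg) * 100.  Cells with p < alpha are
    flagged.  Zero background spread yields a signed-infinity Z sentinel
    when the foreground differs, 0 otherwise.
    """
    if not foreground:
        raise ValueError("empty foreground")
    k = foreground[0].k
    if any(w.k != k for w in foreground):
        raise ValueError("foreground windows have mixed widths")
    if sample_size is None:
        sample_size = len(foreground)

    arg_sites = all_arginine_sites(proteome)
    if len(arg_sites) < sample_size:
        raise ValueError(
            f"proteome has {len(arg_sites)} arginines; "
            f"need at least sample_size={sample_size}"
        )
    bg_windows = [
        extract_window(proteome, pid, pos, k).residues for pid, pos in arg_sites
    ]
    bg_codes = _encode_windows(bg_windows)

    fg_codes = _encode_windows([w.residues for w in foreground])
    fg_freq = _freq_matrix(fg_codes)

    rng = np.random.default_rng(seed)
    width = 2 * k + 1
    sums = np.zeros((width, len(AMINO_ACIDS)))
    sq_sums = np.zeros_like(sums)
    for _ in range(n_samples):
        idx = rng.choice(len(bg_codes), size=sample_size, replace=False)
        f = _freq_matrix(bg_codes[idx])
        sums += f
        sq_sums += f * f
    bg_mean = sums / n_samples
    bg_var = np.maximum(sq_sums / n_samples - bg_mean**2, 0.0)
    bg_sd = np.sqrt(bg_var)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (fg_freq - bg_mean) / bg_sd
    zero_sd = bg_sd == 0
    z[zero_sd & (fg_freq != bg_mean)] = np.inf * np.sign(
        (fg_freq - bg_mean)[zero_sd & (fg_freq != bg_mean)]
    )
    z[zero_sd & (fg_freq == bg_mean)] = 0.0
    p = 2.0 * stats.norm.sf(np.abs(z))
    pct_diff = (fg_freq - bg_mean) * 100.0

    offsets, residues = np.meshgrid(
        np.arange(-k, k + 1), np.arange(len(AMINO_ACIDS)), indexing="ij"
    )
    table = pd.DataFrame(
        {
            "offset": offsets.ravel(),
            "residue": [AMINO_ACIDS[i] for i in residues.ravel()],
            "fg_freq": fg_freq.ravel(),
            "bg_mean": bg_mean.ravel(),
            "bg_sd": bg_sd.ravel(),
            "z": z.ravel(),
            "p_value": p.ravel(),
            "pct_diff": pct_diff.ravel(),
        }
    )
    table["flagged"] = table["p_value"] < alpha
    return PositionalEnrichment(
        table=table,
        k=k,
        n_foreground=len(foreground),
        n_samples=n_samples,
        sample_size=sample_size,
        seed=seed,
        alpha=alpha,
    )
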