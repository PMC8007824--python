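"""Synthetic multi-omics inputs with planted, recorded ground truth.

The generator emits every table the pipeline consumes — proteome FASTA,
per-perturbation SILAC site and protein-abundance tables, phosphosite and
somatic-mutation tables, splice-event junction counts with upstream
sequences, and gene sets — from a single seeded configuration, and records
what it planted so every downstream call can be scored.

It emulates the *downstream* structure of a three-PRMT knockdown study
(site-level quantification tables, event-level junction counts), not raw
spectra or reads.  Planted features: a by-1/by-2/by-3 substrate overlap
design across three PRMTs; GAR/RXR motif composition at substrate sites;
a two-fold-plus knockdown effect with a fraction of heavy channels fully
missing ("abolished"); an optional protein-abundance confound; phospho
clustering and mutation enrichment around substrate arginines; and shared
differential splicing events with one latent direction per event.

Noise model: measured heavy/light ratios are true_ratio * 2**e with
e ~ Normal(0, noise_sd) — i.e. ``noise_sd`` is the standard deviation of
the log2 ratio error, the scale SILAC ratios are usually analysed on.

Randomness: one child generator per output stream, derived from the master
seed through named spawn keys, so regenerating one table never perturbs
another and everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ProteomeDB, write_fasta, write_gmt, write_table

#: background amino-acid frequencies (approximate vertebrate proteome
#: composition, fixed constants; they only need to be realistic, not exact)
AA_FREQUENCIES: dict[str, float] = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.053, "C": 0.021,
    "Q": 0.041, "E": 0.063, "G": 0.071, "H": 0.022, "I": 0.052,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.065,
}

PRMT_LABELS = ("PRMT4", "PRMT5", "PRMT7")

#: methyl types each PRMT's antibody panel can recover (type I / II / III)
_MODALITY_CHOICES = {
    "PRMT4": ("MMA", "aDMA"),
    "PRMT5": ("MMA", "sDMA"),
    "PRMT7": ("MMA",),
}

#: named pseudo-random streams -> fixed spawn-key index
_STREAMS = {
    "proteome": 0,
    "sites": 1,
    "methyl": 2,
    "context": 3,
    "splice": 4,
    "gene_sets": 5,
}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic three-PRMT experiment.

    The defaults describe the emulated study conditions: three PRMTs with
    200 substrate proteins each in a by-1/by-2/by-3 overlap design, a
    five-fold knockdown effect (true ratio 0.2), a majority of regulated
    sites fully abolished, phospho clustering and mutation enrichment at
    substrate arginines, and shared splicing events with |ΔPSI| = 0.7.
    """

    seed: int = 0
    # proteome
    n_proteins: int = 800
    protein_length_mean: int = 450
    protein_length_sd: float = 0.35  # lognormal sd on ln(length)
    # substrate design: per-PRMT total = n_unique + 2*n_by2_pair + n_by3
    n_unique_substrates: int = 120
    n_by2_pair: int = 20
    n_by3: int = 40
    sites_extra_lambda: float = 0.47  # extra sites per substrate ~ Poisson
    n_background_sites: int = 600  # detected but unregulated methyl sites
    # motif composition of substrate sites
    frac_gar: float = 0.60
    frac_rxr: float = 0.20
    # measurement model
    knockdown_effect: float = 0.2  # true heavy/light ratio at regulated sites
    noise_sd: float = 0.3  # sd of the log2 ratio error
    abolished_fraction: float = 0.6  # regulated sites with heavy absent
    confound_fraction: float = 0.0  # substrate proteins whose drop is protein-level
    base_intensity: float = 1e6
    intensity_log_sd: float = 0.5
    # context tables
    phospho_base_density: float = 0.005  # per residue
    phospho_enrichment: float = 10.0  # density factor within ±3 of sites
    phospho_window: int = 3
    mutation_base_density: float = 0.01
    mutation_enrichment: float = 5.0  # factor within ±5 of substrate sites
    mutation_window: int = 5
    # splicing design (per event type)
    n_events_per_type: int = 80
    n_events_by3: int = 8
    n_events_by2_pair: int = 4
    n_events_by1: int = 8
    true_delta_psi: float = 0.7
    depth: int = 1000
    inc_len: float = 2.0
    skip_len: float = 1.0
    upstream_length: int = 576  # 25..600 bp upstream of the 3' splice site
    rna_motif: str = "TAGGGA"
    n_planted_motif_matches: int = 3
    motif_center_window: int = 100
    # gene sets
    n_random_gene_sets: int = 9
    gene_set_size: int = 60

    def __post_init__(self) -> None:
        for name in (
            "frac_gar",
            "frac_rxr",
            "abolished_fraction",
            "confound_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_gar + self.frac_rxr > 1.0:
            raise ValueError("frac_gar + frac_rxr must not exceed 1")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        needed = (
            3 * self.n_unique_substrates + 3 * self.n_by2_pair + self.n_by3
        )
        if needed > self.n_proteins:
            raise ValueError(
                f"substrate design needs {needed} proteins, "
                f"n_proteins is {self.n_proteins}"
            )

    @property
    def substrates_per_prmt(self) -> int:
        return self.n_unique_substrates + 2 * self.n_by2_pair + self.n_by3

    def rng(self, stream: str) -> np.random.Generator:
        key = _STREAMS[stream]
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for downstream scoring."""

    substrate_proteins: dict[str, set[str]] = field(default_factory=dict)
    substrate_sites: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    confounded_proteins: dict[str, set[str]] = field(default_factory=dict)
    motif_class: dict[tuple[str, int], str] = field(default_factory=dict)
    background_sites: set[tuple[str, int]] = field(default_factory=set)
    regulated_events: dict[str, dict] = field(default_factory=dict)
    gene_set_planted: str = ""

    def expected_methylome(self, label: str) -> set[str]:
        """Planted substrate proteins minus the protein-level confounds."""
        return self.substrate_proteins[label] - self.confounded_proteins.get(
            label, set()
        )

    def to_jsonable(self) -> dict:
        return {
            "substrate_proteins": {
                k: sorted(v) for k, v in self.substrate_proteins.items()
            },
            "substrate_sites": {
                k: sorted([list(s) for s in v])
                for k, v in self.substrate_sites.items()
            },
            "confounded_proteins": {
                k: sorted(v) for k, v in self.confounded_proteins.items()
            },
            "motif_class": {
                f"{p}:{pos}": m for (p, pos), m in sorted(self.motif_class.items())
            },
            "background_sites": sorted([list(s) for s in self.background_sites]),
            "regulated_events": self.regulated_events,
            "gene_set_planted": self.gene_set_planted,
        }


# ---------------------------------------------------------------------------
# proteome


def _sample_lengths(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    mu = np.log(cfg.protein_length_mean) - 0.5 * cfg.protein_length_sd**2
    lengths = np.exp(rng.normal(mu, cfg.protein_length_sd, cfg.n_proteins))
    return np.clip(lengths.astype(int), 120, 3000)


def _draw_aa(rng: np.random.Generator, n: int, exclude: str = "") -> np.ndarray:
    aas = [a for a in AA_FREQUENCIES if a not in exclude]
    probs = np.array([AA_FREQUENCIES[a] for a in aas])
    probs = probs / probs.sum()
    return rng.choice(np.array(aas), size=n, p=probs)


def generate_proteome(cfg: SimConfig) -> tuple[ProteomeDB, GroundTruth]:
    """Random proteome with planted substrate sites and motif contexts.

    Substrate proteins are partitioned into the by-1/by-2/by-3 overlap
    design; each substrate protein carries 1 + Poisson(sites_extra_lambda)
    methyl-arginine sites whose local sequence encodes the planted motif
    class (GAR: glycines at offsets -1/+1/+2; RXR: an arginine at +2 and no
    adjacent glycine; other: neither pattern).  Background methyl sites are
    planted on non-substrate proteins with unconstrained context.
    """
    rng = cfg.rng("proteome")
    site_rng = cfg.rng("sites")
    lengths = _sample_lengths(cfg, rng)
    ids = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    seqs = {
        pid: _draw_aa(rng, int(n)) for pid, n in zip(ids, lengths)
    }

    truth = GroundTruth()

    # --- overlap design ------------------------------------------------
    order = rng.permutation(cfg.n_proteins)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        sel = [ids[i] for i in order[cursor : cursor + n]]
        cursor += n
        return sel

    by3 = take(cfg.n_by3)
    pairs = {}
    for pair in (("PRMT4", "PRMT5"), ("PRMT4", "PRMT7"), ("PRMT5", "PRMT7")):
        pairs[pair] = take(cfg.n_by2_pair)
    unique = {lab: take(cfg.n_unique_substrates) for lab in PRMT_LABELS}

    for lab in PRMT_LABELS:
        prots = set(unique[lab]) | set(by3)
        for pair, members in pairs.items():
            if lab in pair:
                prots |= set(members)
        truth.substrate_proteins[lab] = prots
        truth.substrate_sites[lab] = set()

    substrate_ids = sorted(set().union(*truth.substrate_proteins.values()))
    non_substrates = [p for p in ids if p not in set(substrate_ids)]

    # --- plant substrate sites and motif contexts ----------------------
    motif_choices = np.array(["GAR", "RXR", "other"])
    motif_probs = np.array(
        [cfg.frac_gar, cfg.frac_rxr, 1.0 - cfg.frac_gar - cfg.frac_rxr]
    )
    for pid in substrate_ids:
        seq = seqs[pid]
        n_sites = 1 + site_rng.poisson(cfg.sites_extra_lambda)
        # candidate centres spaced >= 13 apart, clear of the termini
        candidates = np.arange(8, len(seq) - 8, 13)
        n_sites = min(n_sites, len(candidates))
        centres = site_rng.choice(candidates, size=n_sites, replace=False)
        for c in centres:
            motif = site_rng.choice(motif_choices, p=motif_probs)
            seq[c] = "R"
            if motif == "GAR":
                seq[c - 1] = "G"
                seq[c + 1] = "G"
                seq[c + 2] = "G"
            elif motif == "RXR":
                seq[c + 2] = "R"
                for off in (-1, 1):
                    if seq[c + off] == "G":
                        seq[c + off] = _draw_aa(site_rng, 1, exclude="G")[0]
                if seq[c - 2] == "G":  # keep context unambiguous
                    pass
            else:
                for off in (-1, 1):
                    if seq[c + off] == "G":
                        seq[c + off] = _draw_aa(site_rng, 1, exclude="G")[0]
                for off in (-2, 2):
                    if seq[c + off] == "R":
                        seq[c + off] = _draw_aa(site_rng, 1, exclude="R")[0]
            pos = int(c) + 1  # 1-based
            key = (pid, pos)
            truth.motif_class[key] = str(motif)
            for lab in PRMT_LABELS:
                if pid in truth.substrate_proteins[lab]:
                    truth.substrate_sites[lab].add(key)

    # --- background (unregulated) methyl sites -------------------------
    n_bg = cfg.n_background_sites
    bg_pool = []
    for pid in non_substrates:
        L = len(seqs[pid])
        for c in range(8, L - 8, 29):
            bg_pool.append((pid, c))
    picks = site_rng.choice(len(bg_pool), size=min(n_bg, len(bg_pool)), replace=False)
    for i in picks:
        pid, c = bg_pool[i]
        seqs[pid][c] = "R"
        truth.background_sites.add((pid, int(c) + 1))

    db = ProteomeDB({pid: "".join(seq) for pid, seq in seqs.items()})
    return db, truth


# ---------------------------------------------------------------------------
# SILAC tables


def generate_methyl_tables(
    cfg: SimConfig, proteome: ProteomeDB, truth: GroundTruth
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-perturbation site-quant and protein-quant tables.

    Every perturbation's site table contains all planted sites (its own
    substrates plus everything else, which behaves as unregulated).
    Regulated sites get true ratio ``knockdown_effect`` with log2-normal
    noise; an ``abolished_fraction`` of them lose the heavy channel
    entirely.  A ``confound_fraction`` of substrate proteins get a matching
    drop in the protein-abundance table, making their sites
    protein-explained by construction.
    """
    rng = cfg.rng("methyl")
    all_sites = sorted(
        set().union(*truth.substrate_sites.values()) | truth.background_sites
    )
    out: dict[str, dict[str, pd.DataFrame]] = {}
    all_proteins = sorted(proteome.records)

    for lab in PRMT_LABELS:
        regulated = truth.substrate_sites[lab]
        reg_proteins = sorted(truth.substrate_proteins[lab])
        n_conf = int(round(cfg.confound_fraction * len(reg_proteins)))
        confounded = set(
            rng.choice(reg_proteins, size=n_conf, replace=False).tolist()
            if n_conf
            else []
        )
        truth.confounded_proteins[lab] = confounded

        modalities = _MODALITY_CHOICES[lab]
        rows = []
        for pid, pos in all_sites:
            is_reg = (pid, pos) in regulated
            true_ratio = cfg.knockdown_effect if is_reg else 1.0
            noise = 2.0 ** rng.normal(0.0, cfg.noise_sd)
            ratio = true_ratio * noise
            L = cfg.base_intensity * np.exp(
                rng.normal(0.0, cfg.intensity_log_sd)
            )
            if is_reg:
                mtype = modalities[rng.integers(len(modalities))]
            else:
                mtype = "MMA"
            abolished = (
                is_reg
                and pid not in confounded
                and rng.random() < cfg.abolished_fraction
            )
            H = np.nan if abolished else L * ratio
            rows.append(
                {
                    "protein": pid,
                    "position": pos,
                    "methyl_type": mtype,
                    "intensity_L": L,
                    "intensity_H": H,
                }
            )
        site_df = pd.DataFrame(rows)

        prot_rows = []
        for pid in all_proteins:
            if pid in confounded:
                ratio = cfg.knockdown_effect * 2.0 ** rng.normal(
                    0.0, cfg.noise_sd
                )
            else:
                ratio = 2.0 ** rng.normal(0.0, cfg.noise_sd)
            L = cfg.base_intensity * np.exp(
                rng.normal(0.0, cfg.intensity_log_sd)
            )
            prot_rows.append(
                {"protein": pid, "intensity_L": L, "intensity_H": L * ratio}
            )
        prot_df = pd.DataFrame(prot_rows)

        # a confounded protein's sites must track the protein ratio so the
        # normalized ratio lands near 1
        if confounded:
            pr = prot_df.set_index("protein")
            conf_mask = site_df["protein"].isin(confounded)
            for i in np.flatnonzero(conf_mask.to_numpy()):
                pid = site_df.at[i, "protein"]
                p_ratio = pr.at[pid, "intensity_H"] / pr.at[pid, "intensity_L"]
                if (pid, int(site_df.at[i, "position"])) in regulated:
                    site_df.at[i, "intensity_H"] = (
                        site_df.at[i, "intensity_L"] * p_ratio
                    )

        out[lab] = {"sites": site_df, "proteins": prot_df}
    return out


# ---------------------------------------------------------------------------
# phospho / mutation tables


def generate_context_tables(
    cfg: SimConfig, proteome: ProteomeDB, truth: GroundTruth
) -> dict[str, pd.DataFrame]:
    """Phosphosite and somatic-mutation tables with planted hotspots.

    Phosphosites appear per residue with probability ``phospho_base_density``
    everywhere and ``phospho_enrichment`` times that within
    ±``phospho_window`` of any substrate methyl site (the site position
    itself never carries a phosphate).  Mutations follow the same scheme
    with ``mutation_enrichment`` within ±``mutation_window``; counts are
    1 + Poisson(0.3).
    """
    rng = cfg.rng("context")
    all_substrate_sites = set().union(*truth.substrate_sites.values())
    site_positions: dict[str, np.ndarray] = {}
    for pid, pos in all_substrate_sites:
        site_positions.setdefault(pid, [])
    for pid, pos in all_substrate_sites:
        site_positions[pid].append(pos)
    site_positions = {k: np.asarray(v) for k, v in site_positions.items()}

    phospho_rows = []
    mutation_rows = []
    for pid in sorted(proteome.records):
        L = len(proteome[pid])
        positions = np.arange(1, L + 1)
        centres = site_positions.get(pid)
        if centres is not None and len(centres):
            d = np.min(np.abs(positions[:, None] - centres[None, :]), axis=1)
        else:
            d = np.full(L, np.iinfo(np.int32).max)

        p_phos = np.where(
            d <= cfg.phospho_window,
            cfg.phospho_base_density * cfg.phospho_enrichment,
            cfg.phospho_base_density,
        )
        p_phos = np.minimum(p_phos, 1.0)
        p_phos[d == 0] = 0.0  # an arginine cannot be phosphorylated
        hit = rng.random(L) < p_phos
        for pos in positions[hit]:
            phospho_rows.append({"protein": pid, "position": int(pos)})

        p_mut = np.where(
            d <= cfg.mutation_window,
            cfg.mutation_base_density * cfg.mutation_enrichment,
            cfg.mutation_base_density,
        )
        p_mut = np.minimum(p_mut, 1.0)
        hit = rng.random(L) < p_mut
        for pos in positions[hit]:
            mutation_rows.append(
                {
                    "protein": pid,
                    "position": int(pos),
                    "count": int(1 + rng.poisson(0.3)),
                }
            )
    return {
        "phospho": pd.DataFrame(phospho_rows),
        "mutation": pd.DataFrame(mutation_rows),
    }


# ---------------------------------------------------------------------------
# splicing tables


def _psi_pair(
    rng: np.random.Generator, direction: str, delta: float
) -> tuple[float, float]:
    """(psi_ctl, psi_kd) honouring the latent direction and |ΔPSI|."""
    margin = 1.0 - delta - 0.1
    base = rng.uniform(0.05, 0.05 + max(margin, 0.0))
    if direction == "ES":  # knockdown skips: PSI falls
        psi_ctl = base + delta
        psi_kd = base
    else:  # EI: knockdown includes: PSI rises
        psi_ctl = base
        psi_kd = base + delta
    return float(psi_ctl), float(psi_kd)


def _inc_prob(psi: float, inc_len: float, skip_len: float) -> float:
    """Probability a read supports inclusion, given effective lengths."""
    w_inc = psi * inc_len
    w_skip = (1.0 - psi) * skip_len
    return w_inc / (w_inc + w_skip)


def generate_splice_tables(
    cfg: SimConfig, truth: GroundTruth
) -> dict[str, pd.DataFrame]:
    """Junction-count and upstream-sequence tables for siCTL + 3 knockdowns.

    Per event type, ``n_events_by3`` events are regulated by all three
    PRMTs, ``n_events_by2_pair`` by each pair, ``n_events_by1`` by each
    single PRMT, and the rest are null.  Every regulated event has one
    latent direction (EI or ES) shared by all of its regulators and a true
    |ΔPSI| of ``true_delta_psi``.  Counts are binomial at ``depth`` reads
    per event and condition, with inclusion probability adjusted for the
    effective lengths.  Upstream sequences are uniform ACGT with
    ``n_planted_motif_matches`` copies of ``rna_motif`` written inside the
    central window for events regulated by all three PRMTs.
    """
    from .io_formats import SPLICE_EVENT_TYPES

    rng = cfg.rng("splice")
    conditions = ["siCTL"] + [f"si{lab}" for lab in PRMT_LABELS]
    count_rows = []
    seq_rows = []
    n_design = (
        cfg.n_events_by3 + 3 * cfg.n_events_by2_pair + 3 * cfg.n_events_by1
    )
    if n_design > cfg.n_events_per_type:
        raise ValueError(
            "splice design exceeds n_events_per_type "
            f"({n_design} > {cfg.n_events_per_type})"
        )
    pair_list = [("PRMT4", "PRMT5"), ("PRMT4", "PRMT7"), ("PRMT5", "PRMT7")]

    for etype in SPLICE_EVENT_TYPES:
        regs: list[frozenset[str]] = []
        regs += [frozenset(PRMT_LABELS)] * cfg.n_events_by3
        for pair in pair_list:
            regs += [frozenset(pair)] * cfg.n_events_by2_pair
        for lab in PRMT_LABELS:
            regs += [frozenset({lab})] * cfg.n_events_by1
        regs += [frozenset()] * (cfg.n_events_per_type - n_design)

        for i, regulators in enumerate(regs):
            event_id = f"{etype}_{i:04d}"
            if regulators:
                direction = "EI" if rng.random() < 0.5 else "ES"
                psi_ctl, psi_kd = _psi_pair(rng, direction, cfg.true_delta_psi)
                truth.regulated_events[event_id] = {
                    "event_type": etype,
                    "regulators": sorted(regulators),
                    "direction": direction,
                    "psi_ctl": psi_ctl,
                    "psi_kd": psi_kd,
                }
            else:
                direction = None
                psi_ctl = float(rng.uniform(0.05, 0.95))
                psi_kd = psi_ctl

            for cond in conditions:
                lab = cond[2:] if cond.startswith("si") and cond != "siCTL" else None
                psi = psi_kd if (lab is not None and lab in regulators) else psi_ctl
                p_inc = _inc_prob(psi, cfg.inc_len, cfg.skip_len)
                inc = int(rng.binomial(cfg.depth, p_inc))
                count_rows.append(
                    {
                        "event_id": event_id,
                        "event_type": etype,
                        "condition": cond,
                        "inc_count": inc,
                        "skip_count": cfg.depth - inc,
                        "inc_len": cfg.inc_len,
                        "skip_len": cfg.skip_len,
                    }
                )

            seq = rng.choice(np.array(list("ACGT")), size=cfg.upstream_length)
            if regulators == frozenset(PRMT_LABELS):
                usable = cfg.upstream_length - len(cfg.rna_motif) + 1
                mid = (usable - 1) / 2.0
                half = cfg.motif_center_window / 2.0
                lo = int(np.ceil(mid - half))
                hi = int(np.floor(mid + half)) - len(cfg.rna_motif)
                starts = rng.choice(
                    np.arange(lo, hi),
                    size=cfg.n_planted_motif_matches,
                    replace=False,
                )
                for s in starts:
                    seq[s : s + len(cfg.rna_motif)] = list(cfg.rna_motif)
            seq_rows.append(
                {"event_id": event_id, "upstream_sequence": "".join(seq)}
            )

    return {
        "splice_counts": pd.DataFrame(count_rows),
        "event_seq": pd.DataFrame(seq_rows),
    }


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    cfg: SimConfig, proteome: ProteomeDB, truth: GroundTruth
) -> dict[str, set[str]]:
    """GMT collection: one set seeded with the shared substrates + decoys."""
    rng = cfg.rng("gene_sets")
    universe = sorted(proteome.records)
    by3 = set.intersection(*[truth.substrate_proteins[l] for l in PRMT_LABELS])
    planted = set(by3)
    n_fill = max(0, cfg.gene_set_size - len(planted))
    others = [p for p in universe if p not in planted]
    planted |= set(rng.choice(others, size=n_fill, replace=False).tolist())
    sets = {"SHARED_SUBSTRATE_SET": planted}
    for i in range(cfg.n_random_gene_sets):
        sets[f"RANDOM_SET_{i:02d}"] = set(
            rng.choice(universe, size=cfg.gene_set_size, replace=False).tolist()
        )
    truth.gene_set_planted = "SHARED_SUBSTRATE_SET"
    return sets


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimResult:
    config: SimConfig
    proteome: ProteomeDB
    truth: GroundTruth
    methyl: dict[str, dict[str, pd.DataFrame]]
    context: dict[str, pd.DataFrame]
    splice: dict[str, pd.DataFrame]
    gene_sets: dict[str, set[str]]


def simulate(cfg: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate every pipeline input; optionally write them to *outdir*."""
    proteome, truth = generate_proteome(cfg)
    methyl = generate_methyl_tables(cfg, proteome, truth)
    context = generate_context_tables(cfg, proteome, truth)
    splice = generate_splice_tables(cfg, truth)
    gene_sets = generate_gene_sets(cfg, proteome, truth)
    result = SimResult(cfg, proteome, truth, methyl, context, splice, gene_sets)
    if outdir is not None:
        write_sim(result, outdir)
    return result


def write_sim(result: SimResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.proteome, outdir / "proteome.fa")
    for lab, tables in result.methyl.items():
        write_table(tables["sites"], outdir / f"sites_si{lab}.tsv")
        write_table(tables["proteins"], outdir / f"proteins_si{lab}.tsv")
    write_table(result.context["phospho"], outdir / "phospho.tsv")
    write_table(result.context["mutation"], outdir / "mutations.tsv")
    write_table(result.splice["splice_counts"], outdir / "splice_counts.tsv")
    write_table(result.splice["event_seq"], outdir / "event_seq.tsv")
    write_gmt(result.gene_sets, outdir / "gene_sets.gmt")
    manifest = {
        "config": dataclasses.asdict(result.config),
        "truth": result.truth.to_jsonable(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
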