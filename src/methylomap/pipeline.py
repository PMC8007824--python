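"""End-to-end orchestration: simulate inputs, run every analysis stage and
emit a machine-readable run report.

The report is deterministic under a fixed seed: it echoes the full
configuration (thresholds included), summarises each stage from its output
tables, and contains no timestamps.  Every number in it is read back from a
stage result, never recomputed report-side.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from . import splicing
from .enrichment_sets import ora
from .methylome_calling import (
    DEFAULT_FOLD_CHANGE,
    DEFAULT_MODALITIES,
    call_methylome,
    intersect_methylomes,
    sites_per_protein,
)
from .sequence_context import (
    extract_window,
    motif_fractions,
    positional_enrichment,
)
from .site_context import (
    mutation_enrichment,
    phospho_background,
    phospho_proximity,
)
from .synthetic_data import PRMT_LABELS, SimConfig, SimResult, simulate

logger = logging.getLogger(__name__)

DEFAULT_PIPELINE_CONFIG: dict[str, Any] = {
    "seed": 0,
    "fold_change": DEFAULT_FOLD_CHANGE,
    "delta_psi": splicing.DEFAULT_DELTA_PSI,
    "min_total": splicing.DEFAULT_MIN_TOTAL,
    "fpkm_threshold": 0.5,
    "window_k": 5,
    "phospho_window": 3,
    "mutation_window": 5,
    "motif_n_samples": 200,
    "motif_sample_size": 200,
    "motif_alpha": 0.01,
    "phospho_resamples": 199,
    "rna_motif_window": 100,
    "simulate": {},  # SimConfig overrides
}


def _merge_config(overrides: Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))
    for key, val in (overrides or {}).items():
        if key == "simulate":
            cfg["simulate"].update(val)
        elif key in cfg:
            cfg[key] = val
        else:
            raise ValueError(f"unknown pipeline config key {key!r}")
    return cfg


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = list(obj) if not isinstance(obj, (set, frozenset)) else sorted(obj)
        return [_jsonable(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, float) and (obj != obj):  # NaN -> null for valid JSON
        return None
    return obj


def _file_checksums(directory: Path) -> dict[str, str]:
    out = {}
    for path in sorted(directory.iterdir()):
        if path.is_file():
            out[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out


def run_pipeline(
    config: Mapping[str, Any] | None = None,
    outdir: str | Path | None = None,
) -> dict[str, Any]:
    """Simulate inputs, run every stage in dependency order, return report.

    When *outdir* is given, the simulated inputs, per-stage tables and the
    JSON report (``report.json``) are written there.
    """
    cfg = _merge_config(config)
    sim_cfg = SimConfig(seed=cfg["seed"], **cfg["simulate"])
    outdir = Path(outdir) if outdir is not None else None
    sim_dir = outdir / "sim" if outdir else None

    logger.info("stage simulate: seed=%d", sim_cfg.seed)
    sim = simulate(sim_cfg, outdir=sim_dir)

    report: dict[str, Any] = {
        "tool": {"name": "methylomap", "version": __version__},
        "config": {**cfg, "simulate": dataclasses.asdict(sim_cfg)},
    }

    # --- substrate calling ------------------------------------------------
    logger.info("stage call: substrate calling for %s", PRMT_LABELS)
    methylomes = {}
    tallies = {}
    for lab in PRMT_LABELS:
        m, tally = call_methylome(
            sim.methyl[lab]["sites"],
            sim.methyl[lab]["proteins"],
            prmt_label=lab,
            modality_filter=DEFAULT_MODALITIES[lab],
            fold_change=cfg["fold_change"],
        )
        methylomes[lab] = m
        tallies[lab] = tally
    inter = intersect_methylomes(list(methylomes.values()), level="protein")
    recovery = {}
    for lab in PRMT_LABELS:
        called = methylomes[lab].proteins
        expected = sim.truth.expected_methylome(lab)
        tp = len(called & expected)
        recovery[lab] = {
            "n_called": len(called),
            "n_expected": len(expected),
            "precision": tp / len(called) if called else float("nan"),
            "recall": tp / len(expected) if expected else float("nan"),
        }
    report["calling"] = {
        "tallies": tallies,
        "overlap_classes": {
            str(k): v for k, v in inter.class_counts().items()
        },
        "sites_per_protein_PRMT7": sites_per_protein(methylomes["PRMT7"]),
        "recovery_vs_truth": recovery,
    }

    # --- sequence context -------------------------------------------------
    logger.info("stage motif: windows and positional enrichment")
    windows = [
        extract_window(sim.proteome, pid, pos, k=cfg["window_k"])
        for pid, pos in sorted(methylomes["PRMT7"].site_keys)
    ]
    fractions = motif_fractions(windows)
    enr = positional_enrichment(
        windows,
        sim.proteome,
        n_samples=cfg["motif_n_samples"],
        sample_size=cfg["motif_sample_size"],
        seed=sim_cfg.seed,
        alpha=cfg["motif_alpha"],
    )
    g_cells = {
        f"{off:+d}": float(enr.cell(off, "G")["z"]) for off in (-1, 1, 2)
    }
    report["motif"] = {
        "n_windows": len(windows),
        "fractions": fractions,
        "glycine_z_at_offsets": g_cells,
        "n_flagged_cells": int(enr.table["flagged"].sum()),
        "seed": enr.seed,
    }

    # --- site context -----------------------------------------------------
    logger.info("stage context: phospho proximity and mutation enrichment")
    fg_sites = sorted(methylomes["PRMT7"].site_keys)
    prox = phospho_proximity(
        fg_sites, sim.context["phospho"], half_width=cfg["phospho_window"]
    )
    bg = phospho_background(
        sim.proteome,
        sim.context["phospho"],
        n_fg=len(fg_sites),
        observed_frac_ge1=prox.frac_ge1,
        half_width=cfg["phospho_window"],
        n_resamples=cfg["phospho_resamples"],
        seed=sim_cfg.seed,
    )
    from .sequence_context import all_arginine_sites

    bg_arg = set(all_arginine_sites(sim.proteome))
    mut_at = mutation_enrichment(
        fg_sites,
        bg_arg,
        sim.context["mutation"],
        mode="at_site",
        proteome=sim.proteome,
    )
    mut_vic = mutation_enrichment(
        fg_sites,
        bg_arg,
        sim.context["mutation"],
        half_width=cfg["mutation_window"],
        mode="vicinity",
        proteome=sim.proteome,
    )
    report["context"] = {
        "phospho_bins": prox.bin_fractions,
        "phospho_frac_ge1": prox.frac_ge1,
        "phospho_bg_mean_ge1": float(bg.frac_ge1_bg.mean()),
        "phospho_p": bg.p_value,
        "mutation_at_site": {
            "rate_fg": mut_at.rate_fg,
            "rate_bg": mut_at.rate_bg,
            "odds_ratio": mut_at.odds_ratio,
            "p": mut_at.p_value,
        },
        "mutation_vicinity": {
            "rate_fg": mut_vic.rate_fg,
            "rate_bg": mut_vic.rate_bg,
            "odds_ratio": mut_vic.odds_ratio,
            "p": mut_vic.p_value,
        },
    }

    # --- splicing ---------------------------------------------------------
    logger.info("stage splice: delta-PSI calls and concordance")
    calls = {
        lab: splicing.call_events(
            sim.splice["splice_counts"],
            "siCTL",
            f"si{lab}",
            threshold=cfg["delta_psi"],
            min_total=cfg["min_total"],
        )
        for lab in PRMT_LABELS
    }
    summaries = {lab: splicing.summarize_events(df) for lab, df in calls.items()}
    conc = splicing.concordance_analysis(calls)
    by3_ids = set(
        conc.per_event.loc[
            conc.per_event["n_regulators"] == 3, "event_id"
        ]
    )
    seq_df = sim.splice["event_seq"]
    shared_seqs = seq_df.loc[
        seq_df["event_id"].isin(by3_ids), "upstream_sequence"
    ].tolist()
    if shared_seqs:
        rna = splicing.central_motif_enrichment(
            shared_seqs, sim_cfg.rna_motif, cfg["rna_motif_window"]
        )
        rna_summary = {
            "motif": sim_cfg.rna_motif,
            "n_sequences": len(shared_seqs),
            "n_matches": rna.n_matches,
            "n_in_window": rna.n_in_window,
            "p": rna.p_value,
        }
    else:
        rna_summary = {"motif": sim_cfg.rna_motif, "n_sequences": 0}
    report["splicing"] = {
        "summaries": summaries,
        "class_counts": {str(k): v for k, v in conc.class_counts.items()},
        "n_concordant": conc.n_concordant,
        "n_discordant": conc.n_discordant,
        "concordance_fraction": conc.concordance_fraction,
        "rna_motif": rna_summary,
    }

    # --- ORA ----------------------------------------------------------------
    logger.info("stage ora: shared substrates vs gene sets")
    universe = set(sim.proteome.records)
    query = set.intersection(*[methylomes[l].proteins for l in PRMT_LABELS])
    if query:
        ora_table = ora(query, sim.gene_sets, universe)
        top = ora_table.iloc[0]
        ora_summary = {
            "n_query": len(query),
            "top_set": str(top["set_name"]),
            "top_p": float(top["p_value"]),
            "top_q": float(top["bh_q"]),
        }
    else:
        ora_summary = {"n_query": 0}
    report["ora"] = ora_summary

    report = _jsonable(report)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        for lab, m in methylomes.items():
            m.sites.to_csv(outdir / f"methylome_{lab}.tsv", sep="\t", index=False)
        for lab, df in calls.items():
            df.to_csv(outdir / f"splice_calls_{lab}.tsv", sep="\t", index=False)
        if sim_dir is not None and sim_dir.exists():
            report["input_checksums"] = _file_checksums(sim_dir)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report
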