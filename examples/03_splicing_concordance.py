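"""Differential splicing calls and cross-PRMT direction concordance.

Computes PSI from junction counts for siCTL vs each knockdown, calls
events at |dPSI| >= 0.5, partitions them by how many PRMTs regulate them,
and checks that shared events move in the same direction.
"""

from methylomap.splicing import (
    call_events,
    central_motif_enrichment,
    concordance_analysis,
    summarize_events,
)
from methylomap.synthetic_data import PRMT_LABELS, SimConfig, simulate

sim = simulate(SimConfig(seed=1))
counts = sim.splice["splice_counts"]

calls = {lab: call_events(counts, "siCTL", f"si{lab}") for lab in PRMT_LABELS}
for lab in PRMT_LABELS:
    s = summarize_events(calls[lab])["total"]
    print(f"{lab}: {s['differential']} differential events "
          f"({s['EI']} EI, {s['ES']} ES)")

conc = concordance_analysis(calls)
print(f"regulated by one/two/three PRMTs: "
      f"{conc.class_counts[1]}/{conc.class_counts[2]}/{conc.class_counts[3]}")
print(f"shared-event direction concordance: {conc.concordance_fraction:.2f} "
      f"({conc.n_discordant} discordant)")

by3 = set(conc.per_event.loc[conc.per_event["n_regulators"] == 3, "event_id"])
seqs = sim.splice["event_seq"]
shared = seqs.loc[seqs["event_id"].isin(by3), "upstream_sequence"].tolist()
rna = central_motif_enrichment(shared, sim.config.rna_motif, 100)
print(f"RNA motif {sim.config.rna_motif}: {rna.n_in_window}/{rna.n_matches} "
      f"matches central, binomial p = {rna.p_value:.2g}")
print("# concordance 1.0 reflects the single planted latent direction per")
print("# shared event; the central motif p recovers the splicing-factor")
print("# binding site planted upstream of shared exons")
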