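# methylomap

Integrative analysis of protein arginine methyltransferase (PRMT)
substrates and their downstream consequences, built for proteomics and
RNA-biology groups who quantify methylation with SILAC mass spectrometry
and splicing with RNA-seq junction counts.

PRMT enzymes methylate the guanidinium group of arginine: type I enzymes
(e.g. PRMT4/CARM1) produce mono-methyl arginine (MMA) and asymmetric
di-methyl arginine (aDMA), type II (e.g. PRMT5) MMA and symmetric di-methyl
arginine (sDMA), and the sole type III enzyme PRMT7 MMA only.  Knocking
down one enzyme and comparing methyl-site intensities between control
(light) and knockdown (heavy) SILAC channels identifies its substrates; the
called substrate set is that enzyme's *methylome*.  `methylomap` implements
the full downstream analysis:

- **Substrate calling** (`methylome_calling`): a site with heavy/light
  ratio r_HL ≤ 1/t (default t = 2, boundary inclusive) is *decreased*; a
  site detected light-only is *abolished* and counts as decreased.  Sites
  whose drop tracks a matching protein-abundance change are flagged
  `protein_explained` and excluded from the methylome.  Cross-PRMT
  intersection partitions substrates into regulated-by-1/2/3 classes at
  protein or (protein, position) level.
- **Sequence context** (`sequence_context`): 2k+1 residue windows around
  each methyl-arginine (default k = 5), GAR (RG/RGG) vs RXR motif classes,
  and a sampled-background positional enrichment
  Z = (f_fg − mean_bg) / sd_bg per (offset, residue) cell, with the
  background drawn as random arginine-centred window sets from the
  proteome.
- **Site context** (`site_context`): phosphosite counts within ±3 (or ±5)
  residues with a resampled arginine null and add-one empirical p-values;
  somatic-mutation rates at or around methyl sites with a two-sided
  Fisher's exact test computed in exact integer arithmetic.
- **Splicing** (`splicing`): PSI = (inc/inc_len) / (inc/inc_len +
  skip/skip_len) per event and condition; differential calls at
  |ΔPSI| = |PSI(ctl) − PSI(kd)| ≥ 0.5; exon-inclusion (EI) vs skipping
  (ES) direction induced by the knockdown; cross-regulator concordance;
  FPKM expression filter; and a central positional motif-enrichment test
  (binomial tail) for upstream regions of shared alternative exons.
- **Set statistics** (`enrichment_sets`): one-sided hypergeometric overlap
  tests with explicit universes and GMT-based over-representation analysis
  with Benjamini–Hochberg correction.
- **Synthetic data** (`synthetic_data`): a seeded generator that emits
  every input table with planted ground truth — substrate overlap design,
  motif mix, knockdown effect and abolished sites, phospho/mutation
  hotspots, and shared splicing events with one latent direction each — so
  every stage is testable end to end without external downloads.

## Worked example

```sh
python examples/01_substrate_calling.py
```

prints (seed 1, default study design of 200 substrate proteins per PRMT
and a true knockdown ratio of 0.2):

```
calling cascade (sites):
  sites_detected                      1280
  sites_quantified_incl_abolished     1280
  sites_decreased                     300
  sites_abolished                     184
methylome: 299 sites on 200 proteins
precision 1.000  recall 1.000
```

The cascade shrinks from detected to abolished exactly as a knockdown
experiment should, and the called methylome recovers the planted substrate
set perfectly at the default noise level.  The other examples cover motif
and disease context (`02`), splicing concordance (`03`) and set statistics
(`04`); each prints the numbers it computes with a note on what they mean.

A thin CLI mirrors the library:

```sh
methylomap simulate --seed 1 --outdir sim/
methylomap call --sites sim/sites_siPRMT7.tsv --proteins sim/proteins_siPRMT7.tsv \
    --label PRMT7 --modalities MMA --out methylome.tsv --tally tally.json
methylomap report --seed 1 --outdir run/
```

## Layout

- `src/methylomap/` — the library (one module per stage).
- `examples/` — narrative scripts, one per capability.
- `tests/` — unit, property and acceptance tests (seeded/derandomised).
- `docs/methods.md` — models, assumptions, parameter defaults and
  limitations.
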