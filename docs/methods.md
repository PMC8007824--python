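# Methods

## Substrate calling from SILAC ratios

Each methyl site carries a light (control) and heavy (perturbed) intensity.
The calling cascade is:

1. **Ratio.** r_HL = I_H / I_L when both channels are present and I_L > 0.
   Intensities of exactly zero are coerced to "absent": zero means below
   the detector floor, which is the operational meaning of an abolished
   signal.  Absence is a first-class state (NaN), never silently zero.
2. **Classification** (total function): light absent → `not_quantified`;
   heavy absent → `abolished`; r_HL ≤ 1/t → `decreased` (boundary
   inclusive); r_HL ≥ t → `increased`; otherwise `unchanged`.  The
   fold-change threshold t defaults to 2 and must exceed 1.
3. **Protein-abundance control.** normalized ratio = r_HL / r_protein.  A
   raw `decreased` site whose normalized ratio rises above 1/t is flagged
   `protein_explained`: its methylation merely tracked protein amount.
   The threshold is applied to the **raw** ratio and normalization only
   flags; it never re-admits sites that failed the raw cut.  Sites without
   protein quantification are retained un-normalized — proteins missed by
   proteome profiling should not silently vanish from the methylome.
4. **Methylome.** Decreased/abolished, not protein-explained sites;
   substrate proteins are their projection.  Abolished sites count as
   decreased in every tally.  Whether "quantified" includes abolished
   sites is a reporting convention, not a fact about the data, so the
   tally reports both (`sites_quantified` and
   `sites_quantified_incl_abolished`); the monotone cascade invariant
   (detected ≥ quantified ≥ decreased ≥ abolished) holds for the inclusive
   convention.

Deduplication key is (protein, position, methyl type): the same site
recovered from several immuno-enrichment experiments is counted once.
Modalities follow enzyme class — PRMT4 tables keep MMA+aDMA, PRMT5
MMA+sDMA, PRMT7 MMA — matching the antibody panels such experiments use.
There is no replicate model: one table per perturbation.

Cross-PRMT intersection at `position` level keys on (protein, position)
and ignores methyl type, because one arginine can carry me1, me2a or me2s
depending on the acting enzyme.

## Sequence windows and motif classes

Windows are 2k+1 residues (default k = 5, an 11-residue window) centred on
the methyl-arginine, padded with `-` past the termini; the centre must be
`R` (anything else is treated as a coordinate bug and raised).  Motif
classes: **GAR** when glycine sits at offset −1 or +1 (covers RG, GR and
RGG contexts), else **RXR** when another arginine sits at ±2, else
**other**.  GAR wins on overlaps such as RGR, so the classes are disjoint
and exhaustive; the window only needs k ≥ 2 for classification.

Positional enrichment draws `n_samples` random arginine-centred window
sets of `sample_size` from the proteome (without replacement within a
draw), computes per-(offset, residue) frequency means and standard
deviations, and scores each foreground cell as
Z = (f_fg − mean_bg) / sd_bg with a two-sided normal p and a percent
difference (f_fg − mean_bg)·100.  The background is arginine-anchored
(not all residues) because the foreground is, by construction, arginine-
centred.  Pad characters are excluded from frequency denominators.  A zero
background sd yields a signed-infinity Z when the foreground differs and 0
otherwise.  Sampling is seeded and the seed recorded in the result.

## Phospho proximity and mutation enrichment

Phospho counts per methyl site are |{p : |p − site| ≤ w, p ≠ site}| with
w ∈ {3, 5}; the site position itself is excluded since an arginine cannot
carry a phosphate.  The null resamples `n_fg` arginine positions uniformly
without replacement from the proteome `n_resamples` times; the empirical
p-value for the observed "≥1 phospho nearby" fraction uses the add-one
correction (1 + #{bg ≥ obs}) / (1 + n), so it never reports zero.

Mutation rates collapse the mutation table to a binary "position mutated
at least once" indicator.  `at_site` mode considers the sites themselves;
`vicinity` the deduplicated union of ±w residues (centre included, clipped
to protein bounds).  The window is measured in amino acids.  Enrichment
builds a 2×2 table (mutated/not × foreground/background) with the
foreground removed from the background so rows are disjoint, and tests it
with a two-sided Fisher's exact test.

Fisher's exact p-values are computed in **exact integer arithmetic**: the
p-value is the sum, over all tables with the observed margins, of
probabilities of tables whose hypergeometric weight (an integer) does not
exceed the observed table's.  Integer comparison avoids the floating-point
tie-breaking ambiguity that a "point probability ≤ observed" rule
otherwise inherits; the test suite checks agreement with an independent
full-enumeration oracle to |Δp| < 1e−10 over every 2×2 table with total
≤ 60, and with the scipy implementation on reference tables.

## Splicing

PSI uses effective-length normalization,
psi = (inc/inc_len) / (inc/inc_len + skip/skip_len), because the inputs
are junction counts; with equal lengths it reduces to inc/(inc+skip), the
plain isoform-ratio definition (asserted as a property).  Events with
fewer than `min_total` reads (default 10) in a condition are "not
testable" and reported as such rather than dropped — a coverage guard this
package adds, exposed as a parameter.  ΔPSI = PSI(ctl) − PSI(kd);
differential iff |ΔPSI| ≥ 0.5 (inclusive).  Direction names the change the
knockdown induces: EI when PSI rises upon knockdown, ES when it falls, so
swapping conditions negates ΔPSI and swaps EI↔ES.

Concordance analysis requires one common event universe across the three
regulators (an error otherwise, since a by-2/by-3 partition over unequal
universes conflates "not regulated" with "not measured"), partitions
differential events by regulator count, and flags shared events concordant
iff every regulating enzyme calls the same direction.

FPKM = reads / (exonic_kb) / (total_reads/1e6); genes are kept iff FPKM is
strictly greater than 0.5 in at least one condition.

The central motif test is a simplified positional-enrichment analogue for
upstream-of-3'-splice-site sequences: IUPAC motif matches whose start
falls inside a fixed-width window centred on each sequence's usable start
range are "central"; under uniform placement the central fraction is
p0 = window starts / usable starts, and the one-sided binomial tail
P[X ≥ observed] scores the excess.  It uses one fixed window width rather
than scanning widths, and no control-sequence comparison.

## Set statistics

The overlap test is the one-sided hypergeometric tail
P[X ≥ |a∩b|], X ~ HG(M=|universe|, K=|a|, n=|b|), identical to a one-sided
Fisher test on the equivalent 2×2 table (asserted cross-module to
|Δ| < 1e−10).  The universe must be supplied explicitly; there is no
silent default, because an overlap p-value is undefined without one.  ORA
runs one overlap test per GMT set (intersected with the universe) and
corrects across sets with Benjamini–Hochberg.

## Synthetic-data generator

The generator defines the study conditions on which the package is
validated.  Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 800 | proteome size; lengths lognormal, mean ≈ 450 aa |
| `n_unique_substrates` / `n_by2_pair` / `n_by3` | 120 / 20 / 40 | overlap design; 200 substrates per PRMT |
| `sites_extra_lambda` | 0.47 | extra sites per substrate ~ Poisson, so ≈ 37% of substrates carry > 1 site |
| `frac_gar` / `frac_rxr` | 0.60 / 0.20 | planted motif mix at substrate sites |
| `knockdown_effect` | 0.2 | true heavy/light ratio at regulated sites (five-fold drop) |
| `noise_sd` | 0.3 | sd of the log2 ratio error |
| `abolished_fraction` | 0.6 | regulated sites losing the heavy channel entirely |
| `confound_fraction` | 0.0 | substrate proteins whose drop is protein-level |
| `phospho_enrichment` / `mutation_enrichment` | 10 / 5 | density factors near substrate sites |
| `true_delta_psi` / `depth` | 0.7 / 1000 | planted splicing effect and per-event coverage |

Measured ratios are true_ratio · 2^e with e ~ N(0, noise_sd): the noise is
defined on the log2 scale, where SILAC ratios are conventionally analysed.
The amino-acid background is a fixed frequency table shipped as a module
constant (approximate vertebrate composition), not sampled from any
external proteome.  Each output stream has its own child generator derived
from the master seed through fixed spawn keys, so regenerating one table
never perturbs another and outputs are byte-identical across runs with the
same seed.

What the generator does **not** emulate: peptide-level identification and
localization uncertainty, missing-at-random heavy channels on unregulated
sites (heavy-channel dropout occurs only at regulated sites), intensity-
dependent variance, replicate structure, correlated mutation hotspots
beyond the planted windows, and read-level splicing artefacts (alignment
error, novel splice sites).  Passing tests therefore demonstrate the
correctness of the calling, statistics and bookkeeping under the stated
model, not robustness to every failure mode of real acquisitions.

## Numerical and design choices

- Residue positions are 1-based everywhere; splice conditions are named
  strings; tables are tab-delimited UTF-8 with `#` comments.
- Empirical p-values use the add-one correction; exact tests use integer
  or scipy hypergeometric arithmetic; BH correction via statsmodels.
- The figure-level ambiguity between a nucleotide and an amino-acid
  mutation window is resolved in favour of amino acids, and the window is
  a parameter.
- The GAR/RXR boundary for overlapping patterns (RGR) is this package's
  decision (GAR precedence), chosen so the two reported fractions are
  disjoint.
- Default problem sizes (800 proteins, ~1300 sites, 400 events, 200-draw
  backgrounds, 999 resamples) keep a full run in seconds on one core
  while leaving every statistic well-powered; they scale up linearly via
  the config.

## Known limitations

- No replicate or variance model for SILAC ratios: one swap per
  perturbation, as in a single-comparison design.
- `protein_explained` flags rather than deletes; consumers must respect
  the flag.
- The positional-enrichment normal approximation is poor for very small
  foregrounds (< ~50 windows); the sampled background sd is then noisy.
- The central motif test assumes approximately equal-length sequences for
  a sharp p0; heterogeneous lengths are pooled through their aggregate
  start counts.
- ORA treats gene sets as unstructured; no redundancy clustering of
  related sets.
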