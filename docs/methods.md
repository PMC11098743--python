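# Methods

This note documents the models, parameter choices and numerical decisions
behind `fluxscreen`, and what the synthetic-data generators do and do not
emulate.

## Screen scoring

### Phenotype model

Counts for a (treated, control) sample pair are first depth-matched to the
geometric mean of their totals, so the pipeline is invariant to uniform
sequencing-depth rescaling of either sample (exactly so at pseudocount 0,
and up to a bounded ψ/min-count effect otherwise). sgRNAs must reach
`min_count` (default 100; 25 for tumour screens, where coverage per tumour
is lower) in at least one of the two depth-matched samples; retained sgRNAs
receive a pseudocount ψ = 10. Applying the filter and pseudocount on the
depth-matched scale keeps both comparable across samples of different
depth — the alternative (raw counts) makes the filter depth-dependent.

The per-sgRNA phenotype is

    rho_i = [ log2((c_i,t + ψ) / (c_i,c + ψ)) − median_NTC ] / D ,

centred so the NTC median is exactly zero and divided by the population
doublings D of the screen; in vivo screens set D := 1 because tumour
doubling numbers are not measurable per replicate. Technical replicates are
averaged before any of this, on a reads-per-million scale.

### Gene-level statistics

Each 10-sgRNA unit (a transcription start site; 37 genes carry two TSSs and
the gene inherits the TSS unit with the larger |screen score|) is summarized
by:

* phenotype score PS: the signed mean of the `top_k = 7` phenotypes largest
  in absolute value. Selection is by |rho| with a stable sort, so exact ties
  resolve deterministically by input order.
* p: two-sided Mann–Whitney of the unit's rhos against all NTC rhos. When
  both groups have ≤ 12 observations the p value is exact, computed by a
  dynamic program over the permutation distribution of the rank sum on
  (doubled) midranks, which remains correct under ties; otherwise the normal
  approximation with tie and continuity correction is used. p is floored at
  1e−16 before taking −log10, capping a screen score's significance factor
  at 16.
* screen score SS = PS · (−log10 p).

A unit must retain at least `min_sgrnas = 5` phenotypes after filtering to
be scored; otherwise it is reported unscored rather than raising.

### Significance calibration

Pseudogenes — as many random groups of 10 NTC sgRNAs as there are real
genes, sampled without replacement within a group and with replacement
across groups (730 NTCs cannot supply 489 disjoint groups) — are scored
identically to real genes. Thresholds are the extreme pseudogene screen
scores; for replicate screens they are taken per replicate, before
averaging (the stringent variant), and a hit must clear the cut-off in
every replicate as well as on the replicate average. This reproducibility
requirement matters quantitatively: the averaged score of one in ~500 null
genes occasionally drifts past the extreme of the (internally correlated,
because members are reused) pseudogene null, whereas requiring every
replicate to clear the bar makes a null exceedance vanishingly rare while
leaving genuine hits — whose per-replicate scores sit far beyond the
cut-off — untouched.

Hits that score below −0.12 in the untreated control arm of a screen in any
single replicate are reset to non-significant unless strongly resistant
(> 1.5) or hypersensitive in the test condition: a general slowdown in
proliferation produces spurious pan-resistance. The paper quantifies only
the resistant side; the hypersensitive cut-off defaults to −1.5 (mirroring
+1.5) and is configurable.

### In vivo screens

Tumour replicates are ranked by a noise metric — the number of NTC sgRNAs
whose counts lie outside ±1 log2 of the NTC median — and the two noisiest
of six are excluded. Survivors are paired by metric rank (1st with 2nd, 3rd
with 4th); pairing of surviving tumours is not specified by the source
protocol, and rank-matching keeps similarly noisy samples together. Pair
members are rescaled to their mean total and averaged. Growth scores from
tumour screens are reported after division by |most depleted score|, so the
minimum is exactly −1.

Cross-condition similarity is the pairwise Pearson correlation of screen
scores over genes significant in at least one condition, with an optional
display filter dropping genes that never score below −0.20 or above 0.10.

## Tracer kinetics

### Model and assumptions

The assay runs at metabolic steady state: the free intracellular pool P of
each amino acid is constant, and switching cells into medium whose amino
acids are fully heavy-labelled exchanges the pool at rate k = J_in/P:
H(t) = P(1 − e^(−kt)). The import flux is the initial slope of H(t),
estimated by ordinary least squares inside a per-amino-acid window chosen
short enough that curvature is negligible (defaults: 100 s for
Asn/Asp/Gln/Glu/Pro; 40 s for Arg/Gly/His/Ile/Lys/Ser/Thr/Val; 20 s for
Leu/Tyr; 10 s for Phe; all overridable). Rates are reported as slope ± SE
in pmol·min⁻¹ per 10⁶ cells, with the effective cell number defaulting to
0.64 × 10⁶ (0.8 × 10⁶ in the monolayer minus ~20% wash loss).

### Correction chain

Raw isotopologue ion counts pass through, in this fixed order:

1. **Natural-abundance deconvolution.** The forward matrix A maps a
   labelling distribution to the observed spectrum: column j is a delta at
   +j convolved with the natural-isotope mass-shift distribution of the
   molecule's unlabelled atoms, truncated to the observable M+0..M+n window
   and column-renormalized (redistributing the tiny truncated tail, so
   total signal is conserved). The labelling distribution is recovered per
   timepoint by non-negative least squares; matrices with condition number
   above 1e8 are rejected.
2. **Internal standard.** Each timepoint is divided by its norvaline signal
   relative to the time-course mean, removing per-sample handling
   variability.
3. **Steady-state TIC.** Import assays divide by TIC_t / mean TIC; the
   consumption assay, whose TIC carries a genuine trend, divides by
   TIC_t / fitted TIC(t) from a linear regression, preserving the trend
   while removing scatter. These two corrections do not commute with the
   internal-standard step in general (the TIC mean is recomputed after
   norvaline scaling); the order above is fixed and matches the assay
   protocols.
4. **Volume accounting (consumption only).** Each 15 µl draw from the
   300 µl well removes analyte; the corrected level is
   conc_t · V_remaining(t) plus the amounts carried away by earlier draws,
   expressed per initial volume. A cell-free constant-concentration medium
   therefore gives an exactly constant corrected level, and consumption
   slopes are free of the sampling artefact.
5. **Absolute quantification.** pmol = (ions − intercept)/slope scaled by
   the standard-to-sample norvaline ratio, with the per-amino-acid linear
   response fit by unweighted OLS through ≥ 3 dilution points (free
   intercept). Negative values after intercept subtraction clip to zero
   with a warning.

### Heavy-signal quantification

Because medium amino acids are labelled all-or-none, every transported
molecule appears in the fully-labelled M+n channel after deconvolution; the
partially labelled channels carry only the correction residual of the large
unlabelled pool's natural-abundance satellites. The default therefore
quantifies transported label as the M+n channel alone. Summing M+1..M+n is
available as an option and is identical in expectation, but at realistic
per-channel measurement noise the M+1 residual (an absolute error scaling
with the pool, not with the small early heavy signal) roughly doubles the
rate error on low-flux/large-pool amino acids.

Consumption rates are minus the slope of medium amounts over time (positive
for depleted amino acids, negative for secreted ones such as Asn, Asp, Glu,
Gly and Pro); export rates are the slope of labelled amounts released into
fresh medium. Intracellular levels are the mean total (labelled plus
unlabelled) amount over the time course, and pool turnover is
k_turn = J_in / level.

## Competition and plate assays

The qPCR competition phenotype is −ΔΔCt / D: ΔCt = Ct_test − Ct_ntc, ΔΔCt
its change from T0 to endpoint, and D either the doubling difference
between test and reference media (low-nutrient assays) or the test
condition's total doublings (complete media). The sign convention — higher
Ct means less template, so depletion of the test line is negative — matches
screen-score signs. Primer efficiency defaults to exactly 2 per cycle, with
an efficiency-corrected mode for primers validated at other efficiencies.
The estimator exactly inverts the noiseless competition simulator for any
effect size and doubling schedule.

Viability titrations average quadruplicate luminescence readings, divide by
T0, normalize within the plate to a control condition and report log2
population doublings; a layout table remaps spatially randomized plates.
Lipid peroxidation is the oxidized/reduced fluorescence ratio normalized to
a control condition.

## Synthetic-data generators

The generators define the study conditions for every test:

* **Screens.** Initial sgRNA abundances are lognormal (σ = 0.5, a typical
  post-cloning library skew where the 90/10 abundance ratio is ~3.6-fold);
  each biological replicate draws its own abundances (independent
  transductions). Growth is multiplicative, 2^(D(1 + efficacy·e_g)), with
  the fitness effect acting only in selective arms, so the expected rho
  equals e_g after doubling normalization. Sequencing is multinomial at
  500 reads/sgRNA by default. Not emulated: PCR amplification bias, sgRNA
  off-target effects, overdispersion beyond multinomial, tumour spatial
  bottlenecks — so passing recovery tests demonstrates the statistics, not
  robustness to those artefacts.
* **Tracers.** All-or-none labelling, forward natural-abundance
  convolution through the same matrix the correction inverts, a per-pmol
  ion-count response of 50, a shared per-timepoint handling factor
  (affecting the norvaline channel, so the internal-standard correction has
  something real to remove) and independent per-channel lognormal noise,
  both at CV 5%. Chromatographic peak integration and derivatization
  chemistry are upstream and not modelled; fragment formulas are
  user-supplied so derivatization atoms can be included or not.
* **Competition.** Ct values from known mixture fractions under perfect
  doubling per cycle, exactly invertible when noiseless.

## Problem sizes

The test suite and the acceptance script run the full 489-gene, 5,990-sgRNA
library: spiked-recovery and null-calibration checks use 10 simulation
seeds each at 2 replicates and 500 reads/sgRNA; tracer recovery uses 100
series with import fluxes log-uniform on [1, 500] pmol·min⁻¹·(10⁶ cells)⁻¹
and pools on [50, 5000] pmol, the eight-timepoint schedule (0–250 s) and 5%
noise. These sizes make the statistical checks sharp while keeping a full
run to a couple of minutes.

## Known limitations

* Pseudogene scores are internally correlated (489 groups drawn from 730
  NTCs), so their extremes slightly understate the extremes of an equally
  sized set of independent null genes; the per-replicate threshold source
  and the reproducibility requirement compensate.
* The Mann–Whitney exact branch is limited to groups of ≤ 12; gene-vs-NTC
  comparisons (10 vs 730) always use the corrected normal approximation.
* In vivo doubling numbers are unknown, so tumour phenotypes are per-screen
  log2 enrichments, comparable within but not across screens (hence the
  normalization to the most depleted gene).
* Import-rate estimation assumes the regression window is short relative to
  1/k; for very high-turnover conditions (k·t_window ≳ 0.5) the initial
  slope systematically underestimates the flux, which is why windows are
  per-amino-acid and overridable.
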