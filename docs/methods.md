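# Methods

## The mitotic-entry network

The model describes the commitment of a human cell to mitosis as the
interplay of two cyclin:Cdk1 activities, the Wee1/Cdc25 tyrosine-
modification switch, and the Greatwall–ENSA–PP2A:B55 phosphatase arm.
Assumptions:

* Cyclins are synthesised at constant rates (`ksa`, `ksb`) and turned over
  first-order (`kda`, `kdb`); there is no APC/C-mediated destruction, so
  both pools plateau — the modelled experiments stabilise cyclins by
  APC/C inhibition. Mitotic exit is outside the model's scope.
* Only CycB:Cdk1 carries inhibitory Tyr15 phosphorylation. Newly made
  CycB:Cdk1 enters the active pool; turnover removes total and
  phosphorylated pools proportionally. This is the simplest scheme
  consistent with a synthesis/turnover plateau.
* Wee1 and Cdc25 respond to the combined kinase signal `Ba + muA·A`
  through Hill functions (`nw = n25 = 4`): CycA:Cdk1 contributes to
  flipping the switch (weight `muA = 0.6`) but is not itself a substrate
  of it. PP2A:B55 opposes the flip on both ends: it reactivates Wee1
  (`kaw·B55a`) and inactivates Cdc25 (`ki25·B55a`). A small basal Cdc25
  inactivation (`ki250`) keeps the off-state numerically well defined.
* Greatwall is activated by both cyclins (`Ba + gammaA·A`) and
  dephosphorylated by free B55; phospho-ENSA binds B55 tightly
  (`kass = 100`, `kdiss = 1`) and is slowly dephosphorylated inside the
  complex (`kcat = 0.5`), releasing free phosphatase — so ENSA is both
  inhibitor and competing substrate.
* Substrate classes differ only in kinase input and phosphatase:
  early — either cyclin, Hill-gated, constant-rate phosphatase (`kde`);
  intermediate — either cyclin, linear, B55-dephosphorylated;
  late — strictly CycB:Cdk1, B55-dephosphorylated.

Units are dimensionless; one "model minute" is not calibrated to wall
time. The default horizon is 300 model minutes from the interphase state
(everything zero, Wee1 fully active), matching the duration over which
entry phenotypes are scored.

## The canonical-v1 parameter set

The set was hand-calibrated; its sole correctness contract is the
seven-condition phenotype atlas. The load-bearing choices, found by
fixed-point analysis and grid refinement:

* **Interphase stability without cyclin A.** With full B55, basal active
  CycB:Cdk1 is `Ba ≈ kdb/(kdb + kwee) ≈ 0.05`, far below the switch
  thresholds `Jw = J25 = 0.27` at Hill exponent 4, and Wee1 activation
  (`kaw·b55_tot ≈ 0.6`) dominates its inactivation (`kiw·H ≈ 0.03`). The
  interphase fixed point of the dCycA condition is stable on at least a
  2,000-minute horizon.
* **Entry upon B55 loss without cyclin A.** Basal Wee1 activation `kaw0`
  is nearly zero (0.002): once ENSA sequesters the residual B55, Wee1
  activation collapses and even the weak basal inactivation flips the
  switch within ~100 model minutes. This is what makes partial B55
  depletion epistatic to cyclin A loss.
* **No Greatwall leak in interphase.** The basal CycB:Cdk1 activity also
  drives Greatwall weakly; with slow pENSA turnover that leak would
  silently sequester all B55 and destroy the interphase state. The
  balance `kig = 5`, `kpens = 2`, `kcat = 0.5` keeps interphase
  phospho-ENSA below 0.1 while still allowing near-complete B55
  sequestration once either cyclin signal is high.
* **Substrate operating points.** `kpi/kdi = kpl/kdl = 0.1` put
  intermediate/late steady states at ≈ 0.17 under full B55 (off) and
  ≈ 0.85 under sequestered B55 (on); the early switch
  (`kpe/kde = 4`, `Je = 0.3`) saturates at ≈ 0.8 for either cyclin and
  stays at ≈ 0 in interphase. All atlas levels therefore sit outside
  [0.3, 0.7], making the phenotype calls robust to the threshold
  (default 0.5; labels are unchanged for 0.3–0.7).

Integration uses LSODA (stiff-capable) at `rtol = 1e-8`,
`atol = 1e-10`, sampled on a 601-point grid; refining to
(1e-10, 1e-12) moves final levels by < 1e-5 and changes no label.
Output states are checked against physical bounds at tolerance 1e-6 and
violations raise rather than being clamped.

Phenotype semantics: early-only phosphorylation = prophase-like arrest
(no nuclear envelope breakdown); early+intermediate = prometaphase
without late events (no sister-chromatid segregation/cytokinesis); all
three = mitosis. Patterns with a later class on while an earlier one is
off are treated as diagnostic errors, not silently labelled.

## The phospho-proteomics pipeline

Quantitation follows the standard post-search route for a 6-plex TMT
phospho-site table: contaminant/reverse removal; a strict
quantified-in-all-channels rule (a site enters ratio computation only
with positive intensities in all six channels — the strictest
reproducible reading of a "quantified subset"); optional isotope-impurity
correction by solving `observed = M·true` per row (identity by default,
since vendor correction is usually already applied); loading
normalisation dividing each channel by its median protein intensity
(post-normalisation protein medians are exactly equal, and rescaling any
input channel is exactly invisible downstream); per-replicate
`log2(treated/control)` site ratios, minus the parent protein's ratio
when the protein was quantified (sites on unquantified proteins keep raw
ratios and are flagged `protein_normalized = False`).

Significance is an empirical-null outlier rule: a normal distribution is
fitted to the per-site means of the three replicate log2 ratios (sample
mean, n−1 sd), and sites outside x̄ ± 1.96 s are flagged (strict
inequalities; boundary values are not significant). No FDR correction is
applied — the rule is deliberately the 5% two-sided normal cutoff. Note
the self-referential bias: the cutoff is fitted on the same data it
flags, so on a pure-null dataset the flagged fraction is slightly below
the nominal 0.05 (the fitted sd includes the flagged tail), and truly
changed sites inflate the fitted sd, making the rule conservative.

Motif annotation is at-site proline-directed: the central phospho-
acceptor must be S or T and the residue immediately C-terminal must be P
(the minimal Cdk consensus), not merely an [S/T]P dipeptide anywhere in
the window. Class-I sites have localisation probability > 0.75; the
class-I filter applies to motif-level summaries only, not to
significance testing. The down-regulated summary counts significant down
sites at two-fold or more mean change, and the distinct proteins among
them.

## The synthetic benchmark

The generator emulates one 6-plex mix (three control, three treated
channels, paired biological replicates): log-normal protein abundances
(log2 mean 20, sd 2), sites assigned to proteins with Poisson-weighted
multiplicity, site stoichiometry log-normal around the protein, fixed
per-channel loading factors, per-channel multiplicative noise
`2**N(0, sigma_replicate²)` (noise is parameterised on the log2 scale,
matching the pipeline's units; `sigma_replicate = 0.3` log2 units per
channel), optional tridiagonal adjacent-channel isotope spill, and a
truly changed minority whose effect `N(effect_log2, sigma_effect²)`
applies to site intensities in the treated channels only (protein
abundances are unchanged — phosphorylation-level, not expression-level,
effects). Sequence windows, localisation probabilities (Beta),
contaminant/reverse flags and per-cell missingness are drawn at the
configured rates; the truth table records every site's effect and motif
status. A fixed seed gives bit-identical tables.

Defaults encode the study conditions: 11,234 sites with 11% per-cell
missingness (so roughly half survive the completeness rule, ≈ 5,670),
3.5% truly down-regulated at a mean −2 log2 (4-fold) with spread 0.25,
41% proline-directed sites, 2,800 proteins, Beta(4, 1) localisation
probabilities.

What the generator does **not** emulate: ratio compression from
co-isolation interference, peptide-level aggregation of site evidence,
intensity-dependent variance and missingness (missingness here is
completely at random), correlated sites within a protein beyond the
shared protein ratio, and clustering of true effects on few proteins.
Passing tests therefore show the procedure is implemented correctly and
behaves as the normal theory predicts under these idealised conditions —
not that real acquisitions meet those conditions.

Expected pipeline power on the spiked benchmark is available in closed
form: per-replicate protein-normalised ratios carry noise from four
channels (sd `2·sigma_replicate`), averaged over three replicates; the
cutoff is 1.96 sd of the null/changed mixture; sensitivity is the normal
tail mass of the changed component beyond it (≈ 0.98 at the default
settings, comfortably above the 0.90 contract).

## Numerical and design notes

* Hill evaluation uses the `1/(1 + (J/x)**n)` form to avoid overflow at
  large `x`; domain violations (negative input, non-positive `J`,
  exponent < 1) raise immediately.
* Solver-tolerance-level negative excursions of `Ba` are clamped to zero
  before entering Hill terms; everything else is bound-checked, never
  clamped.
* The ENSA-phosphorylation flux is scaled by the Greatwall total
  (`kpens·gwl_tot·G·…`), so `gwl_tot` is a meaningful conserved total;
  the default 1.0 makes it equivalent to absorbing the total into
  `kpens`.
* Loading normalisation deliberately maps per-channel protein medians to
  exactly 1 rather than preserving the overall intensity scale: this is
  what makes channel-rescaling exactly invisible end to end. Absolute
  post-normalisation intensities are therefore not comparable across
  datasets; all downstream statistics use ratios only.
* Table output renders floats at 6 significant digits; runs write a
  manifest (package version, configuration hash, seed) sufficient to
  reproduce them.
* Problem sizes used by the shipped checks: 20,000-site null benchmark
  for the type-I error, 10,000-site spiked benchmark for
  sensitivity/false-discovery, 1,000 random states for the
  flux-enumeration equivalence, 300-model-minute integrations for the
  atlas. These sizes give binomial standard errors well inside the
  asserted tolerances while keeping a full run under a minute.
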