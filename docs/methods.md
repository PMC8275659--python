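# Methods

## Hydropathy-mismatch scoring

**Model.** Each target position *j* is scored independently as
`z(target_j) − Σ_i z_i · R_cons[i][j]/100`, where `z` is the Kyte–Doolittle
hydropathy scale standardised over the 20 standard residues and `R_cons` is
the per-column appearance rate (%) of each residue across the aligned
family. The second term is the conservation-weighted mean z-hydropathy of
the family at that column; the score is therefore bounded by
`z_max − z_min ≈ 3.09` in absolute value and is exactly zero where the
family unanimously conserves the target's own residue.

**z-transform.** The standardisation uses the *population* standard
deviation (divide by 20, σ ≈ 2.9113, μ = −0.49): the 20 amino acids are the
complete alphabet, not a sample. A `sample` mode (ddof = 1) is exposed for
sensitivity checks; it rescales all scores by a common factor √(20/19) and
changes no ranking.

**Gap handling.** Rates are computed over *all* family sequences by default
(`gap_mode="all"`): gaps (and non-standard letters B/Z/X/U/O/J, which the
hydropathy scale does not cover and which are folded into the gap bucket
with a logged warning) appear only in a per-position `gap_fraction`, so the
20 rates plus 100·gap_fraction sum to 100 and the consensus term becomes a
sub-weighted mean at gappy columns — the literal reading of the score's sum
over exactly 20 residues. `gap_mode="ungapped"` renormalises over the
sequences that carry a residue at the column. The target's own row is
included in the counts by default (`exclude_target` reverses this); with
typical family sizes the difference is below one percentage point per rate.

**Candidates and proposals.** Candidate sites are the positions with the
largest |score|, by default 10 of each sign, positive scores proposing a
switch to more hydrophilic residues and negative to more hydrophobic ones.
The proposed substitution is the argmax of the conservation rate over
non-wild-type residues, ties broken alphabetically by one-letter code; if no
other residue has family support the site is reported with reason
`no family support` rather than silently proposing the wild type. Positions
with a non-standard target residue are reported as unscored (NaN), never as
zero. Scores are printed to 3 decimals in reports; machine-readable output
keeps full precision.

**Secondary structure.** PSIPRED `.ss2` files (index, residue, H/E/C state,
three confidences) can annotate the table; the candidate summary reports the
percentage of sites per element class. Only the output format is parsed —
prediction itself is out of scope.

## Native-MS deconvolution and heme occupancy

**Charge assignment.** For a centroided peak list assumed to be one species,
every assignment of consecutive charges within `[z_min, z_max]` — highest
charge on the lowest-m/z peak — yields per-peak neutral-mass estimates
`z_k (mz_k − m_adduct)`; the assignment minimising their standard deviation
wins and the species mass is their mean ± sd. The adduct is a proton
(1.007276 Da, positive-mode [M+zH]z+), configurable. Assignments whose best
sd exceeds a 200 Da sanity bound are rejected as inconsistent. On noise-free
synthetic envelopes this recovers the generating mass to machine precision
for any mass in 10–100 kDa and any window of ≥ 2 consecutive charges.

**Mixed spectra.** A native spectrum of a heme protein contains two
interleaved envelopes. Species are extracted by seed-and-extend: each
(peak, charge) hypothesis implies a mass, predicted m/z positions at the
other charges are matched to the nearest centroid within ±2 Th, the maximal
consecutive run through the seed is kept, and the longest (then
lowest-sd, then most intense) series is removed before searching again.

**Pairing and occupancy.** Among extracted species, the pair whose mass
difference is closest to the expected cofactor shift — default 616.5 Da,
the average mass of heme b (the elemental composition C34H32FeN4O4 gives
616.489 Da; the monoisotopic +1 m/z is 616.1773) — and within ±40 Da of it
is taken as apo (lighter) / holo (heavier). Occupancy is the holo share of
summed centroid intensities over the charge states where both species are
found; per-charge fractions are always reported alongside the aggregate.
Peak *height* of the single nearest centroid is the integral proxy — the
inputs are centroided, so height and area coincide up to the centroiding
convention. The estimate rests on the assumption that cofactor binding does
not alter ionisation efficiency; intensity rescaling and dropping a
ratio-balanced charge state leave it unchanged.

**Out of scope.** Baseline subtraction, smoothing and centroiding (vendor
preprocessing), isotope-resolved deconvolution, and salt-adduct modelling.
The overlay report flags an inconsistency between the holo-minus-denatured
mass difference and the apo/holo shift (salt adducts commonly cause this in
native measurements) instead of attempting to resolve it.

## Variant analytics

Specific activity is `product / time / enzyme mass` (U mg⁻¹, U = µmol
min⁻¹) from an initial-rate assay; relative activity is the plain percentage
of a reference, reported to integer precision in summaries. The
heme/activity reference is a through-origin line anchored at the wild type
(slope = wt activity / wt heme %): if improved cofactor loading were the
only cause of an activity gain, variants would sit on this line. Variants
are classified above/on/below by residual sign with a ±10% relative band —
the same band that defines "improved" for the hit rate (threshold 110% of
wild type by default; the exact counting rule is a package choice, exposed
as a parameter). Expected mutant mass shifts are sums of residue-mass
differences (new − wild-type) from the pyteomics residue tables; *average*
masses are the default because sequence-derived theoretical masses of intact
proteins are average masses, and only deltas are computed — absolute
construct masses would require the full tagged sequence. Uncertainties are
propagated only when input SDs are supplied. Enzyme kinetics are not
modelled.

## Synthetic data

`generate_family` samples homolog rows column-wise i.i.d.: per position a
gap Bernoulli draw, then a categorical residue draw — either a consensus
residue at probability *p* with the remainder uniform over the other 19, or
an explicit 20-vector. The target is included verbatim as its own row.
Columns are independent: no phylogenetic correlation, no substitution-matrix
structure, no indel process. That suffices for testing a score that itself
treats columns independently, but it means passing tests say nothing about
robustness to the column–column correlations and uneven sequence redundancy
of real alignments (no weighting or deduplication is applied — rates are
unweighted counts).

`generate_spectrum` emits centroid peaks for apo and holo species at
`(M + z·1.007276)/z` over a charge window (default 10–15, emulating the
low-charge native envelopes of a ~41 kDa folded protein where charges
+11…+13 dominate), Gaussian intensity envelope across charges, species
weights {1−f, f}, multiplicative Gaussian intensity noise (CV configurable,
clipped at zero) and optional uniform m/z jitter (off by default; used for
deconvolution robustness tests). Denatured mode emits the apo species only
over a 50% wider window. The default protein/cofactor masses (41,216.78 /
616.5 Da) are realistic values for a tagged ~41 kDa heme enzyme. Real native
spectra additionally contain salt adducts, charge-dependent ionisation
bias and envelope overlap — none of which the generator emulates, so
occupancy-recovery results here bound only the intensity-noise error term.

## Numerical choices and problem sizes

Seeded `numpy.random.default_rng` throughout; byte-identical outputs under a
fixed seed. Ranking ties are resolved first-come (stable order); proposal
ties alphabetically. Degenerate inputs raise typed errors (empty alignments,
all-gap targets, constant hydropathy scales, insufficient peaks, empty
envelopes) rather than returning sentinels. The test suite exercises the
scoring oracle on 100 seeded 10×30 families, deconvolution on a 5-mass ×
3-window grid plus 100 jittered replicates, and occupancy recovery at nine
holo fractions × 500 replicates (±0.03 tolerance per replicate) — sizes
chosen to make the law-of-large-numbers checks sharp while keeping the
default run fast.
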