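# Methods

This note documents the models, defaults and numerical choices behind
`oxypair`, and what the synthetic-data tests do and do not demonstrate.

## Mass conventions

All arithmetic uses full-precision CODATA/IUPAC monoisotopic masses (the
NIST table shipped with pyteomics). Two conventions coexist for the
heavy-oxygen shift and both are exposed as constants:

* `O18_O16_DELTA` = M(¹⁸O) − M(¹⁶O) = 2.0042464 Da — used everywhere a
  mass is computed, a channel is placed or a tolerance is checked;
* `O18_O16_DELTA_PRINTED` = 2.0043 Da — the difference of the
  4-decimal-rounded isotope masses (17.9992 − 15.9949), the figure
  conventionally quoted for the per-oxygen shift. Rounding each mass
  before subtracting does not commute with subtraction, which is why the
  two differ in the fourth decimal. The 60 µDa gap is far below any
  screening tolerance (5 ppm at m/z 300 is 1.5 mDa) and never affects a
  decision.

Protonated ions add the proton mass (1.00728 Da), not a hydrogen atom:
`ion_mz([M+H]+) = M + m_p`, matching Orbitrap-reported m/z to < 1 ppm.
MS/MS product ions are even-electron cations whose formula already
contains the transferred proton; their m/z is the composition mass minus
the electron mass.

## Candidate enumeration

Phase-I biotransformations are signed element-count deltas
(`ReactionRule`): hydroxylation (+O, Z-increment 1), oxo/carbonyl
formation (+O −2H, Z-increment 1), N-debutylation (−C₄H₈, Z-increment 0).
Candidates are multisets of rule applications, so enumeration is
order-independent by construction; class labels (H, DH, O, HO, DA, DAH,
DAO, DADH) are derived deterministically from the multiset.

The default composition limits encode the canonical phase-I pathway map
of the amide-anesthetic family the defaults target: at most 3 total
steps, hydroxylation ≤ 2, oxo-formation ≤ 1, dealkylation ≤ 1, and a
*combine limit* of 2 on oxo-formation (an oxo-carrying metabolite has at
most one co-modification — carbonyl metabolites are observed only as
primary or secondary products in this map). These limits yield exactly
the eight classes above, including the three-step
dealkylated-dihydroxy (DADH) species, while excluding combinations
(dioxo, dealkylated-hydroxy-oxo) absent from the established pathway
map. The limits are per-rule data, not code: a different drug's map is
expressed by a different rule list.

Z — the number of O₂-derived oxygens — assumes every inserted oxygen
(hydroxyl and oxo alike) comes from molecular O₂ via the P450 cycle.
Hydrolysis-type rules, which insert water oxygen, are supported by the
schema with `z_increment=0` but are not in the default set. Z = 0
candidates are intrinsically invisible to the label and are flagged
`label-unconfirmable` downstream, never `confirmed`.

## Isotopologue model

A metabolite with Z inserted oxygens at per-site incorporation
probability q is modeled as the convolution of

1. the natural-abundance fine structure of all atoms except the Z
   inserted sites (¹³C, ²H, ¹⁵N, ¹⁷O/¹⁸O on remaining oxygens, S
   isotopes), computed by binary-exponentiation convolution with pruning
   at 10⁻⁸ relative abundance and renormalization; and
2. Z independent inserted-site distributions, each the mixture
   q·{pure ¹⁸O} + (1−q)·{natural oxygen}: an unlabeled insertion still
   draws from an isotopically natural O₂ pool.

At q = 0 the pattern therefore collapses to the natural-abundance
pattern exactly. q is bounded by the reagent enrichment (default 0.92,
the enrichment of commercially supplied ¹⁸O₂ gas); estimates above it
are flagged as noise artifacts rather than truncated silently.

### Channel windows

Label channels are read in ±5 ppm windows around the monoisotopic m/z
shifted by k·2.00425 (k = 0..Z). At a resolving power of ~35,000 (m/z
200) near m/z 300 this window admits the natural-¹⁸O satellite
(+2.00424, indistinguishable from the label) and excludes ¹³C₂
(+2.00671, 2.5 mDa off-center vs. a 1.5 mDa half-window). Widening the
window to ±0.01 Da — a low-resolution instrument — pulls the ¹³C₂ term
in; `natural_m2_fraction` takes an explicit `window_da` for that case.

### Labeling-degree estimation

Species with i labeled insertions carries the natural fine structure of
the formula minus i oxygens, and its natural +2j satellites leak into
channel i+j. Channel areas are deconvolved level by level,

    A'_k = C_k − Σ_j r_{k−j}(j) · A'_{k−j},    w_k = A'_k / n_k(0),

where r_i(j) is species i's +2j-window fraction relative to its own
monoisotopic line and n_i(0) its absolute monoisotopic abundance. The
weights w_k are then proportional to the binomial label weights and

    q̂ = Σ_k k·w_k / (Z · Σ_k w_k)

is the maximum-likelihood binomial estimate; for Z = 1 it reduces to the
familiar q̂ = A₁₈′/(A₁₆ + A₁₈′) with A₁₈′ the natural-M+2-corrected
labeled area. The inversion is exact against the forward model (tested
to 10⁻⁶ over q ∈ {0..0.9}, Z ∈ {1,2}); negative corrected channels are
clamped to zero with a warning flag. q̂ is clamped to [0, 1].

Confidence intervals: the experiment yields a single area vector with no
replicate-based noise estimate, so the interval is a seeded parametric
bootstrap — multinomial pseudo-counts (default 1000) drawn at the fitted
binomial, re-estimated, 2.5/97.5 percentiles (default 500 draws). The
pseudo-count is a declared effective-counting-statistics choice, not a
measured quantity; intervals should be read as orders of magnitude.

## Chromatographic processing

XICs sum centroid intensities within ±tol ppm per MS1 scan (default
5 ppm MS1, 10 ppm MS2 — measured product ions routinely deviate up to
~7–9 ppm from theory on this instrument class). Peak detection uses a
robust noise scale (1.4826 × MAD of the trace) and requires height and
prominence ≥ min_sn × noise (default S/N 3), at least 2-scan width, and
a *persistence gate*: ≥ 5 consecutive scans above baseline +
(2/3)·min_sn·noise around the apex. White noise essentially never
sustains such a run (0 false peaks over 200 seeded pure-noise traces of
3000 scans), while any peak sampled at a sane acquisition rate does.
Apexes are refined by parabolic interpolation; areas are trapezoidal
integrals of the contiguous above-baseline region, with flank-walking
that tolerates point noise by tracking the running minimum and stopping
only on a clear rise (the next peak); peaks closer than one FWHM are
merged, keeping the taller. Retention times are minutes throughout.

mzML reading and writing are implemented over lxml (centroid spectra,
64/32-bit base64 arrays, optional zlib, minute/second time units, MS2
precursor linkage). Profile-mode input is rejected: the pairing logic is
defined on centroids.

## The paired-run screen

For each candidate the screen extracts features at the theoretical m/z
in the air run and at the theoretical and Z-shifted m/z in the ¹⁸O₂ run.
A hit is **confirmed** when

1. the air feature and the fully shifted (+Z·2.00425) ¹⁸O₂ feature
   co-elute within rt_tol (default 0.1 min; no cross-run alignment —
   same column and gradient are assumed);
2. the shifted channel is *absent* in the air run at that RT —
   operationally, any air-run feature there has area < 5% of the
   unlabeled air feature (the natural M+2 inside a 5 ppm window is
   ~0.4%, so genuine isotope signal never blocks confirmation);
3. control filtering passes: no control run shows a feature at the same
   m/z and RT with area ≥ feature/control_ratio_min (default 5). With no
   controls the filter passes with a logged caveat;
4. the estimated labeling degree clears q_min (default 0.1, safely below
   the 20–45% range observed for microsomal ¹⁸O incorporation but above
   natural-abundance artifacts).

Partial incorporation means both channels coexist in the ¹⁸O₂ run; the
unlabeled channel there is used for q estimation only, never required
for confirmation. Intermediate channels of Z = 2 candidates likewise
feed only the estimator. Scores are the product of three bounded terms
(mass accuracy of the labeled feature, co-elution, labeling
plausibility), each exp(−(x/tol)²)-shaped, deterministic given inputs.
Isomers — same class, different RT — are separate hits, reported as
semicolon-joined retention times.

## MS/MS label propagation

Fragment hypotheses come from a per-drug core library (CSV data; the
packaged default transcribes the characteristic product-ion cores of the
bupivacaine class system, e.g. C₉H₁₈N → C₉H₁₈NO for hydroxy classes).
Identification is group-level only: positional isomers within a class
give near-identical spectra and are not distinguished. Verification
requires every matched oxygen-carrying fragment to reappear at
+n·2.00425 in the labeled spectrum and every oxygen-free fragment to
stay at its own m/z; the verdict is `consistent` when at least one
shifted pair exists and no oxygen-free fragment shifts.

## Synthetic data generator

The generator emulates the paired experiment: Gaussian elution profiles
(default FWHM 0.08 min on a 0–15 min gradient sampled every 0.005 min,
~0.3 s Orbitrap-like scan period), the parent drug in both runs plus a
substrate-in-buffer control, planted metabolites carrying their natural
pattern in the air run and the Binomial(Z, q) label structure in the
¹⁸O₂ run at the same RT. Defaults follow the stated experimental
conditions: reagent enrichment 0.92, planted q = 0.3 (inside the
observed 20–45% range), retention times from the published bupivacaine
inventory.

Noise has three seeded components: a per-species per-run amplitude
factor (CV = `noise_sigma`, default 5% — injection/ionisation
variability; this is deliberately the dominant term so that replicate
*area* CV matches `noise_sigma`, which a purely per-point model would
not), per-point jitter at `noise_sigma`/3, ~1 ppm m/z jitter, and a
sparse uniform chemical-noise floor (~20 exponential-intensity centroids
per scan). Fixed seed ⇒ byte-identical mzML.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: peak tailing and RT drift between runs,
ion suppression and correlated matrix interference, in-source
fragmentation, detector saturation, centroiding artifacts at low S/N,
and any RT-dependence of the labeling degree (dissolved ¹⁸O₂ depletes
over the incubation; no correction is attempted). The pipeline-closure
tests demonstrate internal consistency of the method under the stated
noise model, not instrument-grade robustness.

## Problem sizes used in tests

Most pipeline tests run a 6-minute gradient (1200 scans) with six
planted metabolites spanning Z ∈ {0, 1, 2}; closure is checked over 10
seeds, the no-false-confirmation property over 20. These sizes were
chosen to exercise every code path (co-elution, multi-channel
estimation, Z = 0 flagging, control veto) at comfortably interactive
runtimes; the statistics of the checks (e.g. q̂ recovered to ±0.02) are
insensitive to the gradient length because they are per-feature
properties.

## Known limitations

* The label cannot speak to Z = 0 metabolites (dealkylations,
  hydrolyses); they are reported but never confirmed.
* Regioselectivity is out of reach by construction: H-1/H-2/H-3-type
  positional families are one class here, separated only by RT.
* Exchange-labile oxygens (e.g. allylic hydroxyls) can lose the label to
  water over time ("tag dropout"); the screen does not model label decay.
* The q estimator assumes channel areas from a single co-eluting
  species; unresolved co-elution of an isomer with different q biases q̂
  toward the area-weighted mean.
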