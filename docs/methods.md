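# Methods

## Isotope arithmetic and the mixing coordinate

All conversions run through the VPDB reference ratio R = 0.0112372:
δ ↔ R ↔ F with F = R/(1+R). Mixing and un-mixing are done exclusively in
atom-fraction space. At natural abundance the distinction from δ-space
mixing is negligible, but the experiment's end-members sit at 50–99 atom%
¹³C, where δ is grossly non-linear in the conserved quantity (¹³C atoms);
atom fractions make the two-pool balance exactly linear, so
`percent_replacement` is linear in F_sample and inverts a planted mixing
fraction to machine precision. Instrument deltas are calibrated first
(linear `certified = a·measured + b` through reference pairs, ordinary
least squares when more than two are given) and mixed second; that order
is fixed.

The natural ¹³C atom fraction used by the isotopomer binomial model
defaults to 0.0107 (the IUPAC representative isotopic composition of
carbon). This differs from the VPDB-derived atom fraction at δ = 0
(0.011112) because biological material is depleted relative to VPDB; both
are configurable through `IsotopeConstants`.

Substrate end-members default to the experimental additions: bicarbonate
2.25 mM at 50 atom%, acetate 2.2 mM and glucose 5 mM at 99 atom%. The
ambient dissolved-inorganic-carbon pool dilutes the bicarbonate end-member
in the field, but its concentration is generally unquantified; dilution is
therefore off by default and exposed as
`SubstrateSpec.background_conc`/`background_delta`, with the
concentration-weighted mean atom fraction used when enabled. Users should
treat bicarbonate replacement values as lower bounds when ambient DIC is
substantial. Similarly, the control may be a time-matched unlabeled
incubation or a t₀ sample; the API accepts either a scalar δ or a control
profile.

## Depth profiles

Profiles are normalized affinely (surface → 0, bottom → 1) because mat
surfaces are textured and replicate profile lengths differ. Integration is
trapezoidal on the observed grid; spot spacing (~200–300 µm at 50 µm spot
size) is coarse and irregular, so no spline smoothing is applied — the
piecewise-linear assumption is the conservative one, and the quadrature is
verified against a 10⁵-point Riemann oracle. Replicate (triplicate)
profiles are summarized per profile first and averaged across profiles,
never by pooling spots, since profiles have unequal spot counts.

Slightly negative spot replacements arise from measurement noise around
unlabeled material. They are **retained** in all integrals (clipping would
bias partitions toward the surface) and merely flagged below a reporting
tolerance (default −0.1 %). A partition whose total integral is
non-positive within 10⁻⁹ of zero is returned flagged with NaN fractions
(the dark-control case); a genuinely negative total raises.

The photic boundary is the shallowest depth where scalar irradiance
reaches 10 µmol photons PAR m⁻² s⁻¹, linearly interpolated between
tabulated points. No default depth is hard-coded; callers supply either an
irradiance table or a fixed boundary. Both the depth-integrated mean and
the unweighted spot mean are computed; the integrated form is the default
"average % replacement" because it weights each spot by the depth interval
it represents.

## Acid-wash balance

The three-pool inversion is a balance on carbon atoms:
`carbon_fraction_removed` must be the fraction of sample **carbon** (not
mass) removed by the acid treatment — this is the caller's responsibility
and the single most common way to misuse the function. The inversion is
refused below f = 0.01, where it amplifies measurement error more than
100-fold. Classification uses the sign of the post−pre δ shift with a
tolerance of 2 combined standard deviations, or 0.5 ‰ absolute when no
uncertainties are given. When a supernatant δ is supplied it is interpreted
as the organic (EPS) component only, since carbonate carbon leaves the
acid wash as CO₂.

## Metabolite mass isotopomers

Observed MIDs are deconvolved through the lower-triangular binomial
redistribution matrix B[i,j] = C(n−j, i−j)·f^(i−j)·(1−f)^(n−i) (each of
the n−j unlabeled carbons independently ¹³C with probability f); the
matrix has positive diagonal and is always invertible by forward
substitution. Only carbon natural abundance is corrected: Si/O/N/H
isotopes of TMS derivatives are ignored, and `n_carbons` counts
labeled-backbone carbons only. Noise can leave small negative corrected
fractions; they are floored at zero and the vector renormalized, with the
adjustment logged.

Excess enrichment is the mean molar ¹³C excess,
100·(Σi·mᵢ(sample) − Σi·mᵢ(control))/n — linear in the labeled-population
mixing fraction. The three-level call uses explicit thresholds
(abs_lo = 0.1 %, abs_hi = 0.5 %, z_lo = 1, z_hi = 3): "+" needs the excess
to clear both the absolute ceiling and 3 control standard deviations; "−"
requires clearing neither floor. These defaults are **declared, not
inferred** — the original manual criterion behind such call tables is
typically unstated — and sit in `CallThresholds` config. Controls are the
same-timepoint unlabeled (¹²C-bicarbonate) incubation, falling back to
pooled controls with a logged warning.

The labeled-population fit solves sample ≈ x·Binomial(n, p_label) +
(1−x)·control by closed-form projection with x clipped to [0,1]; it warns
when p_label is within 5 atom% of natural abundance, where the design
matrix degenerates.

## SIP proteomics

Filtering is a pure conjunction of the six SIPPER cutoffs with boundary
equality passing (the cutoffs are stated as ≤/≥). A protein is labeled
when any of its peptides is; relative abundance uses per-column
(timepoint × incubation, optionally × taxon bin) denominators. Because the
literature mixes spectral-count-weighted peptide distributions with
unweighted protein counts in the same breath, both are implemented:
`weight_by_spectra=True` adds the spectra-weighted labeled fraction of the
peptide distribution beside the protein count. A peptide shared across
bins contributes to each bin it maps to. Pathway matrices divide labeled
proteins per pathway by total proteins per column and store √(raw); a
protein in k pathways contributes to all k rows, so columns are not
simplexes.

## The synthetic generator

The generator exists because the study-type raw tables (LA-IRMS spots,
GC-MS intensities, SIPPER scores, acid-wash pairs) are not publicly
deposited in desk-usable form; it emulates the statistical structure the
estimators assume, with truth sidecars for every table.

Forward model: dU/dt = k_p·s(I) for bicarbonate, k_h for organics, minus
k_loss·U when surface irradiance is zero; I(z,t) = I₀(t)e^(−z/λ) with a
half-sine daylight arc (06:00–20:00) and the incubation clock starting at
11:30. Eight sampling timepoints (0.2, 2, 4.5, 8.5, 13, 18.5, 21.5,
24.5 h) put index 4 at dusk, 6 at dawn and 8 at the second solar noon.
Integration is explicit Euler at dt ≤ 0.1 h (default 0.05 h; closed-form
checks use 0.01 h), chosen over an ODE library so every limit is auditable
by hand: with zero rates U ≡ 0; with a linear light response
(`half_saturation=None`) the daylight profile is exactly
U(z) ∝ e^(−z/λ); overnight decay is exactly e^(−k_loss·Δt) for
bicarbonate.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| λ (attenuation length) | 0.12 mat thicknesses | photoautotrophy confined to ~1 mm of a ~1 cm mat |
| I₀ peak | 2000 µmol photons m⁻² s⁻¹ | midsummer surface PAR |
| K_I (half-saturation) | 50 µmol photons m⁻² s⁻¹ | plausible saturating response; any positive value works |
| k_p | 0.60 %/h | yields ≈2.4 % mean replacement over 24 h |
| k_h | 0.17 %/h | comparable organic uptake, depth-uniform |
| k_loss | 0.058 h⁻¹ | ≈44 % of dusk-held fresh C lost over the 10-h night |
| noise | 2 ‰ (1σ) | typical LA-IRMS spot repeatability |
| control δ | −20 ‰ | typical unlabeled organic matter |
| mat thickness | 10 mm, ±10 % per replicate | textured surface; unequal profile lengths |

Known divergences from field data, hence what passing tests do *not*
show: the model has **no vertical transport**, so the below-photic-depth
fraction of bicarbonate-derived C stays small (a few percent) instead of
the ~40 % that downward redistribution produces in real mats; organic
substrates keep being taken up at night, so their dusk→dawn budget shows
net *gain* under the defaults rather than the modest net loss seen in the
field; and the peptide generator plants labeled proteins by exact count
(round(fraction·n)), so recovery tests exercise the estimator rather than
binomial sampling luck. Metabolite truth patterns plant labeled-population
fractions of 0.05 / 0.003 / 0 for +, +/− and − cells — with a 99 atom%
tracer these give ≈4.9 %, ≈0.29 % and 0 % excess, landing each call class
safely inside its threshold band at the 1 % intensity noise used.

All emitters are deterministic given their seed; the pipeline derives
per-stage child seeds (< 2³¹) from the run seed via `SeedSequence`, and
CSV writers pin column order, float format and line endings, so a full
`run-all` is byte-reproducible.

## Problem sizes

The reference scenario uses 64 depth points × 0.05 h steps over 24.5 h,
triplicate profiles of 32–43 spots at 8 timepoints for 4 treatments
(3 labeled substrates + dark bicarbonate control), 6 metabolites ×
3 timepoints × 4 incubations × 3 replicates of isotopomer intensities, and
1000 proteins per taxon bin (2000 per condition) with 1–3 peptides each at
4 timepoints × 3 incubations. A full pipeline run completes in a few
seconds on one CPU.

## Limitations

No lateral (2-D/3-D) mapping, no reaction–transport realism, no
carbonate-mineral speciation, no MS/MS search or SIPPER envelope scoring
(scores are consumed, not computed), and no KEGG ontology retrieval
(mappings are inputs). The three-level call thresholds and the generator's
rate constants are package choices, not inferred field values.
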