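# Methods

`glyquant` quantifies intact glycopeptides from centroided DDA LC-MS runs.
This note records the model and procedure, the parameters that matter, what
the synthetic benchmark emulates (and does not), and the numerical choices
made where the design was genuinely open.

## Evidence: per-isotopologue chromatograms

For each glycopeptide spectrum match (GPSM) the elemental composition is the
sum of residue formulas (J is the glycosylated Asn), one water, dehydrated
monosaccharide formulas (Hex 162.0528, HexNAc 203.0794, NeuAc 291.0954,
NeuGc 307.0903, Fuc 146.0579 Da) and named modification formulas. The
theoretical isotopologue envelope is computed by stepwise convolution in the
emass style: per-element single-atom distributions raised to the element
count by repeated squaring, convolved across elements, binned by nominal
neutron number with abundance-weighted aggregate masses, pruned below 1e-10
relative abundance. Six isotopologues are kept by default (`max_isotopes`);
that covers >99.9% of the envelope for glycopeptides up to ~10 kDa.

In every MS1 scan, each isotopologue's intensity is the most intense peak
inside a ±`tol_ppm` window (default 20 ppm; ties broken toward the closer
mass; absence is 0). The chromatogram extends left and right from the
trigger scan — for an identified GPSM, the MS1 scan at or before its MS2
retention time — while the summed-isotope profile stays at or above 10% of
the running apex of the extending profile; a scan with no in-window peak
terminates extension on that side. The 10% rule is applied to the summed
profile (a config flag switches it to the mono trace). The reported
intensity is the trapezoidal area of the monoisotopic trace in
intensity·minutes; the integration grid includes the first sub-threshold
scan on each side so the descent to the boundary is captured. On a clean
Gaussian peak this recovers the analytic area above the 10% cut to within
2%; relative to the *total* peak area it is biased low by the ~3% that a
Gaussian holds outside the 10% boundary, a constant factor that cancels in
any ratio.

## The evidence-matching model

Each evidence is rasterized to a fixed K×L image (default 6 isotopologues ×
64 uniform RT bins, linear resampling, max-normalized — so the model sees
shape, not scale). The encoder is a residual network mapping the flattened
image through a dense stem to a 512-dimensional embedding refined by two
residual blocks (x → relu(x + W₂ relu(W₁x))). It is written directly in
numpy with explicit backpropagation; at these input sizes a convolutional
backbone adds depth the problem does not need on a single CPU, and the
512-dimensional embedding contract is what downstream layers rely on. Two
embeddings are concatenated (1024), reduced through a 128-unit hidden layer
to 16, concatenated with 10 standardized classical pair features, and a
final softmax layer yields the match probability in [0, 1].

The 10 classical features, in fixed order: apex-envelope cosine, |ΔRT| of
apices, Pearson correlation of resampled mono traces, log10 mono-area
ratio, FWHM ratio (min/max), ppm difference of theoretical mono m/z, number
of co-detected isotopes, apex-intensity ratio (min/max), RT boundary
overlap fraction, and log signal-to-baseline difference.

Training pairs are mined from label-free runs: positives are the same
glycopeptide identified in two runs with |ΔRT| < 2 min and relative
intensity difference < 30% (|Iₐ−I_b|/max < 0.3); negatives pair an
identified glycopeptide's evidence with a random different-precursor-mass
evidence at a ±4-minute RT offset in a run where it was not identified.
Training uses Adam (lr 1e-3), batch 64, softmax cross-entropy, fully seeded
and bit-reproducible. Default pair budget is 3000+3000; the benchmark suite
uses 500+500 pairs and 25 epochs — this compact encoder needs roughly 25
epochs to converge where a deeper backbone would need fewer — reaching
held-out pair accuracy >0.95 on the synthetic designs in ~25 s on one CPU.

## Match Between Runs and FQR control

For a glycopeptide identified in at least one run and missing in another,
candidate evidences with the same precursor mass are enumerated in a
half-open ±2-minute window around the reference RT — one per local maximum
of the mono trace, with one context scan beyond each window edge so
clipping cannot fabricate a maximum — and each is scored against the
reference (the identified run with the most intense evidence). The best
score wins. No cross-run RT alignment is applied.

False-quantitation-rate control is target-decoy: every reference precursor
gets a +10 Da decoy run through the identical enumerate-and-score path
(same reference evidence, candidates at the shifted mass, so a decoy match
is a true reference against necessarily false candidates). The pooled
target+decoy scores are modelled as a two-component Gaussian mixture
f(x) = π₀f₀(x) + π₁f₁(x), initialized by 2-means (smaller mean = false
component), fitted by EM (posterior E-step; standard M-step updates for π,
μ, σ; ε = 1e-6 on the max parameter change; 500-iteration cap; σ floored at
1e-4 on collapse). FQR(t) = π₀S₀(t) / (π₀S₀(t) + π₁S₁(t)) with Gaussian
survival functions via the complementary error function; a `double_pi` flag
reproduces the alternative composition in which each survival term carries
its mixture weight twice. The acceptance threshold is the smallest observed
score with FQR ≤ α (default 0.01).

Three robustness choices wrap the mixture fit, each measured to matter:

1. **Score floor.** Matches scoring ≤ 0.01 are "no plausible candidate"
   (the softmax is saturated at 0); they are rejected outright and excluded
   from the fit. The point mass at 0 otherwise collapses σ₀ and drags the
   threshold to ~0.
2. **Logit scale.** The mixture is fitted on logit(score): softmax scores
   saturate at both ends of [0, 1], where a two-Gaussian model fits poorly;
   on the open logit scale both populations are near-Gaussian and the
   threshold maps back monotonically.
3. **Empirical decoy bound.** The final threshold is the stricter of the
   mixture threshold and the classic count-based bound (smallest t with
   (#decoys>t + 1) / #targets>t ≤ α, the conservative +1 pseudocount).
   With fewer than 10 informative decoy scores neither estimator is
   determined at any α, and the rule becomes: accept targets scoring above
   every informative decoy. This keeps the control honest when the
   parametric fit is under-determined, and keeps acceptance monotone in α.

Accepted matches fill the quantitation matrix; rejected cells stay missing
(missing is distinct from a detected zero).

## Match In Run for sialylated glycoforms

Glycan structures are canonical strings: depth-first parenthesized trees
over single-letter codes (H, N, A, G, F) with children sorted by subtree
string, so each tree has one canonical form. The candidate database is
first screened to structures containing a LacNAc unit (a HexNAc on a Hex
that carries a Hex — the complex/hybrid antenna pattern; oligomannose
structures drop out), then partitioned into subnets keyed by the
*infrastructure*: the canonical string after removing all terminal
NeuAc/NeuGc units (a sialic acid with children is a structural error).

An identified glycopeptide whose glycan matches a subnet member (by
structure, else by composition) generates one candidate per other member:
same peptide, modifications and charge; precursor shifted by the
composition mass difference over the charge; expected RT shifted by ΔSA
times the per-sialic-acid retention bias. That bias is estimated per run as
the median of ΔRT/ΔSA over identified pairs sharing peptide, charge and
de-sialylated composition, or set by the user.

Inside the RT window, each MS1 scan contributes an experimental envelope Y
(closest-mass peak within ±20 ppm per theoretical isotopologue; missing =
0) and Sim_iso = cos(X, Y) against the theoretical envelope X. If the best
scan exceeds 0.9 the evidence spans the maximal contiguous run of scans
with Sim_iso ≥ 0.9 around it; its intensity is the mono-peak area over that
span and Score_MIR = Σ Sim_iso over the retained scans (so 0.9·n_scans ≤
Score_MIR ≤ n_scans). MIR results carry a `via_mir` origin flag and never
overwrite identification-backed values.

## SILAC, TMT and merging

SILAC channels resolve their mass shift from the peptide's K/R counts and
the label table (K+4/+6/+8, R+6/+10 variants embedded); one evidence is
built per channel at the shifted m/z, channel areas are recorded, and the
matching model's light/heavy similarity is attached but does not gate the
quantities by default. A channel whose mono trace carries no signal is
missing, not zero. The heavy envelope is approximated by the light envelope
translated to the shifted m/z; the label's own isotopic fine structure is
ignored. TMT reporter intensities are picked per channel in MS2 scans at 10
ppm (TMT6 reporter masses embedded); glycopeptide values sum over GPSMs.

Merging aggregates accepted spectrum intensities by summation into six
levels (spectra, modification, site, protein, glycan occupancy, site
occupancy). Cell values are correctly-rounded sums (math.fsum) so totals
are conserved exactly across levels and output is independent of record
order.

## Benchmark metrics

PMVL is the fraction of quantified entities with one or more missing
values (a `strict` flag counts rows with two or more, the alternative
reading of the definition); PMVT is missing cells over all cells. Pearson
correlation uses pairwise-complete rows. The robust SD of a log2-ratio
vector is (R_H − R_L)/2 with the 84.13th/15.87th percentiles (linear
interpolation between order statistics); for normal data it equals the
ordinary SD.

## What the synthetic data emulates — and what it does not

`synthio` generates centroided MS1 runs: Gaussian elution peaks (FWHM
default 0.15–0.2 min) carrying exact theoretical envelopes scaled so the
mono trace integrates to the item's true area; multiplicative lognormal
noise on peak points (σ 0.05); ~300 uniform-random interference centroids
per scan with exponential intensities (the background density of a complex
sample's MS1); identifications emitted near each true apex with probability
0.8 to create realistic missingness. Benchmark designs: replicate runs with
jittered RT/area (training and transfer tests); two-sample disjoint
inventories with replicates (entrapment — every cross-sample transfer is
false by construction); spiked sialylated glycoforms at anchor RT plus the
per-SA shift over a high-mannose background (in-run matching); SILAC
channel pairs and TMT reporter scans at known ratios.

Placement excludes co-eluting envelope overlap — including each analyte's
+10 Da decoy window, so the decoy channel samples the same background as a
genuinely absent precursor, which is what the FQR calibration assumes. Two
consequences deserve emphasis. First, the entrapment guarantee ("no
cross-sample transfer can be genuine") requires the placement exclusion to
exceed the matching window plus worst-case replicate RT jitter; the default
30-minute gradient gives the placement room at 300 analytes per side.
Second, real data is harsher in ways these runs are not: co-eluting
isomers, chimeric envelopes, RT drift beyond a linear trend, detector
saturation and profile-mode artifacts are absent. Passing the synthetic
suite therefore demonstrates the algorithms are implemented and calibrated
as specified, not that real-data performance numbers transfer.

## Numerical and degenerate-input choices

- m/z windows are relative (ppm); window edges are half-open on the right
  wherever a boundary matters, so behavior is deterministic.
- Cosine similarity of a zero vector is defined as 0.
- k-means initialization requires ≥2 distinct scores; identical scores are
  an error, not a silent degenerate fit.
- An EM component collapsing below σ = 1e-4 is floored with a warning.
- Evidence built where the trigger and both neighbors are silent is None
  (unquantified), not an empty object.
- All randomness flows from explicit integer seeds; reruns are
  byte-identical.

## Known limitations

- The matching model is trained per study; shipped code contains no
  pretrained weights, and desk-scale training (≤3000+3000 pairs, CPU)
  is the contract.
- MIR extrapolates only across sialic-acid counts; fucosylated or other
  glycoform series are out of scope, as is enumeration of substructures
  from maximum structures (a user-supplied structure list stands in).
- No cross-run RT alignment, charge-state transfer, reporter-ion impurity
  correction, or ratio normalization.
- The mzML reader/writer covers the centroided subset of the standard
  vocabulary (ms level, scan times, precursors, 32/64-bit zlib or plain
  arrays), not vendor idiosyncrasies.
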