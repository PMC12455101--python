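# Methods

This note documents the models, conventions, default parameters and known
limitations of prmkit, in the order the pipeline uses them.

## Mass arithmetic and isotope envelopes (`prmkit.chem`)

Residue compositions and isotope masses/abundances come from the NIST
table distributed with pyteomics; δ(¹⁵N−¹⁴N) = 0.9970349 Da; the proton
mass is 1.00727646688 Da. Carbamidomethyl-cysteine (C2H3NO) is treated as
a fixed modification. Because standards are alkylated after expression,
its nitrogen is **unlabeled** by default; `label_modification_nitrogen=True`
flips this for workflows where the modification is introduced before
labeling. Fragment support is limited to b/y ions at 1+ and 2+, the only
series the assays use.

Envelope prediction convolves per-element nominal-mass-offset
distributions, with the *n* labeled nitrogen sites following the two-state
distribution (¹⁴N, ¹⁵N) = (1−p, p) and all other atoms (including
modification nitrogen) at natural abundance. Offsets are relative to M0,
the fully labeled monoisotopic species (all labeled N heavy, every other
atom lightest).

**Convention for the M−1/M0 ratio.** At unit (nominal-mass) binning the
bin at offset 0 also contains cross terms such as (one ¹⁴N + one ¹³C),
which for a carbon-rich peptide inflate the binned M−1/M0 by several
percent relative to the binomial value n(1−p)/p. The package therefore
keeps both: `IsotopeEnvelope.offsets/abundances` is the binned, measurable
envelope (what an MS1 extraction at typical resolving power sums), while
`m0_species`/`m1_species` are the exact-species abundances on which
`m1_m0_ratio` is defined. The ratio is exactly n(1−p)/p under this
convention. Since the efficiency regression inverts *predicted* ratios of
the same convention, the choice cancels methodologically; what matters is
that prediction and inversion agree. Extraction software that sums the
full nominal bin will report slightly larger observed ratios, biasing p̂
down by ≲ 0.1% for tryptic peptides — a known, documented limitation.

## Labeling efficiency (`prmkit.labeling`)

Default incorporation grid {0.95, 0.96, 0.97, 0.98, 0.99, 0.995, 1.00}.
The ratio-versus-p relation is mildly convex, so the least-squares line
inverts with ≤ 1e−3 error in p for n ≤ 40; consequently an observed ratio
of exactly 0 inverts to p̂ = 1.0 only to within that same 1e−3. Estimates
whose raw inversion falls outside the grid span are clipped to the span
and flagged `in_range=False`; only in-range estimates enter the
protein-level aggregate. Aggregation is the median (robust to a single
distorted precursor), dispersion the median absolute deviation. Observed
ratios are assumed background-subtracted by the caller; MS1 peak
extraction is out of scope. Curves are fitted per precursor and inverted
per precursor before aggregation.

## Chromatographic features (`prmkit.features`)

Integration is trapezoidal above a linear baseline drawn between the
boundary intensities; the baseline area is the background; negative net
areas floor at zero with a flag. Peak width is FWHM of the
baseline-subtracted apex with linearly interpolated crossings
(configurable fraction); FWHM was chosen over width-at-base because it is
stable under baseline noise. S/B = net area / background area with the
background floored at 1e−9 to stay finite. The median chromatogram is the
pointwise median over a precursor's transitions resampled to the densest
shared grid; the time correlation is Pearson's r over the integration
window. dotp is the cosine of square-root-transformed intensity vectors
(Skyline-like; the exact Skyline transform is undocumented). Degenerate
cases (flat trace, apex on a boundary, zero variance) return NaN rather
than a fabricated value, and NaN fails every filter criterion.

## Assay design (`prmkit.assaydesign`)

Two shipped criteria profiles: **label-free** (min area 100, S/B ≥ 2.0,
relative area ≥ 0.05, correlation ≥ 0.80, width 4–20 s, replicate CV ≤
30%, ≥ 3 qualifying transitions) and **15N-assay** (area 100, S/N 2,
correlation ≥ 0.75, no width/relative-area bound). Scheduled windows
default to 2 min, centered on the expected RT.

Cycle-time model: per-target scan time = scan_range/scan_rate + overhead
(800 Da / 125 kDa/s + 5 ms by default); ion injection is modeled as fully
parallel with the previous scan-out, so it never extends the cycle.
Multiplexed MS3 adds 2 ms per product ion. Splitting is first-fit over
RT-sorted candidates with a per-target feasibility check (cycle time at
the apex ≤ FWHM / points-per-peak goal); balancing is a
longest-processing-time greedy on worst-case cycle time that falls back
to the input assignment if it cannot improve the maximum — so it never
increases the maximum load and always conserves the target count. All
tie-breaks are deterministic by (RT, m/z, sequence, charge, label). The
published tool this mirrors does not document its algorithms; first-fit +
LPT are the package's own choices and are checked against brute force on
small instances.

MS3 product selection keeps the highest-intensity products that are
multiply charged or singly charged above the precursor m/z, up to 5 by
default (an undocumented bound; exposed as a parameter). Isolation widths
follow the calibrated instrument rule 2 Th at the lowest selected m/z
growing linearly to 10 Th at 4× that m/z, clamped to [2, 10].

GPF planning tiles a precursor range (default 380–980 m/z in 100 m/z
segments) into one injection per segment with contiguous 1-Th MS2
windows.

## Adaptive RT (`prmkit.adaptivert`)

The reference container is a documented JSON format (an open stand-in for
the vendor's binary reference file): RT grid, shared 1-Th bin scheme,
combined ≥ 50 Th windows, and 8-bit log-quantized spectra. Quantization
preserves intensity rank order.

Shift estimation maximizes the **mean-centered cosine** correlation
between run and reference spectra over lags in a ±30 s band at the scan
period's resolution, with parabolic sub-grid refinement. Centering
matters: plain cosine of non-negative spectra that share a
chemical-background pattern scores ~0.65 even for structureless noise,
which would defeat the validity flag; centered correlation scores ~0 for
noise and ~0.98 for matched spectra. Estimates with peak score < 0.5 are
flagged invalid and never applied — degradation at gradient edges (no
reproducibly eluting peptides early, variable wash-out late) surfaces as
invalid flags rather than silently wrong shifts. Lag profiles are
smoothed with a rolling median over 5 estimates before window
translation; translation never changes window widths or target counts.

Normalized RT errors (per-replicate deviation from a precursor's mean
RT/gradient-span) reproduce the qualitative edge-noise pattern: errors
inflate at normalized RT below ~0.1.

## Calibration and quantification (`prmkit.quant`)

TIC normalization scales each run's areas by mean(TIC)/run-TIC. The
bilinear model y = floor + slope·max(x − c_t, 0) is fitted by 1/x-weighted
least squares at each of 200 log-spaced candidate turning points between
the lowest and highest level; the SSE-minimizing candidate is kept.
LOD = c_t (the turning point). Fits need ≥ 2 levels above the candidate
and a linear rise of at least 1e−6 of the data scale — flat series are
flagged invalid. LOQ is the lowest level ≥ LOD whose CV and every higher
level's CV stay ≤ 20% (∞ sentinel otherwise).

The efficiency correction divides the mean heavy intensity by p̂ⁿ — the
fraction of heavy molecules with *all* n nitrogens labeled — at the
precursor level (per-fragment correction is available behind a flag).
Heavy S/N uses net area over background area from the features module
(the threshold, 5, is standard; the S/N definition is the package's).
"Interference-free" is operationalized testably: correlation ≥ 0.9 to the
precursor median trace (when trace data exist) and light/heavy fragment
ratio within 2× of the precursor's median fragment ratio. Exclusion flags
are machine-readable and every excluded precursor carries at least one.
Protein amounts are the mean over included precursor amounts with SD/%SD;
mg/L conversion uses 1 pmol × 1 kDa = 1 ng and a configurable plasma
volume equivalent. The shipped default sample-prep profile (5 µl plasma
tenfold diluted, 10 µl digested in 40 µl, quenched to 100 µl, 1 µl
injected) corresponds to 0.01 µl = 1e−8 l plasma per injection.
Chain-resolved constructs (e.g. a protein split into a 30 kDa and a
70 kDa chain) are quantified as separate rows. Missed-cleavage handling
is limited to reporting per-peptide ratios; no automatic correction of
fully cleaved counterparts is attempted.

## Synthetic data (`prmkit.simulate`)

The generators define the study conditions with one mandatory seed and
full determinism. Chromatograms: Gaussian peaks (realistic at these
widths), FWHM lognormal around 8 s, abundances log-uniform over 4 decades
above a floor of 100 (a desk-scale stand-in for plasma's ~7-decade
range), additive baseline noise, 5% multiplicative replicate noise,
fragment patterns drawn once per peptide (Dirichlet) and shared across
replicates, optional interfering peak offset by 2σ at a configured rate.
Gradient default 1260 s (a 21-min, 60-samples-per-day-style run).
Dilution series: 1:4 from 25 ng, 7 levels, 4 replicates, bilinear
response with CV interpolating from 4% (signal-dominated) to 35%
(floor-dominated). Drifting runs: species at random m/z in a 4-Th-window
DIA scheme, per-window chemical background each cycle, drift profiles
bounded by ±30 s (none/constant/linear). What the generators do **not**
emulate: real plasma spectral complexity, FAIMS/ion-mobility effects,
detector saturation, or peak-shape asymmetry — so passing tests
demonstrate algorithmic correctness under the stated model, not
instrument-level performance.

## Problem sizes used in the shipped checks

The acceptance script and test suite use desk-scale sizes chosen to
exercise every code path while completing in seconds: 2,000 simulated
precursors for the filter oracle (200 for the 1,000-draw monotonicity
sweep), 300 targets for scheduling, 60 species / 600 s gradients for
adaptive RT, 100 seeded dilution series, and 100 noise replicates of a
10-precursor labeling panel.
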