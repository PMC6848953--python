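# Methods

This note documents the models and numerical choices behind `fticrms`, the
defaults that matter, what the synthetic generator does and does not
emulate, and known limitations.

## Mass scale and ion convention

All arithmetic uses monoisotopic atomic masses at ≥ 9 significant digits
(12C exactly 12). Singly charged deprotonated ions follow
`m/z = M − 1.00727646 Da`; the electron mass is folded into this proton
term, which keeps computed neutral masses of literature compounds within
the instrument's stated < 1 ppm band (e.g. oleic acid C18H34O2 computes to
282.25588 Da against a printed 282.25602, +0.50 ppm). Published molecular
weights are treated as observations on this scale, not as constants.
`neutral_from_mz` rejects any m/z at or below the proton mass: such an ion
cannot be a (de)protonated molecule in either polarity.

## Peak filtering and alignment

Filtering keeps peaks with S/N strictly above 7 and intensity at least 100
inside the 100–1200 m/z acquisition window; both thresholds and the window
are parameters. The strict/non-strict split reflects that S/N 7 is quoted
as an exclusive criterion while the intensity cut is an instrument default.

Alignment merges all samples' m/z values, sorts them, and starts a new
cluster wherever the gap to the previous peak exceeds the tolerance
(default 1 ppm, matching instrument accuracy) of the larger m/z — greedy
single linkage, deterministic and order-independent for sorted input. The
consensus m/z is the intensity-weighted mean of cluster members. A sample
contributing two peaks to one cluster keeps the peak nearest the
consensus; the conflict is counted and logged.

## Internal calibration

Homologous series are detected by greedy chaining: from each unconsumed
peak in ascending m/z, repeatedly take the nearest peak within the series
tolerance (default 1.5 ppm) of `current + 14.015650`; chains shorter than
3 are dropped and a peak belongs to at most one chain. This realizes the
same maximal-chain semantics as Kendrick-defect grouping with fewer
tunables; the Kendrick mass defect is still reported per series.

Each series is anchored by assigning a formula to its lowest-mass member,
giving a theoretical ladder `anchor + k·14.015650`. The calibration model
is linear in m/z in ppm space, `e(mz) = a + b·mz`, fit by least squares to
the calibrant (observed, theoretical) pairs; corrected masses are
`mz · (1 − e(mz)·1e−6)`. A linear form captures offset plus scale drift
without overfitting the handful of calibrants a single spectrum provides.

The anchor window must exceed the worst uncorrected drift or the true
anchor formula cannot be found, so the bootstrap runs in two passes:
anchoring at 8 ppm (wide enough for several-ppm uncalibrated drift, while
formula spacing at series-head masses keeps wrong anchors rare), an
outlier-robust refit dropping calibrants beyond 3× the fitted RMS, then
re-anchoring at 1 ppm on corrected masses for the final model. On
synthetic spectra with 5 ppm flat or mass-dependent drift and 0.2 ppm
jitter this leaves < 0.3 ppm RMS against ground truth.

## Formula assignment

Candidates are enumerated inside per-element bounds (defaults C 1–100,
H 0–200, O 0–50, N 0–5, S 0–2, P 0–2 — spanning plant-extract organic
matter at desk-scale cost) within a strict ppm window (default 1 ppm).
The enumerator loops only over N, S, P and O; for each combination the
feasible carbon range follows from the residual mass and the compatible
hydrogen count is unique because 1.008 Da dwarfs any sub-ppm window. An
independent brute-force six-deep loop is kept in the test suite as the
oracle. Validity rules: any phosphorus requires at least four oxygens;
DBE ≥ 0; and, by default, integer DBE (H+N+P even) — the analytes are
closed-shell molecules, and admitting radical compositions only adds
decoys. The DBE-integer rule can be disabled.

Selection is fully deterministic: fewest heteroatoms (N+S+P), then
smallest |ppm error|, then lexicographic formula string. Heteroatom
minimization takes precedence because CHONSP space within a 1 ppm window
above ~300 Da routinely contains heteroatom-rich compositions closer in
mass than the true, usually CHO-dominated formula; preferring the leanest
composition is the hierarchical CHO-first practice of
compound-identification algorithms for natural organic matter and is the
only ordering under which "lowest error and lowest number of heteroatoms"
yields unique assignments in this mass range. The cost is deliberate:
genuinely heteroatom-rich species (e.g. the glutathione dimer
C20H32N6O12S2, 8 heteroatoms) can be outranked by a leaner in-window
candidate; such compounds need MS/MS evidence that exact mass alone cannot
supply.

Measured on the synthetic recovery experiment (500 compounds, 0.2 ppm
jitter, default bounds), 97.6–98.6 % of peaks receive their true formula
across seeds. The residual errors are all S- or N-bearing truths above
~500 Da with a fewer-or-equal-heteroatom decoy inside the window — an
information limit of single exact masses, not a search failure (the
enumerator always contains the true formula). Contaminant peaks, which by
construction have no CHONSP mass within 2 ppm, are always reported
unknown.

## Van Krevelen classes and abundances

The seven rectangular class regions (lipid, unsaturated hydrocarbon,
protein, amino sugar, lignin, tannin, condensed aromatic) are encoded with
their exact open/closed endpoints; the condensed-aromatic O:C upper bound
is read as 0.95 (the source text contains a corrupted digit there, and
this is the only reading giving a valid interval). The lipid and
unsaturated-hydrocarbon regions overlap where O:C ≤ 0.125 and H:C 1.5–2.5;
priority follows listing order (lipid first), making classification
single-valued. A carbohydrate region (0.65 < O:C ≤ 1.1, 1.5 ≤ H:C ≤ 2.5)
ships disabled by default because the standard seven-region scheme prints
no range for it — note glucose (O:C 1, H:C 2) is otherwise unclassified.
Class abundance is count-based — the fraction of assigned formulas per
class — and sums to 1 including "unclassified".

## Transformation networks

Nodes are observed m/z values; for each named transformation an edge joins
every pair whose difference matches its exact mass within an absolute
tolerance (default 1 mDa — a ppm tolerance is meaningless for a
difference). Edges are undirected, serialized low→high; parallel edges
with distinct names are allowed. The packaged dictionary holds ~45 common
biochemical transformations (homologation, hydration, (de)carboxylation,
amino-acid and sugar residues, phenylpropanoid acyls, SO3/HPO3, ...), each
defined by a formula so its mass is recomputed, never hard-coded.
First-neighbor extraction returns the subgraph induced by seed nodes and
everything one edge away, counting shared neighbors once.

## Class-abundance PCA

PCA runs on the samples × classes abundance matrix, column-mean-centered
only (compositional fractions share a scale; unit-variance scaling is
opt-in), via a full SVD with a deterministic sign convention: the
largest-magnitude loading of each component is made positive. Group
structure is summarized by ranked Euclidean distances between group
centroids in score space. The test oracle is an independent
eigendecomposition of the sample covariance.

## Synthetic data

The generator emulates a negative-mode direct-injection spectrum of a
plant extract: formulas are rejection-sampled per class inside the van
Krevelen regions (C uniform 6–40; target O:C, H:C uniform inside the
region with a margin so integer rounding cannot flip the class; 25 % of
compounds carry 1–2 N, 4 % carry S; only closed-shell compositions),
neutral masses span 120–900 Da, and the default class mixture is
lignin-dominated (35 % lignin, 15 % lipid, 15 % protein, 10 % tannin,
10 % condensed aromatic, 5 % amino sugar, 5 % unsaturated hydrocarbon) as
in polyphenol-rich moss/plant extracts. Observed m/z values carry
systematic drift `a + b·mz` ppm plus Gaussian jitter (default σ = 0.2 ppm,
inside the < 1 ppm specification); intensities and S/N are log-normal
(medians ~10⁴ and ~30). Optional planted structure: CH2 ladders
(fatty-acyl-like backbones), transformation chains built by composing
dictionary formulas, reference spike-ins, and contaminants drawn uniformly
in m/z and accepted only if the enumerator finds no CHONSP formula within
2 ppm — a guaranteed true-negative set. One seed feeds named substreams
(formulas, errors, intensity, ...), so identical specs are byte-identical
and changing one component does not reshuffle the rest.

What it does not emulate: isotopologue envelopes, multiply charged ions,
adducts beyond ±H, chromatography, detector saturation, or
intensity-dependent mass error. Passing tests therefore demonstrate the
correctness of the computational chain under the stated error model, not
robustness to every artifact of real spectra.

Table emulators produce NMR-style concentration tables (log-normal values
rescaled so each class sums exactly to its target, floored at the ~1 µM
detection limit) and lipid-count tables (multinomial subclass counts with
an embedded, consistent-by-construction total row).

## Packaged reference data

Three small transcriptions of published tables ship with the package: the
29-metabolite NMR concentration table (the source table prints fructose
2,480 µM while its accompanying text says 2,490; the transcription carries
the table value), the 19-row lipid subclass count table with its embedded
total of 152, the 17-compound antimicrobial reference list (two isomer
pairs, hence 15 distinct deprotonated m/z), and per-platform detection
counts (29 + 234 + 240 + 152 = 655). Summary arithmetic uses `math.fsum`
and display rounding to 3 significant figures never alters stored values.

## Problem sizes

Default test and demonstration sizes — 500-compound recovery runs,
100-mass enumeration oracles, 200-node network oracles, 300-compound
calibration runs — were chosen as the smallest sizes at which the measured
rates stabilize; the whole suite completes in well under a minute on one
core, and scaling any of them up only tightens the sampling noise around
the same values.

## Known limitations

- Exact mass alone cannot separate near-isobaric CHONSP compositions at
  high mass; see the assignment recovery discussion above.
- Alignment is single-linkage: a dense run of peaks closer than the
  tolerance chains into one cluster regardless of total span.
- The calibration model is linear in m/z; higher-order instrument
  distortions are deliberately out of reach of two fitted parameters.
- Direct-injection data cannot distinguish isomers; everything downstream
  of a formula (class, network node identity, reference match) inherits
  that ambiguity.
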