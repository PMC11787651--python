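# Methods

This note records the measurement model, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data validation
does and does not demonstrate.

## Chemistry

Residue and element monoisotopic masses come from the pyteomics NIST
tables; the proton is 1.007276 Da. Modification deltas are derived from
elemental formulas, never stored as numbers: ac = C₂H₂O (42.011), me1 = CH₂
(14.016), me2 = C₂H₄ (28.031), me3 = C₃H₆ (42.047), prop = C₃H₄O (56.026),
ph = HPO₃ (79.966), and the methyl-acetyl mark acme = C₃H₄O — note acme is
exactly isobaric with propionyl, which is why it must be placed explicitly
rather than inferred from mass. The registry is a TSV
(`diahist/data/modifications.tsv`) and user-extensible.

Derivatization follows standard propionylation chemistry: propionyl on the
peptide N-terminus and on every lysine that is unmodified **or carries only
monomethyl** (me1 lysine retains a free proton on its ε-amine); acetyl,
di/trimethyl and acme lysines are blocked. Digestion cleaves after arginine
except before proline, never after lysine, with zero missed cleavages.
Histone residue numbering is 1-based after initiator-Met removal, the
community convention behind names like "H3K27"; the bundled FASTA carries
the initiator Met and the loader trims it.

Fragment m/z values are classical b/y ions at product charge 1 (the
precursor search space is 2–4, products 1). b ions carry the N-terminal
modifications; the full-length y ion does too, so y_N coincides with the
singly protonated precursor. Isotope envelopes are computed from the exact
elemental composition by polynomial convolution of per-element natural
abundance distributions, aggregated by nucleon count — compositions are
always known here, so no averagine approximation is needed. Peak spacing
uses the ¹³C–¹²C gap 1.00336/z; three isotopologues are used throughout.

One consequence worth recording: within the H4 4–17 mono-acetyl quartet the
b13 fragment is composition-identical across all four members (each carries
1 ac + 3 prop inside residues 1–13), so b13 cannot separate the positional
isomers; it separates acetyl forms from the pseudo-isobaric trimethyl forms
(Δ 0.036 Da). Only ions cleaved strictly between two candidate lysines —
y10 among them — discriminate within the quartet. The discriminating-ion
enumeration and its tests encode both facts.

## Window design and cycle time

The fixed scheme advances centers by (width − overlap): centers 307…1089 at
width 24 with 1 Da overlap give 35 windows, (295, 319) through
(1077, 1101). The variable scheme emulates vendor variable-window
calculators (whose algorithm is unpublished) by equal-target-count
quantiles: sorted precursor m/z values are split into n chunks whose sizes
differ by at most one, interior boundaries at midpoints between adjacent
chunks, then a minimum width (default 5 m/z) is enforced by forward/backward
sweeps and the overlap (default 1 Da) applied half to each side, so
consecutive windows overlap exactly and coverage has no gaps. Boundaries
are reported to 1 dp in CSV exports.

Cycle time is MS1 accumulation + Σ window accumulations + per-scan overhead
× (n windows + 1). The overhead is an explicit parameter because a 42-window
scheme at 100 ms MS1 / 10 ms MS2 accounts for only 0.52 s of the 0.761-s
cycle such instruments report; the default 5.6 ms/scan is back-fitted to
close that gap and is documented as such.

## DIA run model and formats

A run is an ordered spectrum list with derived cycles: each cycle is one
MS1 survey followed by the scheme's MS2 windows in fixed order, windows
keyed on (low, high) rounded to 2 dp. Only centroided data are modeled;
profile spectra are rejected at parse time. The mzML/mzXML readers are
purpose-built on lxml and deliberately narrow (peak arrays, RT with unit
handling, ms level, isolation windows, 32/64-bit floats, optional zlib);
the mzML writer emits plain non-indexed mzML 1.1 with uncompressed 64-bit
arrays. Gzip is transparent on both ends.

The ms1/ms2 text dialect uses `H` header lines, `S <scan> <scan>
[precursor m/z]`, `I RTime <minutes>`, an `I IsoWindow <low> <high>` line
preserving the exact isolation bounds, and `Z <charge> <M+H>` lines for
every charge in the search space (DIA assigns no precursor charge). Peaks
print as m/z at 5 dp and intensity at 4 dp; round-trip equality is defined
at those printed precisions, and headers are excluded from it. The package
ships its own line parser for re-reading so that empty scans survive the
round trip.

## Quantification

**XIC extraction** sums intensities within |Δm/z|/m/z ≤ ppm·10⁻⁶ per
spectrum (MS1 default 10 ppm, MS2 default 20 ppm, the tolerances standard
for this instrument class). **Peak detection** smooths with a 3-point
moving average, takes smoothed local maxima within expected RT ± tolerance
(default 0.3 min), resolves ties toward the expected RT, and extends
boundaries to the first sample below 1% of the smoothed apex or a local
valley; no Gaussian shape assumption is made anywhere. The noise floor is
max(configured absolute floor, 3 × trace median); peaks truncated at the
trace edge are rejected. Areas are trapezoidal (intensity × minutes) over
raw intensities; the form's MS1 area sums the first three isotopologue XICs
over boundaries shared from the summed-cluster trace. "Points across peak"
counts samples between the boundaries inclusive, so it exceeds
width/cycle-time by one; with the default 1.25-s Gaussian sigma (7.6-s base
at the 1% cut) and the 0.761-s cycle, ~10 samples fall inside the true base
and detected boundaries span 13 samples after smoothing widens them.

**Expected RT** comes either from the target table directly or through a
per-run landmark calibration: anchor targets are located by m/z-only global
XIC maximum and a least-squares line maps library RT to observed RT
(identity below two usable anchors or on a non-positive slope).

**Isomer splitting** uses the cumulative-fraction formulation described in
the README, with heights (not areas) of smoothed MS2 XICs read at the MS1
apex — heights at a single time point make the estimate exact under
co-elution regardless of profile shape, and every ratio cancels the elution
profile and any global intensity scale. Per span, b-ions and y-ions are
pooled separately (sum of modified-variant heights over sum of both
variants) and the two estimates averaged; an ion is used only when it takes
exactly two m/z variants that cleanly partition the members. Spans with no
observed signal are filled by linear interpolation between known cumulative
fractions and flag the result low-confidence; no signal anywhere yields
uniform fractions, flagged. Fractions are differenced, clipped at zero and
renormalized, so they always sum to one. Groups that are not single-site
isomer families (e.g. doubly modified placements, or mixed-modification
families) fall back to nonnegative least squares on per-ion normalized
variant shares. Splitting happens once at the apex; per-cycle time-resolved
splitting is a possible extension, not implemented.

## Ratios and QC

A region is one backbone (protein + span). Ratios divide a form's area by
the summed areas of **all searched** forms of the region (undetected
contribute zero), charge states combined; an observed-only denominator is
switchable. CV% is 100 × sample SD (n−1) / mean. "Identified" means the MS1
peak was found with at least 6 points across it and the isomer split was
not low-confidence — the threshold is configurable because identification
criteria are conventions, not measurements; counts with and without
low-confidence groups are both reported. CVs are computed complete-case
(forms identified in every replicate), the standard way per-peptide CVs are
tabulated.

## The simulator and what it shows

The simulator emits the exact cycle structure the engine consumes. Each
form elutes as a Gaussian (sigma default 1.25 s) whose trapezoid-integrated
3-isotope MS1 cluster equals the injected area; fragments go to every DIA
window containing the precursor, with per-(backbone, ion) base intensities
drawn once from uniform(0.2, 1) so discriminating ions are non-degenerate
and identical across isomer members — which is what makes noiseless split
inversion exact. Isomer groups co-elute exactly and mix fragment intensity
by the injected fractions. Noise is per-peak multiplicative log-normal plus
a uniform additive floor; replicate RT jitter is proportional (default sd
1% of RT) and shared within an isomer group, since members of one backbone
shift together between runs.

The bundled default truth holds 33 derivatized forms built from the
packaged human H3/H4/H2A sequences — the H4 4–17 mono-acetyl quartet at
fractions (0.4, 0.3, 0.2, 0.1), an H3K27 me3/ac pseudo-isobaric pair,
two-member acetyl groups on H3 9–17, H3 18–26 and H2A 4–11, methylation
series on H3K4 and H4K20, and unmodified backbones — with charges chosen to
put every precursor in m/z 300–900, elution slots spread over a 10-min
gradient, and a 42-window variable scheme at 100/10 ms accumulations
(0.761-s cycles). Areas span 2×10⁵–3×10⁶ intensity·min. Validation runs use
this truth at full scale; IO round-trip checks shorten the gradient to 1–2
min to keep file sizes proportionate, which changes nothing but the cycle
count.

What passing recovery tests demonstrate: the engine inverts its own forward
model exactly (machine precision noiseless; ±0.004 fractions and ≤1.3%
areas at 1% noise over 20 seeds), boundaries and sampling behave as
designed, and the format round trips are lossless at printed precision.
What they do not demonstrate: robustness to chimeric backgrounds, tailing
or saturated peaks, charge-envelope ambiguity, or isomers that only
partially co-elute — none of which the simulator generates. Interference
between co-eluting backbones sharing fragment m/z within tolerance is
possible when elution slots are compressed (short test gradients) and is
the main realistic failure mode to expect on instrument data.

## Known limitations

- The split assumes group members co-elute; partially resolved isomers are
  quantified at the shared apex only.
- No FDR/decoy machinery: the search is targeted and library-free by
  design.
- RT calibration is a single linear map per run; no cross-run alignment or
  match-between-runs.
- The bundled target list covers the canonical H3/H4/H2A peptides; a full
  histone PTM search space is expected to be supplied (or extended) by the
  user through the same CSV interface.
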