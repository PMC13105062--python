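# Methods

This note documents the models, statistical procedures, simulator design,
and numerical choices behind `snaparray`. Every number quoted here is
computed by the test suite or the example scripts; nothing is asserted that
the code does not itself produce.

## Probe design

Genomic probes are 48-mers tiled at a 6-bp start-to-start step across
candidate regions (0-based, half-open coordinates throughout; BED
convention). Regions shorter than one probe or longer than 1 kb are skipped
with a logged reason. Probe IDs encode region and offset, so a library
rebuild is bit-reproducible; all combinatorial enumerations emit
lexicographically sorted output for the same reason.

Control probes embed motifs in a fixed 64-base scaffold. The scaffold was
chosen so that no window on either strand lies within two mismatches of the
default consensus — including windows straddling a planted-motif/scaffold
junction — and this property is re-verified at build time (`min_window_distance >= 3`),
so planted sites are the only binding-competent sequence on a control
probe. Dimer spacing is recorded **edge-to-edge** (the number of spacer
bases between the two octamers), matching the natural description of a
"single base pair" separation; the center-to-center spacing `s + 8` is also
stored in probe metadata since the phasing fit's `s_min` absorbs any
constant offset between the two conventions. Spacer bases are drawn from
the scaffold at the positions they occupy, so flank content varies as
little as the geometry allows across the series. The 12-nt primer-extension
constant region is appended at the attachment end and excluded from all
analysis sequence; its only analytical role is the 10-bp exclusion margin
in the flank analysis.

## Normalization

Three stages: (1) **global scaling** — each replicate is multiplied by one
factor; (2) **quantile normalization** — each column is mapped onto the
across-replicate mean of the sorted columns, with tied raw values receiving
the mean of the reference values their ranks span (ties stay tied, at the
cost of exact distribution equality in the tied degenerate case); (3)
**median collapse** — the per-probe median across replicates (mean-of-middle
for even counts) is the final normalized intensity.

The default global-scaling target divides each replicate by its own median
(`target="unit_median"`). This makes the final intensity a
fold-over-median-probe quantity and renders the whole pipeline exactly
invariant to arbitrary per-replicate scale factors — the property a fixed
direct-binding threshold on the final scale requires. A
`target="mean_of_medians"` option preserves raw fluorescence magnitude
instead (every replicate median is scaled to the mean of the raw replicate
medians); the two differ only by one global constant per dataset. Rows with
missing replicate values are dropped (and reported) before normalization,
since quantile normalization needs complete columns. Genomic and control
probes are normalized jointly by default.

## Flanking-base discrimination

Eligible probes carry exactly one perfect consensus window, no second
window within one mismatch anywhere on either strand, and a match at least
10 bases from both the primer junction and the distal probe end. Quartiles
(default 25%) are defined on ranked normalized intensity, ties broken by
probe order, within the eligible subset. For each flank position −5..−1,
+1..+5 (motif-relative; minus-strand matches are reverse-complemented into
motif orientation first, though for a palindromic consensus the forward
reading is canonical):

- the **per-position test** compares the top-quartile 4-base count vector
  against base proportions estimated from all eligible probes (Pearson
  chi-squared, 3 df); the bottom-quartile test is reported alongside;
- the **per-(position, base) test**, which drives the significance flags, is
  the 2×2 Pearson chi-squared (no continuity correction, 1 df) of quartile
  membership against base identity between the two *disjoint* quartiles.
  Disjointness is what makes the test calibrated: a goodness-of-fit test of
  the top quartile against proportions estimated from a superset containing
  it is conservative by construction (the overlap removes about a quarter of
  the sampling variance), so it cannot hold the nominal 5% level.

Raw p-values and Benjamini–Hochberg q-values are both reported; the
significance column and star annotations use raw p < 0.05. The ratio
columns (top/bottom, and top versus background) are descriptive; 0/0 is
reported as the neutral ratio 1.

## Sequence specificity landscape

Each probe is assigned to ring `k` by the minimum Hamming distance of any
window (both strands) to the consensus; the smallest-offset best window is
the representative when several tie, and probes sharing a variant octamer
are collapsed to the class median intensity (the same convention as the
replicate collapse). Within a ring, classes sort by (mismatch-position
tuple, substituted bases in A<C<G<T order, sequence), ordinal `i` of `n`
maps to angle `2πi/n`, and radii grow with ring rank among populated rings
(an empty ring leaves no gap). With strand canonicalization enabled, the 24
one-mismatch variants of a palindromic consensus collapse to 12 classes
over positions 1–4. Flattening ring 1 emits the ordered (ordinal, sequence,
position, base, intensity) table plus the ordinals at which the
mismatch-position section changes; the ring being circular, the transition
from the last section back to the first counts, so a fully populated
uncanonicalized ring has 8 boundaries.

## Helical phasing model

The model and its parameters are stated in the README. Numerical notes:

- All evaluation goes through `log_predict_F`, a log-sum-exp form; the
  linear-scale `predict_F` warns and returns `+inf` where the fluorescence
  exceeds the float range (no phasing minimum within numerical reach), the
  practical signature of every Gaussian term underflowing in linear
  arithmetic.
- `s = 0` is a singular limit (`σ_TW = 0`): the model is `K_min` exactly on
  a minimum center and unbounded elsewhere. The fit excludes `s = 0` by
  default and drops non-finite intensities.
- Truncation at `N = 96` is far past convergence: over `s ∈ [0.5, 40]` with
  the defaults, `N = 96` and `N = 10⁴` agree to better than 1 part in 10¹²
  (asserted in the tests).
- The fit optimizes `(h_r, s_min, ln K_min, ln C_app)` — log
  parameterization keeps the two positive parameters positive — with
  bounded trust-region least squares, multi-started over
  `h_r ∈ {3.5, 5.25, 7, 10.5}` bp crossed with two torsional-stiffness
  starts and two phase-offset starts, because the objective is strongly
  multimodal in the period (period-doubling minima). The best cost wins.
- Residuals may be taken on raw fluorescence (default) or on log
  fluorescence (`scale="log"`). The model's dynamic range spans many orders
  of magnitude and array noise is multiplicative, so the log scale is the
  statistically matched estimator and is what the recovery studies and the
  acceptance script use; optional `weights` (e.g. 1/SEM) are supported.
- A constant-intensity series is flagged non-converged with an
  "unidentifiable" message rather than returning an arbitrary period.
- `phase_of` reports `((s − s_min) mod h_r)/h_r` with a float-mod snap so
  the phase stays in `[0, 1)`; `helix_projection` places spacings around the
  duplex circumference at `2πs/10.5` by default.

## Region classification

Probes collapse into regions by transitive interval overlap on each
chromosome (abutting probes do not merge). A region is **direct** when its
maximum probe intensity strictly exceeds the threshold (default 3.0 on the
final normalized scale — treated here as a fold-over-median quantity and
exposed as configuration); a boundary value is indirect. Distinct binding
sites are maximal runs of above-threshold probes walked in genomic order: a
new site starts after an intervening below-threshold probe or when
consecutive above-threshold windows no longer overlap (a rationale: tiled
48-mers covering one motif necessarily form one contiguous overlapping
run). Differential cofactor association builds a per-region boolean —
IUPAC-pattern presence on either strand of the region sequence, or ≥1-bp
ChIP-seq peak overlap — and tests the 2×2 class-by-feature table with
Pearson chi-squared (1 df, no continuity correction); when an expected cell
falls below 1 the result carries a warning and a Fisher exact p-value is
reported alongside.

## Synthetic data generator

The simulator generates what the analysis stages assume and records ground
truth for recovery tests. Study conditions (the defaults): 300 regions of
150–400 bp on a synthetic chromosome; 70% of regions carry one planted
motif whose mismatch count follows {0: 0.5, 1: 0.3, 2: 0.15, 3: 0.05};
triplicate intensities with per-replicate global scales (1.0, 1.6, 0.7) and
15% multiplicative lognormal noise (unit-mean multiplier; array intensities
are positive and right-skewed). Background sequence is i.i.d. uniform with
rejection of accidental windows within two mismatches of the consensus
(and full rejection below three mismatches when a null genome is
requested).

Expected probe intensity follows a background-plus-binding energy model:
`E = exp(baseline) · (1 + exp(plateau − Σ penalties))` for the
highest-affinity window within four mismatches (fold 1 with none). The
per-position penalties (1.75, 1.75, 3.4, 1.45, 1.45, 3.4, 1.75, 1.75 in log
units) are largest at octamer positions 3 and 6, smallest at the central
4–5, intermediate at the outer A/T positions — the qualitative specificity
ordering genomic binding data show — and the plateau (ln 29, i.e. a perfect
site binds ~30× background) was chosen jointly with them so that **every
achievable noise-free intensity sits well away from the 3.0 classification
threshold** (indirect-class folds ≤ 2.6, direct-class folds ≥ 5). That gap
is what makes the recorded true region class meaningful: classification
errors can then only come from measurement noise, not from folds straddling
the threshold. A +1-flank bonus (0.4 log units for C) applies to perfect
sites only, mirroring the flank analysis, which is defined on perfect
sites. The true class of a region is computed from this same noise-free
model over the region's actual tiling — accidental near-consensus windows
bind too, so the planted site alone does not determine the phenotype.
Dimer-spacing probes instead take expected intensity from the phasing
model at their recorded spacing.

Cofactor sites are planted per region — a FoxA1 consensus
(AWTRTTKRYT expansion) at rate 0.6 in true-indirect versus 0.2 in
true-direct regions (a single odds knob for the tethering scenario), an ERα
half-site (RGGTCA) at a class-neutral 0.3 — with placements rejected if
they would create a new window within three mismatches of the consensus
near the insertion, which could silently change the region's class.

**What the simulator does not emulate:** spatial array artifacts, probe
synthesis bias and secondary structure, position-of-probe effects within
the duplex, dinucleotide or shape-readout binding energetics, cooperative
occupancy of overlapping sites (a probe's intensity reflects its single
best window), and realistic genomic base composition or repeat structure.
Passing recovery tests therefore demonstrate that the pipeline's inference
is correct **given its own modeling assumptions**, not that those
assumptions capture every property of real arrays.

## Problem sizes and reproducibility

The shipped studies run at desk scale as the package's own choice of
experiment size: 300-region arrays (~12,000 probes × 3 replicates) for
end-to-end recovery, 200 simulated datasets of 600 probes for flank-test
calibration, 50 seeded replicates for phasing-parameter recovery, and 10⁵
probes for the normalization invariants. All randomness flows from
explicit seeds (`numpy.random.default_rng`); reruns are bit-identical.

## Known limitations

- The production-scale array (hundreds of thousands of probes over
  thousands of regions) is not reproduced here; its region prioritization
  inputs are not modeled, so real-array summary percentages are outside the
  package's reach and are covered by property-based tests instead.
- The flank analysis treats positions independently; joint flank effects
  and effects beyond ±5 bases are out of scope.
- The phasing model fits the forward-forward orientation; the
  reverse-forward series has no dedicated functional form.
- `scan_motif` reports a strand-equivalent window once (on '+'); consumers
  needing the minus-strand description apply `canonicalize_mismatch`'s
  transform in reverse.
- The fitted `h_r` is reported as-is; whether a ~5.5-bp period is read as a
  half-turn harmonic of a ~10.9-bp repeat is left to interpretation.
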