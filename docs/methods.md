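# Methods

## The behavioral model

The task engine treats one session as a deterministic rule system over a
timestamped event stream. Time is real-valued seconds from session start;
trial *k* owns the half-open window `[k·40, (k+1)·40)`. The schedule
interleaves `round(n_trials × stimulus_fraction)` cue ("stimulus") trials
with cue-free trials in a seeded random permutation; defaults are 60
trials of 40 s, half with a 12-s cue, 0.3-s shocks starting at 0.35 mA.
Classification uses only the **first** port entry of a trial: during the
cue → shock (the cue terminates at the entry and a shock event is emitted
there), at/after cue offset → success, none → omission, any entry on a
cue-free trial → retrieved. Entry exactly at cue offset counts as success
(the cue has ended). Later entries and exits within the trial carry no
task consequence — re-entries after retrieval and entries during the
0.3-s shock itself are not modeled as separate contingencies, and the two
omission classes (cue and cue-free trials) are tallied separately because
the engine cannot know how a particular rig pooled them.

Latency is always measured from the pellet drop. Since cue onset
coincides with the drop, this one convention covers both trial types; the
retrieval anchor used by the photometry warp is the same quantity.

Titration checks the hold criterion first (successes ≥ 2/3 of stimulus
trials, the 20-of-30 rule at the default trial count), then strict
majorities: shocks > 50% → +`step_up`, omissions > 50% → −`step_down`.
Steps default to 0.05 mA (the smaller of the two step sizes in use for
this protocol); the result is clamped at a 0.05-mA floor so intensity
stays positive. With the default logistic agent (see below) a training
cohort converges to 0.45–0.50 mA within five sessions.

## Synthetic agents

`AgentParams` gives the probability `p_success(I)` of waiting out the cue
as a non-decreasing function of shock intensity (default: logistic with
midpoint 0.45 mA, slope 0.1 mA, ceiling 0.95 — chosen so the titration
dynamics produce realistic final intensities), an omission probability
(default 0.05), and a log-normal latency distribution (μ = 0.5,
σ = 0.5 log-s, giving a ~1.6-s median retrieval, shifted past cue offset
on success trials and truncated into the cue window on shock trials).

Rats characteristically oscillate between approaching and retreating from
the visible pellet, retreating faster than they approach. Because the
task defines "entry" by a single beam break, any port entry emitted
*before* the decisive one would itself be the decisive one; the generator
therefore renders the attract–repel oscillation as brief entry/exit bouts
beginning at the classified first entry, which the classifier (by the
first-entry rule) ignores. This keeps the generator and classifier
mutually consistent: classification recovers the generated outcome labels
and latencies exactly, which the tests assert.

## Photometry

**dF/F.** `F_0` at sample *x* is the mean of the central
`middle_fraction` (default 50%) of the ranked samples in the
`window` = 30 s strictly preceding *x* — the current sample is excluded
("preceding"), and when the trim count `w·(1−f)/2` is fractional,
`floor` is trimmed from each tail (stable ranks, the common
interquartile-mean convention). The first 30 s have no complete window
and are flagged NaN rather than back-filled (`edge='grow'` optionally
uses the available shorter window). A non-positive baseline raises: dF/F
is meaningless there. Implementation detail: the sliding windows are
rank-partitioned (`np.partition` at the two trim boundaries) in bounded
chunks, which is exactly equivalent to sort-trim-average (asserted to
1e-12 relative against a brute-force oracle) but runs in O(n·w) with a
small constant — about 15 s for a 40-min session at 100 Hz.

**Time warp.** Each trial's drop-to-entry span is linearly interpolated
onto `round(target_latency · fs) + 1` samples (nearest-neighbor
available); pre-drop and post-entry flanks are carried unwarped. The
target latency defaults to the mean retrieval latency of the contributing
trials, computed per trial type (whether the original analysis pooled
types is unknowable from the text; per-type is the choice here, with an
explicit override). The cue-offset anchor is *recorded*, not warped to:
after a one-piece drop→entry warp its column differs across rows whenever
latencies differ, so the matrix stores per-row anchor columns and reports
the mean-mapping column at matrix level. Warping success trials in one
piece (rather than drop→offset, offset→entry separately) is the default
because only the retrieval latency is a documented warp target. Omission
trials have no retrieval anchor and are stacked unwarped over the fixed
trial window.

**Normalization and approach response.** Min-max normalization maps each
animal's four trial-type mean traces by the animal-wide extrema, so
exactly one sample hits 0 and one hits 1. The approach response is the
mean dF/F over the warped approach span — drop→entry on cue-free trials,
cue-offset→entry on success trials, falling back to drop→entry on shock
trials where the cue ends at the entry itself — minus the mean over an
equal-duration window immediately before the drop. The exact statistic
behind the published quantification is not specified anywhere; this
definition is a configurable stand-in, not a claim of equivalence. The
qualitative hypothesis contrast ("safe approach exceeds punished
approach") is scored as present only when the margin exceeds 25% of the
largest mean response magnitude: under movement coding all responses sit
at noise level and a raw sign test would flip randomly, while measured
relative margins are 0.80–0.97 under value coding and below 0.02 under
movement coding, so the threshold sits in a wide separating gap.

**Signal generator.** GCaMP6s kinetics are modeled as a
difference-of-exponentials kernel (rise 0.2 s, decay 1.5 s — slow-
indicator values; the source protocol gives no kinetics). Value/RPE
coding places a linear ramp (convolved with the area-normalized kernel)
from the moment the pellet becomes safe — drop on cue-free trials, cue
offset on success trials — to the entry, plus a positive transient after
a foot shock; movement coding places a transient at every entry;
inhibition coding holds a sustained elevation while entry is withheld
during the cue. The trace is
`baseline · exp(−t/τ_bleach) · (1 + s(t)) + noise` with τ_bleach = 30 min
and noise chosen so transients stand well clear of the noise floor at
100 Hz. Ramp and transient amplitudes are free parameters, not calibrated
claims — the source reports no amplitudes. What the generator does *not*
emulate: hemodynamic or motion artifacts, indicator saturation, an
isosbestic channel, or learning across sessions; passing tests show the
analysis chain recovers what this forward model encodes, not that real
signals are this clean.

## Nucleus counting

The band-pass is a Gaussian-edged annulus in frequency space,
`H(f) = exp(−ln2·(f·s)²)·(1 − exp(−ln2·(f·L)²))` with half-gain cutoffs
at spatial periods equal to the structure sizes (defaults s = 3, L = 6
px); `H(0) = 0`, so the output is zero-mean. A hard ("tophat") annulus is
available by flag. Dark-nucleus (DAB) images are inverted before
filtering so detection always sees bright peaks.

Before maxima detection the filtered image is contrast-stretched to the
8-bit range with 0.35% symmetric saturation — the display-oriented
"autoscale + saturate" step of the GUI band-pass this routine mirrors.
The prominence threshold (default 145) lives on that 8-bit scale; a plain
min-max stretch would let single extreme pixels compress the scale and
make a fixed threshold meaningless.

`find_maxima` implements flood semantics: a candidate peak is a separate
maximum iff it cannot reach a strictly higher pixel along any 8-connected
path on which intensity stays above `peak − tolerance`; the global
maximum is always reported; plateaus yield one maximum at their centroid,
and equal-height peaks whose connecting saddle is within tolerance merge
into one maximum (without this rule the path criterion alone would never
merge exact ties, contradicting the saddle behavior expected of the
routine). The implementation is a single descending-intensity union-find
sweep (a persistence computation: a region dying at merge level *h* is
reported iff `peak − h ≥ tolerance`); the tests verify it exactly against
an independent per-candidate breadth-first flood on 200 random images.
Maxima whose basin touches the border are kept; ROI masks are supplied as
images — no atlas registration is attempted.

The synthetic micrographs place Gaussian-profile nuclei (FWHM uniform in
3–6 px, ≥ 8 px apart, by bounded dart-throwing) on a second-order
polynomial background with Gaussian noise. Noise (sd 6 at spot amplitude
100) keeps the *band-passed* peak SNR of the largest — most heavily
attenuated — nuclei above 5 and near 10 for the median nucleus; defining
the SNR floor on the raw image instead would be vacuous, since the 3–6 px
annulus passes only 15–33% of a nucleus' amplitude and detection operates
entirely on the filtered image. Recovery-test fields scale with the cell
count (256² for 20–50 cells, 360² for 100) to hold density at a level
typical of a labeled striatal section; at much higher densities
nearly-touching pairs merge under any tolerance, a property of the
counting definition rather than of the noise.

## Statistics

Paired/unpaired t and Pearson r wrap the standard formulas (scipy
distributions for p values); the one-way repeated-measures, two-way
between-subjects and mixed (split-plot) ANOVAs are direct balanced-design
sums-of-squares decompositions in numpy. Self-contained procedures keep a
10,000-replicate null battery under a minute and make the arithmetic
auditable; unit tests check them against loop-based SS oracles (1e-10)
and against statsmodels/pingouin. All tests are two-sided at α = 0.05;
Bonferroni adjusts post hocs as `min(1, m·p)` over all level pairs (the
post hoc family is all pairs — the original pair selection is not
enumerated). No sphericity correction is applied by default (none is
reported in the protocol being mirrored); Greenhouse–Geisser is available
as a flag. Unbalanced factorial designs are rejected explicitly rather
than approximated. Degenerate inputs (zero-variance differences,
all-equal cells) return flagged zero statistics where the limit is
well-defined and raise where it is not.

## Problem sizes and determinism

Every random quantity flows from one integer seed per artifact (schedule,
agent, trace, image); re-running any stage with the same seed reproduces
numeric tables byte-for-byte. The acceptance script runs sessions at the
full 60-trial protocol; photometry hypothesis discrimination uses 3
animals per hypothesis at 100 Hz, count recovery one field per cell count
in {20, 50, 100}, agent recovery 200 sessions, and the null calibration
10,000 replicates per test at 6 subjects — sizes chosen to keep the whole
script in the minutes range on one CPU while leaving Monte-Carlo error
well inside the asserted bands. The analysis drivers use 50-Hz traces for
the same reason; the dF/F window arithmetic is identical at any rate.

## Known limitations

* The approach-response statistic and the stimulus-off anchor handling
  are reasoned stand-ins for an analysis whose exact definition is not
  published; conclusions drawn from their absolute values (rather than
  contrasts) should be avoided.
* The maxima finder reproduces documented flood semantics, not any
  specific GUI build; edge handling and plateau splitting of particular
  versions may differ.
* The agent has no learning or satiety dynamics; pharmacological
  manipulations appear only as parameter regimes (e.g. lowered
  `p_success`, raised `p_omit`), not as receptor-level models.
* Two-way ANOVA supports balanced designs only.
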