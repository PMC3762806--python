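# Methods

## Scope and model

The package treats dyadic interpersonal-distance dynamics as a hybrid
system: a continuous oscillation (approach/retreat cycles) whose
peak-to-peak amplitudes follow a discrete map y_{n+1} = f(y_n), with a
higher-level module switching the map f at peak events.  The analysis
does not integrate the hybrid system; it identifies the discrete maps
from data.  Three families are fitted: linear f(x) = c·x + d (the only
family with an identity-line fixed point, at d/(1−c)), exponential
f(x) = a·e^{bx}, and logarithmic f(x) = a + b·ln x (both "intermittency":
approach/escape without a fixed point in the observed range).

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| filter order / cutoff | 4 / 6 | – / Hz | zero-phase Butterworth on positions; `filter_cutoff_hz=None` bypasses (noiseless data) |
| τ (delay) | 0.1 | s | backward difference ΔD_τ = D(t) − D(t−τ) |
| composite weight w | 0.5 | – | S = w·D̂ + (1−w)·ΔD̂_τ |
| SG order / window | 2 / 9 | – / samples | peak-detection smoothing of S |
| window lengths L | 3–6 | points | moving-window return-map fits, dof = L − 2 |
| σ (measurement std) | 0.02 | normalized | χ² scale; `estimate_sigma` offers a residual-based estimate |
| Q threshold | 0.05 | – | fits with goodness-of-fit probability below it are discarded |
| curved penalty | 2.5 | χ² units | parsimony handicap of exp/log vs linear (see below) |
| quick-detach rule | 1 m / 1.5 s | – | adjacent min→max pairs spreading faster are removed |
| min positive peaks | 4 | – | scene inclusion rule |
| close-approach threshold | 0.25-quantile or absolute (m) | – | negative peaks below it end scenes ("strikes") |
| histogram bin width | 0.05 | normalized | per-match F/N histograms |

### Delay selection

τ is chosen where two min–max-normalized curves over a candidate grid
first cross: the variance of ΔD_τ (growing — longer delays capture more
motion) and the absolute lag-τ autocorrelation of D (decaying — the
delayed coordinate becomes independent).  This is the standard
redundancy/sensitivity trade-off for embedding delays.  Note that the
correlation between D and ΔD_τ itself cannot serve as the decaying
curve: for any stationary series corr(D(t), D(t)−D(t−τ)) =
√((1−ρ(τ))/2), which increases with τ.  The selected τ depends on the
grid range; on the package's synthetic matches (2 s oscillation) a grid
of 0.02–0.30 s selects 0.22 s with perfect stability across seeds.  The
pipeline default stays at 0.1 s, appropriate for the faster content of
real recordings, and is exposed as `tau_s`.

### Composite state conventions

The combination rule is the equal-weight convex combination (w = 0.5),
the difference is backward (causal), and normalization bounds are
computed per match (not per scene) so peak amplitudes are comparable
within a match.  All three are conventions — the downstream analysis
depends only on the ordering and approximate linearity of S-peaks — and
all are exposed as configuration.

### Family selection: the parsimony tie-break

Windows carry 3–6 points with noise on both return-map coordinates
(x_n and y_n are both peak amplitudes).  In that regime the
two-parameter curved families can shadow any straight stretch: on
planted linear repellers at σ = 0.01 a pure best-fit contest picks the
true family only ~50% of the time.  The default tie-break therefore
treats linear as the null family: an overlapping equal-length curved
candidate displaces a linear one only when its χ² is smaller by 2.5
(at the default σ = 0.02).  The 2.5 margin was calibrated as the ≈99th
percentile of χ²_lin − χ²_curved measured on planted linear scenes, so
noise alone almost never promotes a curved family, while genuinely
curved stretches (which beat the linear fit by far more) still win.
Pure best-fit orderings remain available (`tie_break="higher_q"` /
`"lower_chi2"`; identical at fixed dof).

Two related sign constraints: the exponential fit requires a > 0
(convex — the postulated escape shape) and the logarithmic fit b > 0
(concave).  The unconstrained mirror branches (a < 0 exponentials,
b < 0 logarithms) duplicate each other's shapes on short windows and
would make the two intermittency families mutually unidentifiable.

### Screens

A candidate is dropped when Q((L−2)/2, χ²/2) < 0.05, and an exp/log
candidate when its fitted curve crosses the identity line within the
window's observed amplitude range (checked by sign change on a 100-point
grid including the endpoints) — a crossing is a fixed point,
contradicting the intermittency reading.  Selection is greedy
longest-window-first; accepted windows never share a return-map point.

### Degenerate cases

|c| = 1 within 1e-9 is flagged unclassifiable (no crossing with the
identity line); singular designs (all y_n equal) are fit errors; a peak
exactly at the F/N threshold labels N (declared tie rule); sub-states
with zero observations report probabilities as undefined, not 0/0.

## The synthetic generator

`retmap.synthetic` is the verification harness: it plants the exact
structure the analysis assumes.

* **Peak sequences**: regimes iterate their map exactly; switching
  happens at peak boundaries; a regime may chain from the previous
  regime's last peak (so every return-map point belongs to exactly one
  regime).  Iterations must stay inside (0, 1.5) or generation fails
  loudly, naming the regime.
* **Observation noise** is added to peak amplitudes after iteration
  (the quantity the return-map fit observes, matching the χ² error
  model); process noise (inside the iteration) is available via
  `process_noise=True`.  The continuous rendering itself is noiseless so
  peak times are recovered within ±2 samples by construction.
* **Rendering**: half-cosine arcs between peaks and troughs, each
  trough placed at `trough_fraction` (default 0.45) of the smaller
  adjacent peak (so it always lies below both neighbors, even across
  large rotational alternations).  On non-increasing peak runs the
  rising arc into each peak is exactly proportional to that peak's
  amplitude, which makes the composite state's peak amplitudes an exact
  affine image of the planted peaks — planted slopes survive the full
  pipeline exactly; on alternating runs the correspondence is only
  approximately affine and slopes come back with a small bias (classes
  are unaffected).  With the 6 Hz
  Butterworth in the loop, the filter's response to the curvature
  discontinuities at arc junctions leaks ≈2e-6 of neighboring peaks into
  each amplitude, bounding slope recovery at ≈3e-5; the noiseless
  round-trip test therefore runs with the filter bypassed (exact to
  1e-6) and separately with the filter on (1e-3).
* **Matches**: scenes are joined by strike descents to a deep close
  approach (0.65 m) and slow (one-period) two-stage re-engagements —
  rise to the standard trough level, then a standard rising arc into the
  first peak, so even the scene's first peak is affine-consistent — and
  the quick-detachment rule does not fire on planted structure.  The
  meters mapping (baseline 0.65 m, 1.1 m per normalized unit) keeps
  engagement peaks near 1.5–1.7 m, troughs above 0.8 m, and strikes
  cleanly below every trough (default close-approach threshold 0.73 m).  Two agents are placed symmetrically about a
  slowly drifting midpoint on a slowly rotating engagement axis; the
  Euclidean distance reproduces the target IPD to float precision.
* **Planted regime samplers** are rejection samplers constrained for
  identifiability: wide amplitude spans for attractors, lifted-tangency
  exponentials (f(x) > x everywhere, no crossing at any amplitude),
  strongly bent logarithmic divergence from a repelling crossing, and a
  ≥0.15 map separation between consecutive switching regimes so
  boundary-straddling windows fail the Q screen.  Family recovery from
  ≤6 noisy points is only meaningful when the planted shapes occupy
  distinguishable regions of function space; these defaults encode that
  requirement and are documented rather than tuned per run.
* **Two-mode chains** (`markov_regime_chain`) alternate attractors with
  high (0.85) and low (0.35) fixed points under a first-order mode
  chain, producing the bimodal peak histograms the F/N thresholding
  expects, with planted labels as ground truth.

What the generator does **not** emulate: marker dropout and occlusion,
referee stoppages (exclusion intervals must be supplied by the caller),
video-identified strikes (the close-approach threshold is a proxy),
non-stationary oscillation periods, and measurement noise with temporal
correlation.  Passing tests demonstrate correct recovery of planted
structure under the stated noise model, not performance on real
motion-capture data.

## Transition statistics

Transitions are counted within scenes only (scenes are separated by
strikes or stoppages).  Third-order triples exist only from each scene's
second pair onward, so the exact marginalization identity (third-order
counts summed over the older label equal second-order counts) is stated
against `second_order(..., skip_first_pair=True)`.  The two-sided Fisher
exact test enumerates all tables with the observed margins in exact
integer arithmetic (shared denominator), summing point probabilities not
exceeding the observed one; degenerate margins return p = 1 with a
warning.

## Problem sizes

The verification experiments use 100 random series for the smoothing
oracle, all 12 376 tables with margins ≤ 15 for the Fisher oracle,
1 000 random maps for the classification check, 200 single-regime scenes
per family and 100 switching scenes for recovery, ≥1 000 transitions per
conditioning sub-state for chain recovery, and a 6-match two-group
tournament (6 scenes/match) for the end-to-end study — sizes chosen so
binomial standard errors are well inside the asserted bounds.

## Known limitations

* Q values depend on the assumed per-point σ (default 0.02, normalized);
  they are comparable within a run, not across error models.
* Family identification saturates at roughly 95–99% under σ = 0.01 even
  with identifiable planted shapes; with ≤6 points some noise draws are
  genuinely better explained by the wrong family.
* The mean synthetic scene is longer than typical competition scenes
  (multi-regime scenes of 8–20 peaks at the 2 s default period);
  durations stay within the observed real-data range.
* Windows require consecutive peaks; scene-internal gaps are not
  spanned.
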