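# Methods

## The acoustic model of feeding

An echolocating beluga adjusts its click rate to the two-way travel time
to the target. During prey capture the range closes monotonically, so the
inter-click interval (ICI) of a feeding click train decreases gradually
into a terminal buzz and reaches its minimum at the end of the buzz.
Social buzzes have no such range constraint: their ICI is irregular,
longer, and the train is buzzing throughout. The pipeline reduces each
train to five summary variables and classifies on the two that separate
the behaviors without overlap:

* **minICI** — minimum ICI of the train (ms). Feeding buzzes bottom out
  in the 2.3–8.92 ms band; social buzzes stay at or above 9.03 ms.
* **ICIir** — the maximum consecutive-ICI difference within the buzz
  section (ms). A steadily decreasing feeding buzz has every increment
  negative, so its maximum increment is negative (−8.82 to −0.42 ms
  band); irregular social buzzes jump upward by 2.98–18.72 ms.
* **maxICI, ICIr = maxICI − minICI, slope** — context variables carried
  through the cluster analysis; their distributions overlap between
  behaviors and they carry no classification guarantee.

The buzz section of a feeding or unlabeled train starts at the first ICI
at or below 9 ms (boundary inclusive); a social buzz is processed whole.
ICIir is reported absent when the section is missing or holds fewer than
two ICIs — an absent ICIir can never support a feeding call.

The **two-step classifier** for moored-recorder data, where context is
unknown, is the conjunction of strict inequalities minICI < 8.976 ms and
ICIir < 1.49 ms, evaluated after excluding trains with minICI < 1 ms
(surface-reflected multipath duplicates the true click and fabricates
sub-millisecond ICIs). The cuts are configuration, defaulting to the
published decision constants; the stump-derived midpoint on a given
sample (8.975 on the printed extremes) is deliberately **not**
substituted for them.

## Numerical choices

* ICIs are computed as differences of click peak times (s) × 1000 and
  rounded to 1e-12 ms. The rounding absorbs floating-point representation
  noise from the differencing — it is twelve orders of magnitude below
  any instrument clock — so exact comparisons at the 9 ms onset boundary
  behave as written.
* The slope regresses ICI (ms) on the peak time (s) of the click opening
  each interval, in centered form: a constant-ICI train has slope exactly
  0, and the statistic is invariant to shifting all click times. An
  index-based regressor is available behind `slope_regressor="index"`;
  time is the default because ICI is a time-local quantity.
* Feature scaling is centering plus division by the sample (n−1) standard
  deviation; a zero-variance column raises an error naming the column
  rather than silently producing NaNs.

## The cluster sweep

The validation grid reproduces a 64-model comparison: 16 PAM models (the
5-variable and 2-variable {minICI, ICIir} sets × {Euclidean, squared
Euclidean, Manhattan} × {scaled, unscaled} = 12, plus the single-variable
sets {minICI} and {ICIir} × both scalings = 4, where distance is
immaterial in one dimension) and 48 hierarchical models
(complete/single/average/weighted average × {Euclidean, Manhattan} ×
variable sets × scalings = 32; centroid with squared Euclidean only = 4;
median with Euclidean only = 4; Ward with Euclidean and with squared
Euclidean = 8).

PAM is BUILD (greedy medoid seeding minimizing total dissimilarity)
followed by SWAP (steepest-descent medoid/non-medoid exchange).
Determinism without seeds: argmin/argmax ties take the lowest index, and
an equal-cost exchange is accepted only toward a lexicographically
smaller medoid set, so each step strictly decreases (cost, medoid set)
and the walk terminates. Like every BUILD+SWAP variant — including the
canonical R implementation — this is a local search: the result admits no
improving single exchange but is not guaranteed to be the global cost
minimizer, and on small unstructured point sets (n ≤ 8) it lands in a
non-global local optimum on roughly 5–7% of random instances. On data
with actual cluster structure, such as the buzz features, this is not
observed.

Hierarchical clustering applies the Lance–Williams update for each
linkage to the dissimilarity matrix exactly as given (squared-Euclidean
variants square the Euclidean matrix first; Ward on squared distances is
classic Ward, Ward on raw distances mirrors the second Ward variant).
Merges take the smallest pairwise dissimilarity, ties to the oldest pair
of clusters; the tree is cut at k = 2 by undoing the last merge. The test
suite validates every linkage against R's `hclust`/`cutree` on the same
matrices, and PAM against exhaustive medoid enumeration.

The Fowlkes–Mallows index B = T/√(PQ) (pair-counting agreement, 0 when
either partition has no co-clustered pair) is delegated to scikit-learn
and cross-checked against direct pair counting in the tests. The decision
stump searches all midpoints between consecutive sorted unique values of
each variable, minimizing the children's weighted Gini impurity; among
equally pure splits the variable listed first wins, matching the
behavior of formula-order-dependent tree fits.

## Monitoring statistics

An hour with at least one beluga detection of any signal type is a
detection positive hour (DPH); a minute whose first-click timestamp
carries at least one feeding verdict is a foraging positive minute (FPM).
Both are idempotent under event duplication, and FPM ≤ detection-positive
minutes by construction. Bins are clock-aligned in local time; a train
belongs to the minute of its first click (trains last seconds, spillover
is negligible). The 7-day running average of daily DPH is **centered**
(±3 days, shorter windows at the series edges); trailing would lag the
seasonal description it serves. Monthly summaries count, over the days of
a month that have any FPM, the days, the summed FPM, and the summed
non-FPM (detection-positive minutes without a feeding verdict on those
same days). Duty-cycled recorders appear simply as event absence; no
duty-cycle correction is applied.

## Run-timing alignment

Individual site-to-weir travel times (integer days) form a histogram over
their observed support, smoothed by a centered 5-day moving average
(shorter windows at the edges) and normalized. Weir counts are shifted
**earlier** through this distribution — fish at the site precede fish at
the weir — so predicted(d) = Σₗ w(l)·weir(d+l), with the predicted index
extended back by the maximum lag; the convolution conserves total mass.
The run peak threshold is the 90th percentile (linear interpolation of
order statistics) of predicted counts over days with predicted count > 0;
including zero-days would deflate the threshold on long seasons. The peak
period is the contiguous span from first to last qualifying day, with
interior sub-threshold days counted and reported rather than splitting
the period. Because the aggregation behind a "7-day-average DPH" figure
over a window is ambiguous between a sum and a mean, the overlap report
labels and reports both.

## The synthetic-data generators

The generators emulate exactly the structure the analysis assumes, and
are the fixture for every end-to-end test.

* **Feeding trains**: the buzz opens at an ICI drawn in 8.2–8.99 ms and
  descends strictly to a minICI drawn in the 2.3–8.92 ms band, in steps
  no smaller than a drawn increment magnitude, one of which is exact — so
  the realized ICIir equals the drawn value in the −8.82 to −0.42 ms
  band. The pre-buzz section is a decreasing ramp held strictly above
  9 ms whose mean sits at 2–5× the buzz mean (the observed fold-drop into
  the buzz). The printed per-train extremes are jointly infeasible at the
  corners — a buzz opening at ≤ 9 ms cannot both bottom at 8.92 ms and
  step by −0.42 ms, nor reach a −8.82 ms step from a ≤ 9 ms start while
  bottoming at ≥ 2.3 ms — so (minICI, ICIir) are drawn jointly from the
  feasible region inside the published bands. Marginals therefore sit
  inside, but do not span, the printed ranges; the separation from the
  8.976/1.49 cuts, which is what the classifier tests require, is exact.
* **Social buzzes**: the ICI starts at a minimum drawn in 9.03–29.75 ms,
  immediately rises by the drawn maximum increment (2.98–18.72 ms band),
  then alternates smaller rises and falls without dipping below the
  minimum — irregular, alternating-sign increments with an exact realized
  ICIir. Social buzzes run about twice as many clicks as feeding trains.
* **Mooring streams**: Poisson train arrivals per day, uniformly timed,
  mixed between the two generators at a configurable feeding fraction;
  every train emits an echolocation event and call/whistle events arrive
  independently. The clock minutes of feeding-train starts are retained
  as ground truth, making FPM recovery exactly checkable.
* **Weir seasons**: site arrivals follow a rounded Gaussian pulse; each
  fish's weir date adds a travel time resampled from a supplied lag pool
  (default: a gamma draw clipped to the 3–33 day range with median near
  14 days). The true site series is returned for recovery testing:
  a point-mass lag makes the back-shift exact, and with 10,000 fish the
  predicted peak date lands within ±2 days of the true one.

What passing these tests does **not** show about real data: the
generators draw features from inside non-overlapping bands, so perfect
classifier accuracy and Fowlkes–Mallows 1.00 are properties of the band
geometry, guaranteed by construction. Real moored recordings add
fragmentary trains (the whale rarely points at the hydrophone for the
whole buzz), overlapping animals, species confusion, and detector error
— none of which the generators model. The synthetic results validate the
computational chain, not the field performance of the thresholds.

## Problem sizes and defaults

Test and acceptance runs use the study-sized buzz fixture (18 feeding,
19 social), mooring streams of 4–10 days at 12–20 trains/day, weir
seasons of 10,000 fish, and oracle comparisons at n ≤ 10 points — sizes
at which every oracle (exhaustive medoid search, R hclust, direct pair
counting) is exact and the whole suite runs in seconds on one core.

## Known limitations

* The classifier assumes single-source click trains; overlapping animals
  are the upstream detector's problem (the multipath floor removes only
  the surface-reflection case).
* Timestamps are taken as already-local and timezone-naive; no DST or
  timezone arithmetic is performed.
* Travel-time lags are applied uniformly to all species when only one
  species' tagging data exist — a stated approximation of the analysis,
  not corrected here.
* The stump is a single split by design; multi-level trees are out of
  scope.
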