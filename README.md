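# belugabuzz

Acoustic detection of beluga whale (*Delphinapterus leucas*) feeding
behavior from echolocation click trains, and the monitoring statistics
built on top of it.

Belugas, like other odontocetes, end a successful prey chase with a
*terminal buzz*: the inter-click interval (ICI) of the echolocation train
falls steadily as the whale closes on the fish. Buzzes also occur during
social interactions, so a buzz alone is not evidence of feeding — but
feeding and social buzzes differ sharply in their ICI statistics. This
package implements the full analysis chain that exploits that difference:

1. **ICI features** (`buzzfeatures`) — per train: minICI, maxICI, the ICI
   range ICIr = maxICI − minICI, the OLS slope of ICI against time, and
   the ICI increment range ICIir = max(ICIᵢ₊₁ − ICIᵢ) within the buzz
   section. The buzz section of a feeding or unlabeled train starts at
   the first ICI ≤ 9 ms; a social buzz is buzzing throughout. A steadily
   decreasing feeding buzz has ICIir < 0; an irregular social buzz has
   ICIir ≫ 0.
2. **Cluster sweep** (`clustersweep`) — the 64-model validation grid:
   16 partitioning-around-medoids (BUILD+SWAP) and 48 agglomerative
   hierarchical (Lance–Williams, seven linkages) configurations over the
   five variables, each scored against presumed behavior with the
   Fowlkes–Mallows index B = T/√(PQ), plus a decision stump that turns a
   perfect partition into a single threshold (midpoint between class
   extremes).
3. **Two-step classifier** (`feedclassify`) — a train is a feeding event
   iff minICI < 8.976 ms **and** ICIir < 1.49 ms; trains with minICI
   < 1 ms are excluded as surface-multipath artifacts.
4. **Monitoring statistics** (`pamsummaries`) — detection positive hours
   (DPH, any beluga signal in a clock hour), a centered 7-day running
   average, foraging positive minutes (FPM, at least one feeding train in
   a clock minute), and monthly FPM summaries.
5. **Run-timing alignment** (`salmonruns`) — weir counts of anadromous
   fish are back-shifted through a smoothed (centered 5-day moving
   average) empirical travel-time distribution, predicted(d) = Σₗ w(l) ·
   weir(d + l); the run peak is the span of days at or above the 90th
   percentile of positive predicted counts, over which FPM and smoothed
   DPH are aggregated.
6. **Synthetic data** (`synthdata`) — seeded generators for feeding
   trains, social buzzes, mooring detection streams, and weir seasons
   with the statistical structure the analysis assumes, so the whole
   chain is testable without field recordings.

The intended users are passive-acoustic-monitoring analysts who have
click-train tables (from moored click loggers or acoustic tags) and want
feeding occurrence series aligned with prey phenology.

## Worked example

```sh
belugabuzz simulate --seed 7 --out-dir demo
belugabuzz classify --clicks demo/mooring_clicks.csv --out verdicts.csv
belugabuzz sweep --clicks demo/buzzes.csv --out sweep.csv
```

`simulate` writes a labeled 37-buzz table (18 feeding, 19 social), a
10-day mooring stream (186 click trains with timestamps), and a weir
season. `classify` prints the thresholds it used and writes one verdict
per train:

```
train_id,timestamp,verdict,minICI,ICIir
cp_00001,2018-05-01T02:48:34.994526797,not_feeding,15.290192123907,
cp_00003,2018-05-01T04:27:31.850565832,feeding,7.984588739707,-0.9441443887670005
```

`cp_00001` never buzzed below 9 ms (minICI 15.3 ms, no buzz section, ICIir
absent) and fails step 1; `cp_00003` bottoms at 7.98 ms with a steadily
falling buzz (ICIir −0.94 ms) and is a feeding event. On this stream the
classifier marks 57 of 186 trains as feeding. The sweep report ranks all
64 cluster models by Fowlkes–Mallows index:

```
family,distance,linkage,variables,scaled,fm_index
pam,euclidean,,minICI+maxICI+ICIr+ICIir+slope,True,1.0
```

On the labeled fixture the scores span 0.56–1.00, and every model built
on the non-overlapping pair (minICI, ICIir) separates the two behaviors
perfectly. `belugabuzz run-all --config cfg.txt` chains classification,
daily/monthly summaries, and the salmon-run overlap report; see
`belugabuzz --help` for the file schemas and flags.

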