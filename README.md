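# emoagree

Agreement analytics and reliability filtering for crowdsourced emotion-dyad
annotations.

Labeling the emotion of a person *in context* is a subjective task: different
annotators read the same image differently, and some record the emotion the
scene evokes in *them* rather than what the depicted subject feels (the
"projection effect", which produces votes in wheel-opposite categories).
`emoagree` implements, as a reusable and fully tested pipeline, a relabeling
protocol built around two quality controls:

* **AP — attentiveness promotion.** Annotation happens in daily sessions of
  56 images, of which 6 are *control images* (whose expected answer was fixed
  by a 5-rater pilot with a 4-coincidence rule) and one image appears twice.
  A session is discarded wholesale unless the repeated image gets the same
  answer twice and at least 5 of the 6 controls are answered correctly.
* **RE — reliability enhancement.** For each image, the 8 vote counts are
  standardized, `Z_j = (n_j − μ)/σ`, and only the dyads with `Z_j ≥ 0`
  (equivalently, count at or above the per-image mean) are kept as labels;
  the other votes are discarded.

The category system is the eight Plutchik emotion dyads (Anger/Rage,
Engagement/Anticipation, Disgust/Disconnection, Fear/Worry, Joy/Affection,
Sadness/Discouragement, Surprise/Amazement, Trust/Peace); EMOTIC's original
26 emotion words are mapped onto them, and a category-balanced subset is
selected by per-image vote percentage. Agreement is measured per image with
a Fleiss-style coefficient against uniform chance over the K = 8 categories:

```
P_obs = (Σ_j n_j² − n) / (n (n − 1)),      κ = (P_obs − 1/8) / (1 − 1/8)
```

with the usual Landis–Koch reading (Poor < 0 ≤ Slight ≤ 0.2 < Fair ≤ 0.4 <
Moderate ≤ 0.6 < Substantial < 0.8 ≤ Almost Perfect).

A synthetic annotator simulator generates study-scale data (1,120 images,
20 days, 28 raters/day) with known ground truth — attentive raters vote from
a wheel-distance mixture around the true dyad, a configurable fraction of
rater-sessions is inattentive and votes uniformly — so every stage, and the
end-to-end effect of AP + RE, can be exercised and tested without any
external data. See `docs/methods.md` for the model details.

## Worked example

```python
import emoagree as ea

study = ea.simulate(ea.SimulationConfig(seed=1))          # synthetic study
retained, audit = ea.apply_ap(study.records, study.controls)
print(f"sessions valid: {int(audit['valid'].sum())}/{len(audit)}")

results = ea.AnnotationAgreement.from_records(retained).fit()
print(results.summary())

filtered = results.filter_reliability()
print(filtered.summary())
print(filtered.recovery(study.truth))
```

prints

```
sessions valid: 469/560
Per-image agreement over 8 emotion dyads
  images: 1120   mean raters/image: 23.4
  mean kappa: 0.42 (Moderate)

                n_images  mean_n_raters  mean_kappa
band
Slight                93           23.0      0.1554
Fair                 538           23.5      0.3067
Moderate             322           23.5      0.4777
Substantial           62           23.1      0.6830
Almost Perfect       105           23.5      0.9355

Z-score reliability filter (kept dyads: vote count >= image mean)
  images: 1120
  mean kappa: 0.42 -> 0.73
  max labels/image: 8 -> 4
  ...
{'n_images': 1120, 'frac_true_kept': 1.0, 'frac_true_unique': 0.397, ...}
```

Read: AP discarded 91 of 560 sessions (inattentive raters and attentive
slips); the per-image agreement over the retained votes averages κ = 0.42
(Moderate); the Z-score filter then trims each image's label set to its
above-mean dyads, raising mean κ to 0.73 and capping labels at 4 per image,
and on this synthetic run the kept set contains the true dyad for every
image (and is exactly `{true dyad}` for 40% of them).

The same pipeline is available from the shell:

```bash
emoagree --seed 1 run-all --out run/           # all stages + manifest.json
emoagree simulate --out sim/                   # or stage by stage:
emoagree validate-ap --annotations sim/annotations.csv \
    --controls sim/controls.csv --out-retained retained.csv --out-audit audit.csv
emoagree kappa --annotations retained.csv --out per_image_kappa.csv
emoagree filter-re --annotations retained.csv --out re_results.csv
emoagree report --kappa-table per_image_kappa.csv \
    --re-results re_results.csv --out report.json
```

To analyse real annotation exports instead of simulated ones, provide CSVs
in the dialects documented in `emoagree/io.py` (`annotations.csv` with
columns `image_id,annotator_id,day,dyad_id`, `controls.csv` with
`image_id,expected_dyad_id`, and — for subset selection —
`original_annotations.csv` with `image_id,annotator_id,emotion_word`).

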