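# Methods

This note documents the statistical procedure the package implements, the
generative model behind the synthetic annotators, the numerical conventions,
and the design decisions taken where the protocol leaves room.

## The annotation protocol

The pipeline models a four-stage relabeling protocol for emotion-in-context
imagery:

1. **Subset selection.** From original 26-word annotations, each image's
   votes are collapsed into the 8 Plutchik dyads and the image is scored by
   the vote share of its best dyad, `Pct = max_j (votes_j / total votes)`.
   A balanced subset takes, per dyad, the `quota` images with that dyad as
   representative (highest share first). Vote share — not an agreement
   coefficient — is the selection statistic because per-image rater counts
   in the source annotations vary by an order of magnitude.
2. **Session annotation.** Daily sessions of 56 distinct images, one dyad
   per image per rater; 57 presentations because one image repeats.
3. **Attentiveness promotion (AP).** Six of the 56 are control images whose
   expected dyad was fixed in a pilot (an image qualifies when ≥ 4 of 5
   pilot raters coincide; the coinciding dyad is the expected answer). A
   session is kept only if the repeated image is answered consistently and
   ≥ 5 of 6 controls are answered correctly; rejection discards all 57
   presentations. In valid sessions the duplicate collapses to its first
   presentation (the two agree by construction of validity).
4. **Reliability enhancement (RE).** Per image, the 8 counts are
   standardized (`Z_j = (n_j − μ)/σ`, moments over all 8 counts, zeros
   included, population σ); dyads with `Z_j ≥ 0` are kept, the rest of the
   votes are discarded, and the agreement coefficient is recomputed on the
   surviving counts.

## The agreement coefficient

Agreement is per image. With `n = Σ_j n_j` raters,

    P_obs = (Σ_j n_j² − n) / (n (n − 1))

is the fraction of concordant rater pairs (identical to exhaustive pair
counting — the test suite proves this exactly for every vote vector with
n ≤ 12), and

    κ = (P_obs − 1/8) / (1 − 1/8).

Chance agreement is **uniform** (1/8), not the marginal-based expectation of
the classic pooled Fleiss statistic. Two reasons: each image is analysed as
a standalone experiment whose rater count varies, so per-image marginals are
degenerate (a single image's marginal-based chance equals P_obs-like
quantities and yields pathological values); and the uniform convention is
the one that reproduces the protocol's published worked example — the vote
vector (1,1,1,23,3,1,0,0) has P_obs = 512/870 and κ = 0.5297 ≈ 0.53, whereas
marginal-based chance would give a negative coefficient. κ therefore lives
in [−1/7, 1]: −1/7 when each dyad gets exactly one vote, 1 under unanimity.

Aggregate "mean kappa" is the unweighted mean of per-image kappas (a pooled
coefficient is ill-defined when rater counts differ per image). Per-dyad
summaries group images by modal dyad, ties to the lowest id. Landis–Koch
bands: Poor κ < 0; Slight 0 ≤ κ ≤ 0.2; Fair 0.2 < κ ≤ 0.4; Moderate
0.4 < κ ≤ 0.6; Substantial 0.6 < κ < 0.8; Almost Perfect κ ≥ 0.8 (the open
upper edge at 0.8 matches the observed category ranges of the protocol's
reference tables, e.g. 0.7971 Substantial vs 0.8021 Almost Perfect).

## The Z-score filter

Because σ only rescales, the kept set is exactly `{j : n_j ≥ μ}`; it always
contains the modal dyad, so it is never empty, and it equals all 8 dyads iff
all counts are equal (σ = 0, where every Z is defined as 0). Post-filter κ
keeps K = 8 and uniform chance 1/8, computed on the surviving counts with
the dropped votes removed (raters discarded, not reassigned); this
convention reproduces the reconstructable reference value for a two-dyad
15/10 split, κ = 3/7 ≈ 0.4286. The filter is scale-equivariant (kept set
unchanged under `n_j → c·n_j`) and empirically never lowers κ: the suite
checks 10,000 random vote vectors at 15–35 raters and collects (rather than
ignores) any counterexample; none occur. A `z_threshold` knob generalizes
the cut to `Z ≥ c`; only `c = 0` is the protocol's rule (for `c > 0` the
kept set can be empty, which raises).

## Wheel geometry

Dyad ids 1–8 follow the protocol's category list (alphabetical-ish), which
is *not* wheel order, so each dyad also carries a wheel position 0–7 in the
standard Plutchik layout with antagonist pairs joy–sadness, trust–disgust,
fear–anger, surprise–anticipation 180° apart. Wheel distance is the minimal
circular distance (0–4); distance 4 ⇔ opposites. The geometry is needed only
by the simulator's noise model. The 26-word vocabulary keeps the source
spellings as canonical ("Disquitement", "Suprise", "Doubt/Confussion") and
accepts the conventional spellings as aliases; matching is case-insensitive
and whitespace-trimmed.

## The synthetic annotator model

`simulate()` emulates the study at its own scale — defaults 1,120 images,
20 days, 28 raters/day, 56 images/session — with:

* **Ground truth**: one true dyad per image, balanced across the 8
  categories.
* **Attentive votes**: per (rater, image), a dyad from a wheel-distance
  mixture — `p_true` on the truth (default 0.65), `p_adjacent` split over
  the two adjacent dyads (default 0.20), `p_opposite` on the wheel-opposite
  dyad (default 0.05, the projection effect), residual uniform on the
  remaining four. The perceived dyad is drawn once per rater-image, so the
  repeated image is answered consistently — attentiveness *is* consistency.
  Controls are answered correctly with `p_control_correct` (default 0.95),
  otherwise uniformly among the other 7 dyads.
* **Inattention**: a fraction `inattentive_rate` (default 0.10) of
  rater-sessions votes uniformly at random per presentation; such a session
  passes AP with probability `(1/8)[6(7/8)(1/8)⁵ + (1/8)⁶] ≈ 2.05 × 10⁻⁵`
  (duplicate match × ≥5-of-6 controls), which the suite verifies by a
  10⁶-session Monte Carlo against the closed form.
* **Session assembly**: a pilot of 5 simulated raters fixes the control
  pool (≥ 4 coincidences); each day deploys 6 pilot-qualified controls,
  disjoint across days, plus a disjoint block of 50 non-controls; the
  duplicate is drawn from the non-controls so each session contains exactly
  6 control presentations (the validator itself also handles a duplicated
  control, judging correctness on first presentations). Every image is
  shown on exactly one day to all of that day's raters.

The defaults were chosen once to land the post-AP agreement in the
Fair-to-Moderate regime characteristic of crowd emotion annotation (mean
κ ≈ 0.4 at 28 raters); with them, the full synthetic pipeline reproduces the
protocol's qualitative signature — AP discards ~16% of sessions, RE lifts
mean κ from ≈ 0.42 to ≈ 0.73, shifts the band histogram toward Almost
Perfect, and caps labels per image at 4.

All randomness flows from one `numpy` generator seeded by the config, so
every output table is byte-identical across reruns. Attentiveness is drawn
per rater-session (not per rater), matching the per-day discard unit; the
simulator does not model rater identity across days, demographic covariates,
attendance dynamics, or image content. Consequently, passing tests show that
the *procedure* behaves as specified under its assumed noise structure — not
that real human annotations satisfy that structure; dataset-level numbers
from the deposited human relabeling (e.g. its exact mean kappas and band
counts) are reproducible only from those deposits.

`simulate_vote_counts()` bypasses session structure (direct mixture votes,
n raters per image) for parameter sweeps; the fidelity sweep and recovery
checks use it at 200 images × 28 raters with reduced noise masses
(`p_adjacent` 0.05–0.12, `p_opposite` 0.02–0.03) because the mixture
constraint `p_true + p_adjacent + p_opposite ≤ 1` binds at high `p_true`.

## Numerical conventions and degenerate inputs

* Agreement requires n ≥ 2; the pipeline excludes (and counts in its
  manifest) images left with fewer than 2 retained votes after AP — possible
  only in tiny simulated runs, never at study scale.
* Argmax ties (representative dyad, modal dyad, pilot expected dyad) resolve
  to the lowest dyad id; subset ranking ties resolve by ascending image id.
* Population σ (divide by 8) in Z-scores — inert for the filter (only the
  sign of Z matters) but fixed for reproducible reporting.
* Headline kappas print at 2 decimals, per-image tables at 4.
* CSV dialects: UTF-8, comma-separated, mandatory header; schemas in
  `emoagree/io.py`. Malformed inputs are reported with file and line.
* Pipeline problem sizes: the test and acceptance runs use the study-scale
  defaults for single computations (1,120 images) and reduced sizes
  (150–300 images, 2-day toy pipelines) for sweeps and property checks —
  sizes at which Monte-Carlo error is far below the tested effects.

## Known limitations

* The RE monotonicity of κ is an empirical property checked at study-like
  rater counts, not a theorem proved for all vote vectors.
* Pilot raters' votes never enter the public tallies (the protocol is
  silent; exclusion is the conservative reading).
* The deposited human annotations are not consumed; adapting them would
  require mapping their export columns onto the `annotations.csv` dialect.
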