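# Methods

This note records the model the package implements, the choices made where
the published description of the original tool is silent or ambiguous, and
what the synthetic-data experiments do and do not demonstrate.

## Data model

A skeleton stream holds, per frame: 20 joint positions (metres, camera-1
frame), a tracking state per joint (Tracked / Inferred / Not Tracked), 20
bone orientations (XYZ Euler angles, degrees), and a timestamp.  Published
descriptions of such recordings name these fields but not a byte layout, so
the `.kss` format is this package's own: little-endian, a 16-byte header
(magic `KSS1`, u16 version, u16 reserved, u32 frame count, u32 nominal rate
in mHz) and fixed 508-byte frames (f64 timestamp; 20 × (3×f32 position + 1
validity byte); 20 × 3×f32 orientations; 508 is already 4-byte aligned so no
padding is needed).  Fixed-size frames make truncation detectable and
seeking trivial.  The validity byte packs the tracking state in its low two
bits and, on fused streams only, a fusion-provenance code in the next three.
Participant metadata and exclusion intervals live in a JSON sidecar so the
binary body stays fixed-pitch.

Conventions fixed by decision: X = player's right, Y = up, Z = away from the
camera ("vertical" in the rule set is Y, "horizontal" is X); timestamps are
seconds relative to the first frame (rule windows are in seconds);
orientations are degrees.  Streams store positions as float32 (sensor noise
is of order centimetres); single `Frame` objects used in calibration
geometry are float64 so quantisation does not dominate the yaw estimate.

Exclusion intervals mark time outside the capture space.  Frames are
flagged, never deleted: the matcher skips anchors inside excluded spans and
never gathers evidence across an exclusion boundary.  Re-applying the same
intervals is idempotent (across calls the union is taken); intervals within
one call must be non-overlapping.

## Rule semantics

A condition constrains one joint: the displacement along an axis relative to
an anchor frame must satisfy `abs_ge` / `ge` / `le` against a threshold
strictly within a window ("in under 1 second" is read literally as
elapsed < W).  "Changes at least N" clauses are magnitude comparisons and
"changes less than −N" is signed: the sidestep rule's mirrored branches
cannot both fire under a single signed convention, while its explicit
negative clause demands one, so magnitude-for-positive / signed-for-negative
is the only reading consistent with the published rule set as a whole.  A
joint that is Not Tracked at the anchor leaves the condition unsatisfied
rather than raising — game-play data contains dropouts and the original tool
ran on such data.  Joint-angle conditions (the angle at a joint between the
segments to its parent and first child in the kinematic tree) are accepted
by the grammar for completeness; the built-in rules do not use them.

Matching scans anchors left to right, skipping excluded frames, and grows
the window frame by frame up to the rule's longest condition window,
marking each condition at its first satisfying frame.  A match is declared
at the first frame where the Boolean expression over marked conditions is
true and at least one condition is actually satisfied (an IF-THEN whose
antecedent never fired is vacuously true but must not produce a match by
itself; its consequent's satisfying frame may not precede its
antecedent's).  A failed anchor advances by one frame, so no event can be
skipped over.

Two reporting/resumption choices depart from the most literal reading of
the original workflow description, and both are deliberate:

* **The reported match start is the first supra-threshold evidence frame,
  not the anchor.**  Idle sway sits at the same baseline as the pre-event
  pose, so the earliest anchor from which an event is visible precedes the
  event by up to a full window (1 s for the jump rule).  Anchoring the
  report there would timestamp every jump almost a second early; the first
  evidence frame is where the movement demonstrably is.
* **After a match, scanning resumes one maximal window after the match's
  end frame.**  Any smooth supra-threshold excursion — rise, peak, fall —
  would otherwise re-trigger on its own remaining rise and again on its
  descent, turning one jump into three or four counts.  A refractory of one
  window consumes the continuous movement that produced the match while
  leaving events separated by at least two windows untouched.  This matches
  the original system's observed behaviour of near parity with human counts
  rather than a several-fold overcount.

Both the package matcher and the brute-force test oracle implement exactly
these semantics; the oracle re-derives every match by exhaustive
per-(anchor, end-frame) scans with no shared code.

The `.krt` text format is line-oriented: `RULE <name>`, condition leaves
(`DISP <joint> <X|Y|Z> <ABS>=|>=|<=> <metres> WITHIN <seconds>`, `ANGLE`
analogously), operators `AND` / `OR` / `THEN` with precedence
AND > OR > THEN and parentheses for grouping, `#` comments.  A `#:` comment
attaches a display label to the next condition; the shipped `jump.krt` and
`sidestep.krt` carry the published clause texts verbatim as labels, because
the published table's phrasing is typographically inconsistent ("5cm" vs
"5 cm", "cm" vs "centimetres") and no single template reproduces it.
Unlabelled conditions render through a canonical template.  Thresholds are
serialized with `repr` so files round-trip bit-exactly.

The published sidestep rule's left/right asymmetry (the left-lead branch has
a fourth clause on the trailing right foot with no mirror in the right-lead
branch) is preserved verbatim; whether it was intended is unknowable from
the published material.

## Dual-sensor calibration and fusion

Both sensors are assumed level and at the same height, reducing their
relative pose to a yaw about the vertical plus a translation.  From a T-pose
frame pair the yaw is the signed angle between the two cameras' wrist-right
minus wrist-left vectors projected on the XZ plane; the translation aligns
camera 2's hip centre with camera 1's after rotation (a rotation alone
cannot co-locate two cameras' skeletons; published descriptions mention only
the angle).  The 3D wrist spans must agree to within 10 cm or the
calibration is rejected.  A single designated frame pair is used (the
calibration "sequence" length is unspecified; the API accepts any frame
index).

Fusion pairs frames by nearest timestamp within half a frame period (the
two cameras free-run; bounded skew without resampling), transforms camera 2
into camera 1's coordinates, and merges per joint: coordinate-wise mean when
both are valid with equal state, the Tracked view when states disagree
(Tracked beats Inferred), the valid view when only one is valid, camera 1's
stored value when neither is.  "Valid" means Tracked or Inferred.  Output
frames keep camera 1's clock and orientations, and carry a provenance code
per joint (averaged / cam1_only / cam2_only / fallback_cam1).

## Reliability statistics

ICC(2,1) is computed from the two-way ANOVA mean squares (participants and
sources both random, absolute agreement, single measures), with the
McGraw–Wong F-based 95% CI using Satterthwaite degrees of freedom; the tests
cross-check the estimate against pingouin's independent implementation to
1e-10.  Degenerate inputs (all counts equal) and n < 3 raise rather than
returning a meaningless value.  Interpretation uses the Fleiss bands
(≥ 0.75 excellent, < 0.40 poor, otherwise moderate).  Limits of agreement
use 1.96 literally, not a t quantile.

No canonical formula exists for "percentage agreement" between unequal
counts.  This package uses the mean over participants of
100·min(aᵢ,bᵢ)/max(aᵢ,bᵢ), with (0,0) contributing 100: it is scale-free,
handles unequal counts, and is 100 exactly iff the vectors are identical.
Any comparison against previously published percentage-agreement figures
must treat the definition as reconstructed.

Consensus counts (the raters' 100%-agreement numbers) are an input column:
the discussion that produces them is a human process and is not modelled.

## Synthetic sessions

The generator emulates the two study conditions: a supervised FMS task —
three jumps then twelve sidesteps, six to each side, well separated, no
occlusion (the task was performed cleanly in front of the sensors) — and a
five-minute game-play condition with randomly interleaved events and
tracking dropouts (2 occlusion spans/min by default).

Defaults, chosen once as plausible for 10–15-year-old players and not
revisited: 30 fps; postural sway 5 mm SD (iid Gaussian per joint per frame);
jump amplitude 0.15 m over 0.45 s (half-sine applied to every joint — the
body rises as a whole); sidestep amplitude 0.30 m over 0.6 s (smoothstep
body translation, alternating direction so the player stays in the capture
space) with the lead foot stepping out early and fast (peak excursion 1.5×+
the body translation within 0.25 s, then settling); occlusion spans
overwrite states on 1–3 random joints (Inferred 70% / Not Tracked 30%).
With a second camera enabled, each view is the ground-truth motion (camera
2 rigidly transformed) plus independent Gaussian noise, so per-joint
averaging should reduce the error by ≈ 1/√2.

What the generator does **not** emulate: real inter-child variability in
cadence and countermovement depth, systematic pose-estimation biases
(limb-swap artefacts, depth-dependent noise), correlated multi-joint
dynamics, or movements other than jump and sidestep.  Passing tests
therefore demonstrate that the pipeline is internally correct — the matcher
implements its stated semantics exactly, calibration recovers planted
geometry, the statistics match independent implementations — not that the
specific published thresholds generalise to new children or new games.

## Problem sizes and numerics

The test suite and acceptance script use: 500 random streams (≤ ~90 frames)
for matcher/oracle equivalence; 20 seeded FMS sessions (45 s each) for
exact-count recovery; three 5-minute game-play sessions for
precision/recall; 200 replicated simulations at n = 1000 participants for
ICC recovery (with k = 2 sources the between-rater term is estimated from
only two draws, so single-run estimates scatter with SD ≈ 0.05; the
replicate mean recovers the theoretical value to < 0.02); 4000 simulated
pairs for Bland–Altman coverage.  Angle computations clip cosines into
[−1, 1]; yaw wraps to (−180°, 180°]; ICC confidence bounds are clamped to
bracket the point estimate against floating-point overshoot.

## Known limitations

* Movement *quality* is not assessed; the rules encode minimum standards
  for counting only.
* The original study's per-participant count workbook is not
  redistributable here, so the published ICC values can only be reproduced
  by users who supply `data/s1_rater_system_counts.xlsx` themselves; the
  corresponding acceptance test reports the missing input otherwise.
* Rules are generic across participants; no per-child calibration of
  thresholds is provided.
* Fusion supports exactly two cameras.
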