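# Methods

This note records the scoring model, the conventions the implementation
fixes where the leaderboard definitions leave room, and what the synthetic
fixtures do and do not establish.

## Box geometry and matching

Boxes are 0-based pixel rectangles `(x1, y1, x2, y2)` with a **half-open**
extent: area = (x2−x1)(y2−y1). Half-open arithmetic removes the ±1
ambiguity of inclusive corners and makes box IoU equal, exactly, the mask
Jaccard of the two boxes rasterised onto the pixel grid (property-tested).

A prediction may match a reference of the same class when IoU ≥ 0.25 (the
threshold is deliberately permissive: coarse localisation of an artefact is
already clinically useful). `match_boxes` seats predictions in descending
confidence, each taking its best-IoU eligible reference, with
augmenting-path reassignment so the final one-to-one matching has **maximum
cardinality** (verified against a brute-force assignment oracle on random
small instances). Ties in confidence break by input order, ties in IoU by
reference order — every score is deterministic for a given submission file.
Inside the AP sweep, matching is the standard frozen greedy walk down the
confidence ranking: a precision–recall curve cannot revisit past decisions.

## Average precision and the detection score

AP is the all-point area under the PR curve with the monotone precision
envelope (no 11-point sampling). mAP is the unweighted mean over classes
that have at least one reference box; classes absent from the ground truth
are reported as not-applicable rather than zero, so small fixtures are not
distorted. The leaderboard IoU aggregate is the per-class mean over
reference boxes of the best-match IoU, with unmatched references
contributing 0 (missing an artefact is a localisation failure, consistent
with weighting retrieval highly); the pooled-over-boxes variant is reported
secondarily. Then

    score_d = 0.6 · mAP + 0.4 · IoU,

and a submission is valid only when 0.7 < IoU/mAP < 1.3 (strict
inequalities; mAP = 0 is invalid with an undefined ratio).

## Segmentation metrics and averaging order

Per frame and class we compute pixel DSC, Jaccard, overlap = (DSC+J)/2, F2,
PPV and recall. Averaging is macro–macro: mean over frames, then mean over
the five segmentation classes. The composite score uses the aggregate
values, `score_s = 0.75·[0.5·(F1+J)] + 0.25·F2` with F1 ≡ aggregate DSC;
this identity reproduces, row by row, the published segmentation
leaderboard from its own printed columns (regression-tested to ±1e-4, the
rounding of the inputs).

**Empty-mask convention.** A class empty in both reference and prediction
scores 1 for that frame (perfect agreement on absence); empty-vs-nonempty
scores 0. The convention matters: endoscopy masks are mostly background,
so an all-background prediction earns a substantial s-score — the pixel
imbalance caveat that the published leaderboard itself carries. The
convention value is configurable (`empty_value`) and stated in CLI reports.

## Generalization scoring

dev_g^i gates the absolute difference of per-class mAP between the
in-domain and unseen-domain datasets at a 10 % relative tolerance
(boundary inclusive); dev_g averages over the classes scored in both.
mAP_d = 0 cannot be divided by; the deviation is then defined as mAP_g
(0 when both vanish) and logged. score_g combines the dev_g rank (1/3)
and the mAP_g rank (2/3), ties averaged. We rank mAP_g descending
(rank 1 = highest) so a low score_g always identifies a good generaliser;
the literal ascending ordering is available behind `ascending_map_g=True`
and the choice is stated in report metadata.

## Consensus ensembling

Within a class, boxes from all submissions are clustered by single-linkage
on pairwise IoU ≥ 0.25 (deterministic and order-independent; a greedy
match-against-first variant is available). A cluster's support is the
number of **distinct** submissions contributing at least one box; clusters
with support fraction strictly above `min_fraction` (default 0.5, i.e. a
strict majority) survive, represented by the member with the highest
confidence, ties broken by submission order. Mask consensus is a per-pixel
strict-majority vote. Single-linkage can fuse two same-class reference-like
boxes that themselves overlap at the threshold; this is inherent to
consensus-by-overlap, and the contribution tally exposes which submissions
supplied the surviving representatives.

## Rank statistics

The Friedman test ranks methods within each artefact class (ties averaged)
and uses the tie-corrected chi-square statistic (df = k−1); the degenerate
all-tied grid is defined as statistic 0, p = 1. The implementation is
cross-checked against an independent library routine in the tests. Nemenyi
critical difference CD = q_α·√(k(k+1)/6n) with q_α from the studentized
range at infinite df (validated against published tables);
Bonferroni–Dunn compares each method to a control with
z = ΔR/√(k(k+1)/6n) at α/(k−1). Jonckheere–Terpstra counts increasing
cross-pairs (ties half) over groups in a pre-specified order; because the
group sizes in class-trend analyses are small, the default p-value is a
seeded permutation estimate ((count+1)/(n_perm+1), default 10,000 draws,
exhaustive-enumeration-tested on toys), with the normal approximation as
an option. The consistency ratio uses the sample (n−1) standard deviation
over the mean, making it scale-free. The clinical ranking weighs
accuracy/consistency/efficiency sub-ranks at 0.4/0.5/0.1 and averages tied
final ranks; missing efficiency ranks are imputed with the worst observed
rank + 1. The composition of each sub-rank from component metrics is
config-driven — hardware metadata and exact component recipes vary between
challenges, so the package fixes only the aggregation.

## Synthetic fixtures

The generator reproduces the *statistical structure* of endoscopy artefact
annotations, not their appearance: seven classes with Poisson per-frame
frequencies (specularity ≈ 3/frame; artefact and bubbles ≈ 2; saturation
≈ 1; blur, contrast, instrument ≈ 0.5), Gaussian box-area fractions in
which artefact and bubbles are an order of magnitude smaller than the
frame-scale classes, and an `overlap_rate` (default 0.6) with which a
small-class box is planted inside a large-class box — the colocalisation
that makes those classes hard. Masks for the five segmentation classes are
filled rectangles rasterised from boxes; adequate for metric arithmetic,
not for modelling irregular artefact shapes. Default problem sizes: 50
frames of 256×256 px (≈ 470 boxes), chosen so a full evaluation runs in
well under a second.

The perturbation model jitters each box edge with Gaussian noise, drops and
relabels boxes independently, adds Poisson spurious boxes, and assigns
confidences by a monotone map of the surviving box's IoU with its source
(default 0.2 + 0.75·IoU), so confidence ranking carries genuine signal. A
single seeded generator per invocation makes every fixture bit-reproducible.

**What passing tests show.** Metric identities, matching optimality,
monotone degradation under noise, and consensus behaviour are established
on these fixtures. They do not certify behaviour on real endoscopy frames:
real masks are irregular, real confidence models are miscalibrated in ways
no monotone map captures, and real class frequencies drift between
institutions. Published-leaderboard identities are checked directly on the
embedded printed tables instead.

## Known limitations

- The exact aggregation conventions of the original challenge (AP
  interpolation flavour, IoU macro vs pooled, segmentation averaging order)
  are not public; each report states the convention used here.
- The published clinical ranking depends on unavailable sub-rank recipes
  and hardware metadata; the package reproduces the aggregation given
  sub-ranks, not those tables' exact entries.
- Reproducing absolute leaderboard values (e.g. the all-background
  submission's s-score of 0.5289) requires the secret test annotations;
  the closed-form analogue on synthetic fixtures is regression-tested
  instead.
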