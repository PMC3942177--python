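# Methods

## Masked, locally normalized cross-correlation

The score between a template `T`, its binary mask `M` (pixel count `P`), and
a micrograph window at offset `v` is the Pearson correlation restricted to
mask pixels:

```
num(v) = Σ_M I(x+v)T(x) − (Σ_M I(x+v))(Σ_M T)/P
den(v) = sqrt(Σ_M I(x+v)² − (Σ_M I(x+v))²/P) · sqrt(Σ_M T² − (Σ_M T)²/P)
NCC(v) = num(v)/den(v)
```

Restricting all sums to the mask stops background pixels from diluting the
score; the local (per-window) normalization makes the score invariant to
affine intensity changes of the micrograph, so NCC is bounded in [−1, 1]
regardless of illumination or ice thickness. The template-side factor is
included in the denominator (full Pearson form); where a picker instead
pre-normalizes templates the scores differ only by a per-template constant
scale, but the bounded form is what makes a single threshold meaningful
across templates.

Each window sum is a linear correlation of the micrograph (or its square)
with the mask (or masked template), evaluated by FFT at zero-padded sizes.
The micrograph side is transformed once — forward FFTs of `I` and `I²` —
and shared across every template of the same shape; each template costs two
forward FFTs (of `T·M` and `M`) and three inverse FFTs (cross term, window
sum, window sum of squares). Correlating `K` templates against one
micrograph therefore schedules `2 + 5K` transforms; `fft_op_count` exposes
this accounting and the test suite asserts it equals the instrumented
dispatcher's count over real runs.

### Padding and valid region

Transforms are padded to the smallest 7-smooth size (prime factors in
{2,3,5,7}) at least `image + template − 1` in each dimension, where FFT
libraries are fastest. Padding makes the correlation linear rather than
circular: only offsets where the template lies fully inside the micrograph
are kept (valid region `image − template + 1`), so wrap-around artifacts
cannot occur and any larger smooth padding yields identical scores (a tested
invariant).

### Numerical conventions

- Coordinates are 0-based `(row, col)`; offset `v` addresses the template's
  top-left corner; a pick's center is `offset + template_shape // 2`.
- **Low-variance guard:** where the masked window variance is at most
  `1e−12 ×` the global micrograph variance (per mask pixel), the score is
  defined as 0 rather than computed — flat ice or carbon must not produce
  ±∞ or NaN from a near-zero denominator.
- **Precision:** correlation math runs in float32 by default, which is
  accurate to well under the 1e−4 boundedness tolerance used throughout and
  halves memory and FFT time; a float64 option exists and is what the
  oracle-equivalence tests use, because the windowed-variance subtraction
  cancels catastrophically near flat regions and only float64 can track a
  float64 spatial-domain oracle to 1e−6.
- Masks are strictly binary; interpolated (soft) masks are re-binarized at
  0.5, since the count `P` in the normalization must be a crisp pixel count.

## Rotation series and symmetry

Templates are generated by rotating each base projection about its center in
fixed angular steps (default 4°, which must divide 360; 9° gives nearly the
same picking behavior at less than half the cost and is supported).
Intensity images use bilinear interpolation with zero fill outside the
original frame — the fill never reaches a score because masks shrink-wrap
the particle. Masks are rotated the same way and re-binarized at 0.5; pixels
whose distance from the center is exactly the mask radius sit on the 0.5
boundary and may flip, which is why generated masks are only guaranteed
within 5% of the base mask's area.

A base with n-fold in-plane symmetry contributes rotations over 360/n
degrees; a circularly symmetric base contributes a single template. Template
index `k` enumerates bases in input order and angles ascending — a pure
function of the inputs, never of scheduling.

## Reduction and determinism

Per-template maps merge into global score/index maps by elementwise
max/argmax. Argmax ties are resolved to the **smaller template index**, and
the sentinel −1 (no contribution) loses to any real index. This choice —
equivalent to lexicographic comparison on `(score, −index)` — makes the
merge associative and commutative, so the result is independent of merge
order, reduction topology (sequential "direct" chain vs binary-tree rounds),
worker count and work partitioning, and the whole pipeline is bit-reproducible.
Topologies are simulated in-process as explicit merge schedules with cost
accounting: reducing P partials takes P−1 merges; the critical path is P−1
rounds for direct and ceil(log2 P) for tree.

### Contrast polarity

Cryo-EM particles are usually darker than the background, so the
best-matching template correlates *negatively* at a particle. A plain max
over templates would then select the *worst* rotation at particle locations.
With `polarity="min"` the per-template maps are therefore sign-flipped
before the max/argmax reduction (equivalent to correlating the negated
micrograph) and the global map flipped back afterward, so the global map is
`min_k NCC_k`, the index map is the argmin (best template), and picking
thresholds minima — by default at −0.3.

## Peak extraction and evaluation

Candidates are local maxima of the polarity-normalized map in a
`(2·min_distance+1)²` Chebyshev neighborhood at or beyond the threshold.
They are accepted greedily in descending score order (ties by row, then
column) while suppressing any later candidate within Euclidean distance
`min_distance` of an accepted pick; `min_distance` defaults to half the
template width, matching the particle-diameter intuition. Polarity duality
(`extract(M, max) == extract(−M, min)` with negated threshold), threshold
monotonicity and suppression soundness are tested properties.

Evaluation against reference coordinates uses greedy one-to-one matching by
ascending distance within a tolerance (default half the template width).
Precision, recall, FDR (= 1 − precision), F-measure (harmonic mean) and the
mean matched distance are reported; ROC-style curves accumulate
true-positive counts along the ranked pick list with matches never retracted
(each pick in rank order claims its nearest still-unmatched reference).

## Synthetic data: what it emulates and what it does not

The generator plants two fabricated views on a shared square canvas — a
rectangular "side view" with vertical band texture (2-fold symmetric) and a
circular "top view" with ring texture — rotated by known angles, scaled by a
signed amplitude (negative by default: inverted contrast), at
rejection-sampled centers with a minimum pairwise separation (default: the
template canvas size, so particles never overlap), plus additive white
Gaussian noise. Defaults: 12 particles per 512×512 field, equal side/top
mix, angles on the 4° template grid, amplitude −1, and a noise sigma giving
peak-SNR 25 (`amplitude² · template variance / σ²`), a regime with clearly
visible but non-trivial noise. All randomness flows from one seed;
regeneration is byte-identical.

What passing tests on this generator do **not** show about real data: there
is no contrast transfer function, defocus variation, astigmatism, drift,
radiation damage, structured ice/carbon background, or particle
heterogeneity — the planted projection is exactly the template being
searched for, which is why near-perfect recall at peak-SNR 25 is expected
here and not on micrographs. One realistic behavior does carry over: because
NCC is scale-invariant, smooth noise in empty regions produces occasional
threshold crossings whose rate is independent of noise amplitude, so
precision at a fixed −0.3 cut is well below 1 even at high SNR — as with
real template pickers, false positives are left to downstream
classification. Angle recovery is scored modulo each base's symmetry (side
views modulo 180°; top views are angle-free).

## Parallel execution model

Within a micrograph, one producer thread feeds template indices into a
bounded queue (default capacity 2 × workers; the producer blocks when it is
full, consumers sleep when it is empty) and each worker folds its results
into a private partial map; partials are combined by the reduction module.
Across micrographs, `per_micrograph` partitioning assigns whole micrographs
to workers round-robin, while `per_template` shares each micrograph's
templates among all workers — the latter is preferable when workers
outnumber micrographs. Both modes, any worker count, and both topologies
produce identical outputs; this is asserted byte-for-byte on the emitted
pick files. Distributed message passing is out of scope: the reduction
schedules model cluster topologies as data structures, preserving the
algorithmic content without an MPI dependency. One unreadable micrograph is
logged and skipped without aborting the batch.

## Problem sizes used in the test suite

The suite verifies the engine against a brute-force spatial-domain oracle on
random instances up to 32×32 with templates up to 8×8 (100 seeds, float64),
and runs the full pipeline on 320×320 fields with 48-px templates and a 30°
rotation series (7 templates under symmetry) — sizes chosen so the whole
suite completes in seconds while exercising every code path at full
fidelity; the FFT-scheduling arithmetic is additionally executed at 512×512
with 160×160 templates, the template shape of the full-scale accounting.

## Known limitations

- No CTF modeling or defocus-pair logic; micrographs are picked as given
  after an optional k×k averaging prefilter (default 4×4, reflect boundary).
- Masks must be binary; graded masks are not supported.
- The picker reports one in-plane angle per pick (the winning template);
  out-of-plane orientation is outside its scope.
- GPU execution and real cluster deployment are out of scope by design.
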