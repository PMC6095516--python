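# Methods

`dtrack` reconstructs the 3D trajectory of a single large animal in a
pool from two synchronized, wide-angle video views, and summarizes the
trajectory behaviourally. This note records the models, the defaults
and why they hold, the numerical choices, and what the synthetic test
bench does and does not establish.

## Coordinate conventions

* **World frame**: origin at the pool centre on the water surface,
  x/y horizontal in metres, z positive **downward** (z is depth).
  Cameras sit above the water at z < 0. All zone logic depends on this
  convention; it is fixed here and assumed by every module.
* **Pixels**: 0-based, origin top-left, `u` = column, `v` = row. The
  default principal point (1279/2, 719/2) is the centre of a 0-based
  1280×720 sensor.
* **Pose**: world→camera rigid transform, `X_cam = R·X_world + t`.

## Camera model

Each camera is an ideal pinhole plus polynomial radial–tangential
distortion. Forward projection: transform to the camera frame,
perspective divide (x′ = x/z, y′ = y/z), distort

    x_d = x′(1 + k1 r² + k2 r⁴ + k3 r⁶) + 2 p1 x′y′ + p2(r² + 2x′²)

(symmetric in y), then map through the intrinsics (u = fx·x_d + cx).
Coefficients are stored in the conventional five-element order
(k1, k2, p1, p2, k3). The defaults — focal 654.55 px for both axes and
(k1, k2, p3…) = (−0.33505, 0.12023, 0, 0, −0.02017) — describe the
170° action cameras the tool was designed around; both are plain
config values. The default lens model is monotone (invertible) out to
a normalized radius of about 1.5 (≈56° off-axis), which covers the
whole pool from the default camera placement for targets within about
8 m of the pool centre.

**Undistortion** is fixed-point iteration x ← (x_d − tangential)/radial,
capped at 100 iterations with tolerance 1e−10; non-convergence or a
non-positive radial factor raises an error naming the point. On a grid
of normalized points with r < 0.7 the round trip is accurate to well
below 1e−6.

**Back-projection** of a pixel takes the undistorted normalized point,
forms the camera-frame points at z = 0 (the focal point) and z = 1,
maps both through the inverse pose, and returns the world ray through
them.

**Pose estimation** is RANSAC over Perspective-n-Point solves on the
undistorted (normalized) correspondences:

* samples of six or more points are solved by a direct linear
  transform (SVD of the 2n×12 system, orthogonalization of the
  rotation block);
* the minimal five-point sample is solved by an exhaustive coarse
  orientation search (64 Fibonacci-sphere optical-axis directions × 8
  roll angles; translation is the linear least-squares fit given the
  rotation), keeping the candidate with the lowest normalized residual;
* every candidate is refined by Levenberg–Marquardt on the normalized
  reprojection residuals (rotation parametrized as a rotation vector),
  scored by pixel reprojection error against all points, and the best
  consensus pose is refit on its full inlier set.

Defaults: 200 RANSAC iterations, 5 px inlier threshold, seeded PRNG.
With noiseless correspondences every point is an inlier after the
first sample, so the result is seed-independent up to the refinement
tolerance (~1e−10). At least five landmarks visible from both cameras
are required; non-degenerate (non-coplanar, non-collinear) layouts are
the caller's responsibility.

## Detection (background subtraction)

Per frame: absolute grey difference against a static background model
(per-pixel median of N configurable frames — lighting and wind changes
are handled by re-tuning, not by an adaptive model), masked to the
tracking area; locally adaptive threshold (foreground iff the
difference exceeds the block-local mean minus `offset` **and** is
strictly positive — the strict-positivity clause makes an identical
frame segment to nothing regardless of the offset sign); an optional
per-channel colour gate on the original frame; erosion then dilation
with disc structuring elements; 8-connected components filtered to
[min_blob_area, max_blob_area]; the largest survivor's area-weighted
centroid is the detection, ties broken toward the lowest (v, u).
Absence of a blob is a value ("no detection"), not an error.

Defaults (1280×720): block 101 px, offset −10 grey levels (i.e. the
threshold sits 10 levels above the local mean), erosion 1 px, dilation
2 px, area bounds [200, 50000] px. These are engineering defaults for
the synthetic renderer's blob sizes and must be re-tuned per site; the
block size must comfortably exceed the animal's apparent size or the
local mean inside the blob suppresses it. The colour gate's order
relative to the threshold (logical AND of both) is a design choice;
nothing hinges on it for grey input.

## Reconstruction

1. **Pixel smoothing.** Each camera's centroid series is convolved
   with a Gaussian kernel, default σ = 32 frames (≈1 s at 30 fps),
   truncated at 4σ, reflective boundaries, applied independently per
   contiguous run of valid frames so gaps never bleed. This removes
   centroid jitter before triangulation; no additional 3D-space
   smoothing is applied.
2. **Triangulation.** The two back-projected rays are generically
   skew; the "intersection" is the midpoint of their common
   perpendicular, and the segment length (*gap*, metres) is kept as a
   per-frame quality score. Rays within 0.5° of parallel raise an
   error naming the frame.
3. **Refraction.** If the unrefracted midpoint falls below the water
   surface, both rays are bent at the flat z = 0 interface by Snell's
   law (sin θ_air = n · sin θ_water, azimuth preserved) and the
   midpoint is recomputed on the underwater segments. The default
   index n = 1.4 is an *effective* calibrated value rather than the
   textbook 1.33; it absorbs residual lens/interface effects and is
   configurable. The synthetic projector solves the exact forward
   problem (Fermat path, Brent root-finding on the horizontal crossing
   offset, tolerance 1e−12), so the closed loop recovers submerged
   depths to ~1e−11 m in exact arithmetic.
4. **Outlier removal.** For each coordinate series and for the
   consecutive-frame displacement magnitudes, quartiles are computed
   with linear interpolation between order statistics and frames
   beyond the Tukey **outer** fences (Q1 − 3·IQR, Q3 + 3·IQR) are
   invalidated — only "major" outliers; the inner (1.5·IQR) fences are
   deliberately not enforced. A displacement outlier flags a frame
   only when *every* defined adjacent step is outlying: a single-frame
   spike produces two outlying steps (into and out of it), so the
   spike is removed and its neighbour kept. Fences carry a 1e−9 m pad
   so numerically-constant series (IQR ≈ machine epsilon) are left
   intact. Each invalidation records its cause. The single pass is
   idempotent on data matching its model (isolated spikes over mild
   jitter); it is *not* mathematically idempotent for arbitrary
   inputs, and coordinate fences will cut genuinely bimodal behaviour
   (e.g. one brief deep dive in an otherwise constant-depth session) —
   a limitation inherited from applying session-level fences to
   coordinates. Fewer than 8 valid frames skips the filter with a
   warning.
5. **Gap bridging.** Invalid runs of ≤ 30 frames (1 s) between valid
   neighbours are linearly interpolated and flagged `interpolated`;
   longer gaps stay invalid. Positions outside the plausible depth
   band [−0.5, max_depth + 0.5] m are invalidated before filtering.

## Behavioural analytics

* **Zones.** Depth wins: z > 1.4 m (the shallow shelf's maximum depth)
  is **Bottom** anywhere; otherwise the horizontal point is **Deep
  Area** inside the maximal-depth floor footprint (boundary included)
  and **Shallow Area** outside. Every valid frame gets exactly one
  label; occupancy is reported as frames, minutes (frames/fps/60) and
  percent of valid frames.
* **Speeds.** speed_i = ‖P_i − P_{i−1}‖·fps for consecutive valid
  pairs; frames after a gap carry no speed. Interpolated frames get
  speeds but are excluded from the maximum. The three bands split
  [0, max] into **equal-width thirds** (for a 5.1 m/s maximum: 0–1.7,
  1.7–3.4, 3.4–5.1) — these are range thirds, not rank tertiles; a
  rank-based mode exists behind `rank_tertiles=True`.
* **Rings.** A ring is one complete circuit: the unwrapped azimuth of
  the horizontal position about the ring centre (the deep-area
  centroid by default) accumulating 2π in either direction. Two
  numerical safeguards, both no-ops on clean steady circling: the
  azimuth series of each contiguous valid run is denoised with an
  order-1 Savitzky–Golay fit (window 9; exact for constant-rate
  rotation including the run's edges), and a 2π crossing must be
  confirmed by the median of the following 5 samples. The closing
  frame ends the ring and starts the next, with the angular overshoot
  carried over so k uniform turns yield k equal rings. Spans with mean
  horizontal radius < 2 m are rejected (dwelling near the centre is
  not circling). Rings never span detection gaps. Because a closed
  loop's start–end distance is ≈ 0 by construction, ring "size" is
  reported as both the path length and the start–end distance.
* **Regions.** Time over a named horizontal polygon (trainer station,
  gate) is the count of valid frames whose (x, y) is inside it.

## Synthetic scene generator

The generator is the test bench: real pool footage is large, scarce
and truth-free. It states a fixed world matching the recording setup
the tool targets — a 21 m diameter, 5 m deep pool whose shallow shelf
reaches 1.4 m, deep-area footprint defaulting to a 7 m-radius regular
24-gon, two cameras with the default intrinsics/distortion at 11 m
from the pool centre, 4 m above the water, on opposite sides, pitched
at a point 1 m below the surface at the centre, 30 fps. Motion scripts
are piecewise: constant-rate circles, anchored sinusoidal dives, and
jittered dwells. Ring boundaries, zone labels and speeds are recorded
from the generating equations at sampling time. Projection uses the
exact refracted forward model; seeded Gaussian pixel noise is optional.
Rendering draws an ellipse (default 22×12 px half-axes, +80 grey
contrast on a 120-grey background) at the true projected pixel, with
optional static texture and per-frame noise; frames are single-channel
by default. Everything is deterministic under the scene seed.

`CircleSegment.for_turns` pads the duration by half a second past the
k-th turn so that detectors operating on jittered observations can
still close the final ring.

What a green synthetic test does **not** establish: robustness to real
water glare, ripple, shadows, occlusion, appearance change with depth,
rolling shutter, camera desynchronization, or calibration-landmark
survey error. The renderer's uniform ellipse is far easier than a real
animal; segmentation defaults will always need site tuning.

## Known limitations

* One animal only; no identity handling.
* The flat-interface refraction model ignores waves; the effective
  index partially compensates on average but not per frame.
* Session-level Tukey fences on coordinates can discard genuine rare
  behaviour (see above); causes are recorded per frame so such drops
  are auditable.
* The equal-thirds speed bands depend on the observed maximum, so a
  single fast excursion rescales all bands; the rank-tertile mode is
  stable against this but no longer matches the conventional printed
  bounds.
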