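# Methods

`hyolingual` measures how the tongue base retracts during swallowing from
sparse implanted-marker kinematics: rigid-body bone poses, extrinsic-muscle
length and orientation, regional tongue volumes, oral-cavity volume, EMG
activity, and the event/statistics layer that ties the per-cycle quantities
together. The in vivo measurements this pipeline is designed for are
biplanar-videoradiography marker trajectories at 200 Hz; the package ships a
synthetic-swallow generator with known ground truth so every stage is testable
end to end without any recordings.

## Coordinate conventions and data model

All coordinates are in mm in a cranial anatomical frame: +X anterior,
+Y superior, +Z toward the animal's right. The frame is built from static
landmarks: the palate plane is the least-squares plane through the palate
landmark cloud (so palate landmarks have minimal Y variance), X is the
in-plane projection of the posterior-to-anterior midline direction, and
Z = X × Y. The axis *roles* are anatomically fixed; the *signs* are this
package's convention and are used consistently everywhere, including the
generator. Volumes are computed in mm³ and reported in mL (÷1000).

Missing marker samples are NaN and propagate through every derived quantity;
linear gap interpolation (≤ 5 frames) exists only as an explicit, logged
configuration option and is off by default. Whether marker trajectories
should be low-pass filtered before analysis is left as configuration
(default: none).

## Rigid kinematics

Poses are closed-form least-squares rigid registrations (SVD with a
det = +1 reflection guard) of each bone's marker cluster against its
reference configuration; per-frame residual RMS is reported (for an n-marker
cluster with isotropic noise σ the expected per-marker Euclidean residual is
σ·√(3·(1 − 6/3n))). Mandibular pitch is the Z component of an intrinsic
Z-X-Y Euler decomposition of the pose rotation, signed so jaw opening is
positive; no convention for the decomposition is anatomically canonical, so
the same convention is used by the generator. The gape zero reference is the
frame of minimum gape within the sequence (an intercuspation proxy) unless a
reference frame is supplied. Hyoid protraction/elevation are δX/δY of the
basihyoid centroid relative to a stated reference frame.

Velocities are central differences at the native frame rate (one-sided at the
ends). Precision statistics follow the frozen-specimen protocol: per-animal
SDs pooled as √(mean of squared SDs), and zero-velocity bands of ±2 SD of a
static-trial velocity series.

## Muscle kinematics and tongue dimensions

Muscle length is the Euclidean distance between two attachments (markers or
reconstructed points). The sagittal orientation Θ is measured on the
insertion→origin line projected into the cranial X-Y plane (anterior = 0°,
superior = 90°, posterior = 180°, inferior = 270°); the insertion→origin
direction is chosen so a retracting line of action reads ≈180°, matching the
reported convention, and 135° < Θ < 225° defines "predominantly posterior".
Contraction state is classified per frame from the length velocity (negative
= shortening = concentric when EMG-active; within the zero-velocity band =
isometric; inactive frames are never assigned a contraction state).

Linear tongue dimensions are axis-projected (not Euclidean) distances:
posterior width = Z distance between the posterior lateral markers, posterior
depth = Y distance from the posterior surface marker to the hyoid dorsum,
posterior length = X distance between posterior and middle surface markers.
The anterior constellation uses the same axis-projection scheme (an
operational choice; no alternative is defined for it). Tongue-base length is
the X distance between the posterolateral midpoint and the vallecular marker;
tongue-base depth is operationalized as the Y distance between the posterior
surface and vallecular markers.

## Regional tongue volumes

The tongue is modelled per frame as three primitives delimited by two coronal
surfaces:

1. **Rings.** Each coronal boundary is a closed natural cubic spline through
   four ordered markers (middle ring: middle deep → right → surface → left;
   posterior ring: reconstructed dorsal hyoid → right → surface → left). The
   ordered set is wrapped three full loops (13 knots, chord-length
   parameterization), each loop is sampled at 300 points, and only the middle
   loop is retained, which suppresses the natural end conditions' artifacts.
   A residual end-effect of order 10⁻³ (relative to ring size) remains; more
   wrap loops would shrink it but the three-loop construction is the fixed
   procedure.
2. **Harmonic fill.** Each ring is projected onto its first two principal
   directions; the enclosed planar polygon is triangulated (Delaunay over the
   dense boundary samples plus a hexagonal interior lattice, triangles kept by
   centroid-in-polygon, with an explicit check that every boundary edge
   survived — a practical stand-in for a conforming constrained Delaunay
   mesher); and the x, y, z coordinate functions are obtained by solving the
   cotangent-weight Laplace equation with the ring coordinates as Dirichlet
   data (direct sparse factorization; no iteration tolerance). Negative
   cotangent weights from obtuse triangles are kept as-is (a clamp-at-zero
   variant is available behind a flag). Planar boundary rings therefore fill
   exactly flat, interior values obey the discrete maximum principle per
   coordinate, and a saddle ring (z = xy) reproduces the analytic harmonic
   surface to ~10⁻⁵ at the default densities.
3. **Primitives.** The anterior oral tongue (AOT) is a cone from the middle
   coronal surface to the anterior marker; the posterior oral tongue (POT) a
   deformed cylinder between the two surfaces (matched equal-arc-length ring
   samples joined by a split quad strip); the tongue base (TB) a cone from the
   posterior surface to the vallecular marker. Ring correspondence matches
   the middle-deep marker with the dorsal-hyoid marker and enforces equal
   handedness (auto-reversal is logged). Face groups are flipped as needed to
   produce a consistently wound closed mesh, and each volume is the magnitude
   of the sum of signed tetrahedron volumes of the faces against the
   primitive centroid (origin-independent for closed meshes; an open mesh
   triggers a warning plus a reference-dependence report).

Defaults: 300 ring samples (volumes change < 1% against 150), interior
lattice spacing 2× the boundary spacing (the fill of near-planar rings is
insensitive to interior density; 1× is used where sub-10⁻³ surface accuracy
itself is being validated). Per-frame geometric failures yield NaN volumes
and a logged reason; the series continues. If the vallecular marker is
missing the TB primitive is omitted and the event layer falls back to the
posterior-surface offset rule.

## Oral-cavity volume

The oral cavity is bounded by the hard palate mucosa, the lingual surfaces of
teeth/mandible, the anterior hyoid, and a straight 50-point mylohyoid-raphe
segment from the inferior hyoid pole to the mandibular symphysis. Per frame
the posed landmark clouds are pooled and Delaunay-tetrahedralized; tetrahedra
with circumsphere radius > α are discarded (α = 6, interpreted in mm like all
coordinates) and the remaining tetra volumes summed. Sliver tetrahedra below
10⁻¹² mm³ are excluded before the radius test to avoid numerically infinite
circumradii. The α-circumradius convention reproduces the convex hull as
α → ∞ and is monotone in α.

## EMG

Raw channels (2–10 kHz) are filtered with a 4th-order zero-phase
(forward–backward) Butterworth — 30 Hz high-pass, plus an optional
1000–3000 Hz low-pass for high-rate recordings — full-wave rectified, and
RMS-integrated over non-overlapping 5 ms windows placed by time (partial
trailing window dropped), yielding a 200 Hz envelope aligned with the motion
frames.

The noise threshold is a runs test: across 200 candidate thresholds spanning
the envelope range, the run count of the ordered envelope is compared with a
random permutation's, and the candidate maximizing (randomized − ordered)
runs is selected; the final threshold averages 30 seeded replicates, and is
then applied to the channel's other trials. Within the band that separates
noise from activity the above/below pattern — hence the score — is exactly
constant, so every threshold there is equally optimal; ties are broken toward
the **highest** equally-optimal candidate, i.e. the activity-side edge of the
band, which rejects residual noise crossings (the lowest-tie alternative
degenerates to the noise ceiling and admits them). When activity occupies
much more of a trial than noise, the test input should be narrowed to a
window with roughly balanced durations; this window is a user decision, not
automated. Activity is flagged wherever the envelope exceeds the threshold;
bursts are maximal supra-threshold runs.

## Events and alignment

TBR onset is the frame at which the posterior superficial marker is most
anterior before moving posteriorly; TBR offset the frame at which the
vallecular marker is most posterior after onset (posterior-surface minimum as
the flagged fallback when no vallecular series exists). Extrema are located
on a 5-frame moving-median copy and mapped back to the raw series by a local
arg-extremum within the smoothing window — exact on noise-free traces and
within ±2 frames at the 0.07 mm precision scale. The per-cycle search window
is supplied by the caller (cycle segmentation is upstream of this package);
an extremum on a window edge raises a detection error. The intercuspal phase
comprises maximal intervals (≥ 2 frames) with mandibular pitch velocity
inside the precision zero-velocity band. All aligned quantities are δ-series
relative to the value at TBR onset.

## Statistics

One-sample/paired Wilcoxon signed-rank tests (exact distribution for n ≤ 25
without ties, normal approximation with continuity correction otherwise;
zero differences dropped; ≥ 6 usable pairs required), Bonferroni-adjusted
significance thresholds (α' = 0.05/m), and pairwise-complete Pearson
correlation matrices with two-sided t-based p-values. Cycles are pooled
across animals and treated as independent — a deliberate replication of the
upstream analysis design, noted as a limitation rather than replaced by a
mixed model.

## Synthetic-swallow generator

The generator emulates one swallow gape cycle (1 s at 200 Hz by default):
a rigid cranium; a mandible cluster rotating about a condylar Z axis through
fast close, a 0.1 s intercuspal plateau, slow open and fast open; a hyoid
cluster translating by the programmed protraction/elevation; a 10-marker
tongue constellation (plus reconstructed dorsal-hyoid point) deforming
between its TBR-onset and TBR-offset configurations along smooth ramps; EMG
channels built as Gaussian noise plus noise-modulated bursts time-locked to
the kinematic phases; and static-trial "precision" recordings. Defaults are
the observed swallow magnitudes the pipeline is meant to measure (posterior
surface/deep/vallecular retractions 6.25/4.30/4.08 mm; TB length +3.61 mm;
ΔPOT +0.85 mL; ΔTB +0.65 mL with AOT constant; hyoid 4.23/2.13 mm;
styloglossus −0.76 mm; hyoglossus −4.74 mm; marker noise SD 0.07 mm).

Because the regional volumes are a nonlinear function of the marker
constellation, the volume targets are met by tuning three deformation knobs
against the forward volume model itself: (i) an in-(base-)plane radial
expansion of the posterior ring (tunes ΔTB without touching any programmed X
displacement), (ii) an in-plane scaling of the middle ring (tunes ΔPOT), and
(iii) an axial anterior-marker correction (restores ΔAOT). The dependence is
triangular, so three 1D secant iterations suffice; each must close within 2%
(0.002 mL floor) within 50 forward evaluations or generation fails. Muscle
length targets are realized exactly by virtual intramuscular attachment
points that slide along their (slowly rotating) lines of action. Event
detectability is part of the design: the posterior-surface trace rises with a
non-zero slope into its onset maximum and retraction starts fast
(anticipatory protraction, amplitude 0.29× the retraction target), and the
vallecular trace is V-shaped at offset with a linear post-offset rebound
(0.37× its retraction target) — without such structure the extrema would be
flat and no detector could localize them under measurement noise.

All randomness derives from one seed; two runs with the same seed are
byte-identical. What the generator does **not** emulate: soft-tissue
dynamics or muscle mechanics (it is kinematic, not biomechanical), bolus
interaction, marker dropout/occlusion, correlated or heteroscedastic
measurement noise, within- and between-animal variability, and chew-swallow
sequences (one cycle per trial). Passing closure tests therefore demonstrate
that the *measurement pipeline* recovers known kinematics at realistic noise,
not that real tongues behave like the generator. The posterior ring widens
as it deepens under knob (i); real tongue bases deepen more than they widen.

## Problem sizes

The shipped analyses and checks use one 200-frame cycle per trial, 300-point
rings (120-point rings with a coarser interior lattice in the fast test
fixtures — closure comparisons always use the generator's own
discretization), ~7 000-point oral boundary clouds, 2 kHz EMG over 1 s, and
multi-cycle tables of 8–12 simulated swallows for the statistical layer.

## Known limitations

* The reconstructed dorsal-hyoid landmark is taken as given (the generator
  places it; real data must supply it).
* The TB volume shares its boundary with the moving hyoid, so part of ΔTB
  reflects hyoid protraction — inherent to the regional decomposition.
* The regional model covers the sub-surface marker hull, not the whole
  tongue; absolute volumes are underestimates by construction.
* The mandibular coordinate system is constructed exactly like the cranial
  one from mandibular landmarks; this is an assumption, flagged where used.
* Swallow-vs-chew classification, 2D→3D marker tracking, and image
  segmentation are out of scope; inputs are marker tables, landmark clouds,
  and raw EMG traces.
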