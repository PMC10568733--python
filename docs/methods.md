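# Methods

## Problem and model

`mphspect` evaluates multi-pinhole (MPH) collimator designs for dual-head
brain SPECT. The question it answers is a trade-off: for a fixed dual-head
camera (540 × 400 mm NaI detectors, 3.2 mm intrinsic resolution, 135 mm
radius of rotation, 200 mm spherical field of view), how should the number
of pinholes and the number of gantry projections be chosen so that the
reconstructed image quality — error against ground truth versus noise — is
best for cerebral-perfusion (HMPAO-like) and dopamine-transporter
(TRODAT-like) imaging?

The pipeline is: digital phantom → collimator design → analytical forward
projection with clinical count scaling and Poisson noise → ML-EM
reconstruction → NMSE / COV / SBR / profile metrics → sweep tables and
optimum selection.

## Collimator design

Two families share one layout rule and differ only in the target planar
system resolution R_t at the radius of rotation: the general-purpose design
(R_t = 12 mm, perfusion) and the high-resolution design (R_t = 8 mm,
striatal imaging).

For n pinholes, a centred near-square grid (ties broken wider-than-tall to
match the landscape detector) tiles the detector into one cell per pinhole;
sparse rows get proportionally wider cells so the detector area is fully
used. Each pinhole sits on the collimator plate at the position whose chief
ray (through the FOV centre) pierces its cell centre, and is tilted at the
FOV centre (focused geometry). Its knife-edge acceptance cone is opened as
wide as the cell permits, capped at the angle that subtends the whole FOV
sphere. Because cones are inscribed in disjoint cells, every footprint lies
on the detector and the total projection overlap is below 20% by
construction (both are still verified by a rasterised pixel-counting
oracle).

A single pinhole can view the entire 200 mm FOV sphere without its
footprint spilling off the detector only for very small pinhole counts;
beyond that, each pinhole views a sub-volume and the *system* provides the
FOV. The focal length f is therefore maximised (bisection) subject to the
union of all acceptance cones covering the FOV sphere, sampled on a
quasi-uniform point cloud (Fibonacci directions at four radii plus the
centre). Maximising f maximises the aperture diameter, hence sensitivity,
at fixed resolution. The aperture diameter then follows from the planar
system-resolution formula

    R_sys(b) = sqrt( (d_e (b + f)/f)^2 + (R_i b/f)^2 ),

solved for d_e so that R_sys(ROR) = R_t. This requires f > R_i·ROR/R_t;
for the 8 mm family that floor (54 mm) exceeds the focal length permitted
by joint FOV coverage once the pinhole count reaches ~11, so those designs
are reported infeasible and sweeps skip them with a log entry.

Geometric efficiency uses the standard knife-edge pinhole formula
d_e² sin³θ / (16 h²) summed over pinholes (θ the incidence angle onto the
tilted pinhole plane, h the source–aperture distance). Aperture
penetration, scatter and attenuation are not modelled anywhere in the
package (the analytical study design assumes perfect corrections).

## Forward model

Projection is detector-pixel-driven: for every pose and pinhole, rays run
from each candidate detector pixel centre through the aperture centre, are
clipped to the FOV sphere and the grid bounding box, and sample the volume
by trilinear interpolation at steps of half the voxel size. Sample weights
carry the step length and the local geometric efficiency. Finite system
resolution is modelled as a single detector-space Gaussian per design whose
FWHM equals R_t·f/ROR — the system resolution at the radius of rotation
mapped through the magnification. On a point source at 135 mm this
reproduces R_t exactly (verified through the full projector to 2%); at
other depths the blur is approximate (a fixed-depth simplification of the
distance-dependent response).

The operator is materialised as a sparse matrix composed with the Gaussian
(which is symmetric, hence self-adjoint), so the adjoint used in
reconstruction is exact to floating point. Detector binning defaults to
3.2 mm (the intrinsic resolution). Coarser binning makes the line sampling
of the volume sparser than the voxel pitch and visibly biases sweep
results, so it is not used for the trade-off studies; the
detector-position study uses 6.4 mm binning, where only qualitative
position comparisons are drawn.

Count scaling maps noise-free projections to clinical count levels:
C_s = C_ref · (n_p · S_MPH)/(n_ref · S_LEHR), with the reference clinical
scan fixed at n_ref = 120 views of a parallel-hole collimator of
sensitivity S_LEHR = 0.01%, and C_ref = 5·10⁶ counts for perfusion or
3·10⁶ for striatal scans (guideline-level injected activities). S_MPH is
the design's geometric efficiency at the FOV centre. Poisson noise is then
drawn per pixel with the scaled mean (seeded, reproducible).

## Phantoms

The brain phantom is a parametric ellipsoid surrogate for a NURBS-based
human brain: brain ellipsoid (semi-axes 75 × 90 × 65 mm), white-matter
interior, cortical gray shell, zero-uptake ventricles, two mirrored
striatal ellipsoids; 64³ voxels of 3.125 mm by default, rasterised by
voxel-centre inclusion so uptake ratios are exact. Perfusion mode sets
gray:white = 10:1 with striata at the gray level; striatal mode sets a
uniform background with striatum:background = 10:1 so the striatal binding
ratio SBR = mean(striatum)/mean(background VOI) − 1 equals 9 exactly (the
convention that the *SBR*, not the activity ratio, is 9). Analysis regions:
a 10 × 7 × 9-voxel (630-voxel) uniform background VOI inside white matter
for COV and the SBR denominator, and a 29 × 23 × 17-voxel box around the
striata for striatal NMSE.

What the surrogate does not emulate: cortical folding and regional uptake
variation of a real perfusion scan, anatomical asymmetry, attenuation and
scatter. Passing the sweep tests therefore shows that the *pipeline*
recovers sampling/noise trade-offs for a brain-scale piecewise-constant
object, not that the exact published optima transfer to anatomically
realistic data — the perfusion optimum matches, the striatal optimum lands
one grid step away (9 vs 7 pinholes; see Limitations).

The Derenzo hot-rod phantom packs six 60° sectors of rods (diameters 4.8,
6.4, 7.9, 9.5, 11.1, 12.7 mm) on triangular lattices with centre-to-centre
spacing twice the diameter, wholly inside a 100 mm container. The star
phantom alternates 32 hot/cold wedges of 11.25°. Both are single-slice;
for simulation they are rasterised at 1.5625 mm so the data are not
generated on the reconstruction grid.

## Reconstruction

Plain ML-EM with the multiplicative update x ← x/s · Aᵀ(y/(Ax)),
s = Aᵀ1, uniform unit initialisation inside the imaged support,
zero-sensitivity voxels frozen, 0/0 ratios defined as 0. No subsets,
regularisation or post-filter — image quality is controlled by the
iteration number, so metrics are recorded per iteration. The Poisson
log-likelihood and the count-preservation identity Σ(s·x) = Σy are tracked
every iteration as diagnostics. Full-scale reconstructions use a 200³ grid
of 3.125 mm voxels cropped back to 64³; the desk-scale studies reconstruct
on 32³ at 6.25 mm.

Reconstructions live in scaled-count units, so before NMSE they are
rescaled by one global factor matching total activity inside the analysis
region. Matching inside the region (not over the whole grid) keeps the
comparison insensitive to low-sensitivity build-up near the FOV edge in
sparse-view acquisitions; SBR and COV are ratios and unaffected.

## Experiments and their scales

* **Pinhole × projection sweeps.** For each pinhole count: design,
  simulate (64³ phantom), scale, add Poisson noise (3 seeds), reconstruct
  40 iterations on 32³, record NMSE (whole brain for perfusion, striatum
  box for striatal) and COV (background VOI) per iteration. The optimum is
  the lowest mean NMSE at a matched COV — curves are interpolated at the
  midpoint of their common COV range — falling back to the minimum NMSE
  when the ranges do not overlap; ties break toward fewer pinholes.
  Full-scale budgets (200³, up to 1000/100 noise-free and 80/40 noisy
  iterations) sit behind `paper_scale=True` / `--paper-scale`.
* **Detector-position sweeps.** Noise-free 2/4/6-view acquisitions for
  parallel (H, heads 180° apart) and perpendicular (L, 90°) modes over the
  protocol angle grids (20° start increments for 2 views, 20° rotation
  increments for 4 views, 10° start increments for 6 views), both tracers,
  200 iterations, final-iteration NMSE.
* **Resolution/sampling studies.** Noise-free 2D Derenzo and star
  acquisitions, 40 iterations, 64² reconstruction. A rod sector is
  "resolved" when the mean valley-to-peak ratio over adjacent rod pairs is
  below 0.75 (a configurable operationalisation of the usual visual
  judgement); star angular sampling is scored by counting distinguishable
  hot bars on a circumferential profile.

## Numerical choices

* Rasterisation by voxel-centre inclusion everywhere (no anti-aliasing).
* Ray steps: half the smallest voxel size; trilinear interpolation;
  out-of-grid neighbours dropped.
* Focal-length and acceptance-angle searches by bisection to 0.25 mm /
  fine angular tolerance; FOV-coverage check on 769 sample points.
* EM ratio 0/0 → 0; support threshold 10⁻¹² of the peak sensitivity.
* Orbit angles are exact floats; duplicate angles (mod 360°) are an error.
* Determinism: phantoms are analytic; all noise flows through
  `numpy.random.default_rng(seed)`; identical inputs give bit-identical
  tables.

## Known limitations

* Single fixed-depth Gaussian resolution model (exact at the radius of
  rotation only); no attenuation, scatter or penetration.
* Line sampling of the volume under-samples when detector pixels are much
  coarser than the magnified voxel pitch; keep binning at or below the
  intrinsic resolution for quantitative sweeps.
* The ellipsoid brain surrogate is smoother than a real perfusion
  distribution; it needs less angular sampling, which nudges striatal
  optima toward fewer/adjacent pinhole counts and makes opposing-head
  (H-mode) 2-view acquisitions look relatively better on the whole-brain
  error than they would on folded anatomy (the perpendicular-mode
  advantage at 2 views does appear for the striatal distribution).
* High-resolution designs above ~10 pinholes are infeasible under the
  joint-coverage rule with this detector and ROR; sweeps skip them.
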