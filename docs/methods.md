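# Methods

## Plaque geometry

A plaque shell is a spherical cap of curvature radius `R` whose plan-view
footprint is a disc of diameter `D`.  All notch parameters (`a`, `r1`, `r2`)
and the inactive margin `s` are interpreted as chord/projection-plane
distances, not arc lengths along the cap: this matches the plan-view
photographic procedure the modified values were fitted with, and it makes
circles circles.  Whether the vendor manual defines them in projection or
along the curved surface is not documented; at these cap angles the
difference is a few percent at most and is absorbed by the fitted values.

The cutout construction is fully determined by tangency.  With
`d1 = D/2 − a + r1` the notch circle center sits at `(0, −d1)` (notch along
−y), so its deepest intrusion is at radius `D/2 − a`.  The fillet centers
solve internal tangency to the outer circle (`|c_f| = D/2 − r2`) and
external tangency to the notch circle (`|c_f − c_n| = r1 + r2`) in closed
form; residuals are at machine precision (< 1e−9 mm is asserted).

The cutout *region* is the area enclosed by the tangent boundary chain:

    rim arc across the mouth → fillet arc → notch arc → fillet arc

This one construction covers both plaque families.  For CI types the notch
circle crosses the rim and the chain reduces to (notch ∩ outer) minus the
fillet discs — the fillets round the re-entrant corners as material.  For CO
types the notch circle is interior to the footprint and is reached through a
channel whose side walls are the fillet arcs.  Treating the fillet discs as
removed material instead (a plausible reading of the construction sketch) is
refuted by the certificate data themselves: points that sit inside the
fillet discs of the CO plaques carry full dose in the certificates.

The active region applies the margin `s` both to the rim (`|p| ≤ D/2 − s`)
and to the cutout (distance to the cutout region ≥ `s`), implemented with
exact polygon offsets.  The active layer itself sits on the sphere of radius
`R + t_active` with `t_active = 0.1 mm` standing in for the (unpublished)
encapsulation depth; relative doses are insensitive to its exact value.

## Source physics

Full condensed-history electron transport is replaced by dose-point-kernel
superposition in homogeneous water.  The Rh-106 kernel is generated at
import time, never stored as data:

* allowed-shape beta spectrum, endpoint 3.541 MeV (no Coulomb correction;
  the resulting mean, ≈1.59 MeV, is within ~12% of the nuclear-data mean and
  only the shape matters for relative dosimetry);
* mono-energetic scaled point kernels `F(r/r0)` with a synthetic tabulation
  carrying the canonical features of condensed-history kernels in the
  0.1–3 MeV band (finite origin value, broad maximum near `x ≈ 0.45`,
  extinction past `x ≈ 1.1`), normalized to unit integral and assumed
  energy-independent;
* Katz–Penfold CSDA ranges `r0(E)` in water;
* truncation at 17.7 mm (the endpoint-energy range) and normalization of the
  total-energy integral `∫4πr²k dr` to the spectrum mean.

A bare in-water kernel, however, systematically distorts the surface dose
pattern of a real applicator: it produces an off-axis "horn" of +10–13% on
the inner plateau and multi-millimetre lateral tails beyond the cutout,
because electrons emitted at grazing angles travel far along the 1 mm-depth
shell.  In the physical plaque those electrons must cross the silver
encapsulation window along the slant path.  The standard physics of the
package therefore uses the *encapsulated kernel*: each spectral component is
range-shifted by the water-equivalent slant path of the window,

    d_eff = d + t_we·sec ψ − t_geo ,    t_we = 0.1 mm × 10.49 ≈ 1.05 mm,

with ψ the emission obliquity at the source node.  This is parameter-free
(vendor window thickness and silver density), leaves normal incidence almost
untouched, restores a flat plateau, keeps the central-axis depth dose
monotone, and removes the spurious tails.  The bare kernel remains available
(`default_kernel()`) and is the reference for the pure-superposition
oracles; silver backscatter, shell heterogeneity and the Ru/Rh-106 gamma
component remain unmodeled.

Source nodes are an equal-area tessellation of the cap (rings of equal polar
width, azimuthally split into ~square cells; default cell 0.1 mm) with exact
ring-zone areas as weights, or uniform random samples on the cap by
rejection against the active classifier.  Quadrature is the default so runs
are bit-reproducible; random mode exists to mirror surface-sampling Monte
Carlo sources and for uniformity tests.  At the closest evaluation point
(CAX, 1 mm depth, nearest source 1.1 mm) the 0.1 mm quadrature is converged
to ≈0.05%; a 0.2 mm cell still carries ≈1.7% discretization bias there,
which is why Monte Carlo comparisons use the 0.1 mm reference.

## Certificate comparison and radii calibration

Certificate-style evaluation uses 32 points on four concentric circles
(8 angles, 45° apart) on the sphere 1 mm inside the inner surface, plus the
CAX point; everything is expressed in percent of the CAX dose at 1 mm depth,
and mirror-equivalent angles (45/315, 90/270, 135/225) are averaged
("symmetric folding").  Differences are simulated − reference, in percentage
points; cells whose |difference| exceeds the reference standard deviation
are flagged.

The circle radii are vendor-private.  They are estimated per plaque by
least squares against the reference restricted to the **non-notch columns
(0°, 45°, 90°) only**, so the notch-direction columns remain untouched
validation data.  Two facts anchor the search: circle 3 lies just inside the
active edge and circle 4 beyond the active surface.  Because the relative
dose is radially flat across the inner plateau, circles 1–2 are only weakly
identified by non-notch data; the calibration therefore regularizes all four
radii toward a diameter-proportional template — fractions
(0.35, 0.625, 0.90, 1.25) of the active radius `D/2 − s`, searched within
±(0.15, 0.125, 0.15, 0.20) windows with a quadratic pull (weight 100 %²/mm²)
toward the template center.  On the steep falloff (C3/C4) the data dominate
the prior by orders of magnitude; on the plateau the template does.  The
radii are calibrated once per plaque with the *modified* geometry (the
better model of the physical plaque) and reused unchanged for the official
comparison, so the official/modified discrimination is never fitted.
Every report that uses calibrated radii flags them as this package's
estimate of the vendor coordinates.

With this pipeline at 0.1 mm quadrature the official parameter set misfits
the packaged certificate table by ≈9 percentage points on average
(max ≈37), while the modified set agrees to ≈4 points on average, with the
notch-direction certificate points reproduced within two reference standard
deviations.  The residual modified-set misfit is dominated by a +3–7 point
plateau-level bias of the surrogate against the certificate plateau — the
same sign and comparable size as the full Monte Carlo comparison shows on
those columns — plus detector effects (1 mm scintillator volume, Cerenkov
ratio at the outermost circle) that no dose engine reproduces.

Central-axis tables are normalized at 2 mm depth per the user-manual
convention; tilted film planes are extracted by rotating the sampling plane
about the plaque apex (equivalent to tilting the plaque with the film
fixed); isodose contours are marching squares on the resampled plane.

## Film dosimetry

Only the red channel is used.  The processing order is fixed by protocol:
5×5 median filter (reflected edges) → nod = log₁₀(PV₀/PV) → calibration
inversion; since rank filters commute with monotone per-pixel maps, the
order is protocol fidelity rather than numerical necessity.  The two-term
calibration nod(D) = k₁·D + k₂·Dⁿ is linear in (k₁, k₂) given n and carries
a degeneracy ridge at n → 1 where the two terms collapse; the fit profiles
the exponent (exact linear solve on a fixed n-grid over the bounded range
0.2–3, then a bounded polish) and rejects non-monotone results.  Inversion
uses a dense inverse lookup polished to 1e−10 nod by Newton steps with a
bracketed bisection fallback; out-of-range (saturated) pixels are masked,
not converted.

A consequence of the ridge worth stating: with 1% noise on nod, the
*individual* coefficients k₁ and k₂ are statistically unidentifiable at the
few-percent level (their Cramér–Rao bound is ≈20% at the nine-dose
calibration design), while the fitted response curve is stable to ≈2–3%.
Uses of the calibration only ever evaluate the curve.

Energy independence is assumed (a 6 MV-derived calibration applies to
Ru-106 irradiations).  Lateral scanner response and film-cut edge stress are
not modeled; comparisons should exclude a ~3 mm border.  Synthetic film
scans for testing are produced by the forward model (dose → nod → 16-bit red
pixel value, optional Gaussian pixel noise).

## Eye model and DVHs

The eye is a 24 mm-diameter globe concentric with the plaque curvature
center: sclera (1 mm shell), retina (0.3 mm shell, posterior), cornea
(anterior cap), lens (ellipsoid), macula (small cap near the posterior
pole), optic nerve (1.5 mm-radius cylinder inserting on the notch side) and
a dome-shaped tumor (spherical segment on the inner sclera, default
10 mm base × 5 mm apex height).  These are literature-typical defaults,
declared in the configuration and explicitly **not** patient-specific;
structure masks are implicit-geometry tests on the dose-grid lattice.
DVHs are cumulative volume fractions on a fixed dose grid; the engine is
relative-only, so absolute scaling is by user prescription (e.g. an apex
dose target).  The qualitative clinical finding reproduced by tests: with
the notch toward the optic nerve, the modified (smaller) cutout delivers a
higher nerve mean dose than the official geometry.

## Synthetic data and what passing tests show

All test inputs are generated in code: silhouette masks by rasterizing the
constructed geometry, film scans by the forward optical model, reference
tables for self-consistency tests from the engine itself.  Parameter-recovery
results on these fixtures demonstrate correctness of the estimators under
the model's own assumptions (plan-view projection, exact binarization,
Gaussian noise); they do not certify performance on real photographs with
lens distortion, perspective or segmentation artifacts, which are out of
scope (a user supplies a binary mask).  Likewise the packaged certificate
table is measured data: agreement there is bounded by the surrogate physics
(kernel fidelity, no shell scatter) and by the radii-calibration stand-in,
as quantified above.

## Problem sizes and numerical choices

Standard runs use 0.1 mm quadrature cells (≈14k–50k nodes per plaque),
0.02 mm calibration grid scans, 0.25–0.5 mm dose-grid voxels and 50 px/mm
silhouette rasters; the full four-plaque certificate benchmark completes in
under a minute on one CPU.  Tie-breaks and degenerate inputs: calibration
windows enforce C1 < C2 < C3 < C4 sequentially; fit infeasibilities
(tangency with no solution) are penalized, not raised, inside optimizers and
raised at API boundaries; out-of-range isodose levels return empty
polylines; the kernel is held constant below its first tabulated radius and
zero at/after `r_max`.
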