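# rutheye

Geometry and relative dosimetry of **notched Ru/Rh-106 ophthalmic
brachytherapy applicators** (BEBIG CIA, CIB, COB, COC types).

Asymmetric ruthenium eye plaques carry a cutout ("notch") that spares a
critical structure — optic nerve, macula or lens — adjacent to the tumor.
The notch is parameterized by three tangent circles in the plan view: a
notch circle of radius *r₁* intruding a depth *a* from the rim of the
*D*-diameter shell, and two mirror-symmetric fillet circles of radius *r₂*
tangent to both the notch and the outer circle, which round the cutout
entrance.  The radioactive layer keeps an inactive margin *s* from every
boundary and conforms to a spherical cap of curvature radius *R*.

Two parameter sets ship with the package: the *official* (vendor
user-manual) values and *modified* values refit to photographs of physical
plaques.  The package lets you quantify what that difference does to the
dose:

* **Geometry** — closed-form tangent-circle construction, active-region
  classification, cap areas, certificate-style surface evaluation points
  (`rutheye.geometry`).
* **Notch fitting** — recover (*a*, *r₁*, *r₂*) and pose from a binary
  plaque silhouette by constrained least squares (`rutheye.notchfit`).
* **Dose engine** — relative dose in water from the uniform active-surface
  beta source by dose-point-kernel superposition,
  D(t) = Σᵢ wᵢ·k(|t − qᵢ|), with deterministic equal-area quadrature or
  uniform random surface sampling.  The default physics augments the
  spectral Rh-106 kernel with slant-path filtering by the 0.1 mm silver
  encapsulation window (`rutheye.kernels`, `rutheye.dose`).
* **Evaluation** — certificate comparison tables with symmetric folding,
  measurement-circle radius calibration, central-axis depth tables, tilted
  plane extraction, isodose contours and profiles (`rutheye.evaluation`).
* **Film dosimetry** — net optical density nod = log₁₀(PV₀/PV),
  two-term calibration nod(D) = k₁·D + k₂·Dⁿ, and scan-to-dose-plane
  conversion (`rutheye.film`).
* **Eye model / DVH** — a simple parametric (not patient-specific) eye with
  ocular structures, structure mean doses, tumor apex dose and cumulative
  DVHs (`rutheye.eye`).

## Worked example

Compare both parameter sets of the CIA plaque against the packaged
certificate-average surface-dose table (percent of the central-axis dose at
1 mm depth; measurement-circle radii calibrated on the non-notch columns):

```
$ rutheye compare-surface --plaque CIA --sets official,modified --cell 0.1
CIA official: mean |diff| = 6.02, max |diff| = 16.98 (radii [2.59, 4.41, 6.36, 8.31]; ...)
CIA modified: mean |diff| = 2.22, max |diff| = 5.59 (radii [2.59, 4.41, 6.36, 8.31]; ...)
```

The official notch parameters miss the certificate values by 6 percentage
points on average (17 points at worst, in the notch direction, where the
official cutout is too large); the modified parameters agree to about 2
points — the same discrimination seen across all four plaque types.

The same from Python:

```python
import rutheye as re
from rutheye.kernels import encapsulated_kernel

kernel = encapsulated_kernel()                    # Rh-106 kernel + window
ref = re.load_reference()                         # certificate averages
model = re.build_plaque(re.get_params("CIA", "modified"))
nodes = re.make_nodes(model, resolution=0.1)      # equal-area quadrature
radii = re.calibrate_radii(model, kernel, nodes, ref[ref.plaque == "CIA"])
table = re.surface_table(model, kernel, nodes, radii, ref[ref.plaque == "CIA"])
print(table.summary())   # {'mean_abs_difference': 2.22..., 'max_abs_difference': 5.59...}
```

Other entry points: `rutheye geometry`, `rutheye fit-notch`,
`rutheye simulate`, `rutheye cax-table`, `rutheye film-calibrate`,
`rutheye film-convert`, `rutheye dvh`, `rutheye make-fixtures` (synthetic
test inputs).  See `docs/methods.md` for the physics, calibration design and
known limitations.

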