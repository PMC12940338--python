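# paleomorph

Quantitative morphometrics for skeletal and dental remains, written for
biological anthropologists who need the standard measurement pipelines —
long-bone cross-sectional geometry, micro-CT dental tissue proportions,
enamel-thickness mapping, binary-trait clustering, and craniometric
ordination — as reproducible, phantom-validated Python code rather than
a chain of GUI tools.

Every analysis stage has a matching synthetic generator with closed-form
ground truth, so the whole pipeline is testable end to end without any
fossil data.

## What it computes

**Cross-sectional geometry** (`paleomorph.csg`). For a binary cortical
section with pixel spacing *s*: total subperiosteal area TA (outer
contour including the medullary cavity), cortical area CA,
%CA = 100·CA/TA, centroidal second moments of area

    Ix = Σ[(y − ȳ)²·s² + s⁴/12],   Iy = Σ[(x − x̄)²·s² + s⁴/12],

the product moment Ixy, principal moments Imax/Imin (eigenvalues of the
area-moment tensor), the principal-axis angle, and the polar moment
J = Ix + Iy. Sections are taken at the standard 20/35/50/65/80% levels
of total bone length; the Martin pilastric and platymeric indices
(100·AP/ML) summarize external shaft proportions.

**Dental tissue volumetrics** (`paleomorph.dental`). From a labeled
(or HMH-thresholded grayscale) tooth volume with user-supplied cervical
and bifurcation planes: tissue volumes Ve, Vcdp, Vpc, Vc, Vcervix,
Vbranch, Vt; the EDJ surface SEDJ; average and relative enamel thickness

    3D AET = Ve / SEDJ (mm),   3D RET = 100 · AET / Vcdp^(1/3),

the coronal dentine-and-pulp share 100·Vcdp/Vc; and the volumetric
bifurcation index VBI = 100·Vcervix/(Vcervix + Vbranch) with its Keene
taurodontism class (cyno/hypo/meso/hypertaurodont at 25/50/75% bands).
Lateral-crown variants (LVe, LSEDJ, 3D LAET, 3D LRET) exclude everything
above the occlusal basin plane, so worn crowns remain measurable.

**Mesh thickness maps** (`paleomorph.thickness`). The shape diameter
function: rays cast in a cone about each vertex's inward normal, outlier
rays trimmed, the rest averaged with angle weights — a per-vertex local
diameter rendered on a dark-blue-to-red scale.

**Trait clustering** (`paleomorph.clustering`). Mismatch distance
d(i,j) = (#10 + #01)/(#traits observed in both), dummy-trait exclusion,
and WPGMA dendrograms (on squared distances by default) with
deterministic tie-breaking, cophenetic distances and Newick export.

**Craniometric morphospace** (`paleomorph.morphospace`). PCA on the
correlation matrix of a 23-variable cranial battery (eigenvalues sum to
p), KMO sampling adequacy from anti-image partial correlations,
Bartlett's sphericity test (df = p(p−1)/2), coefficients of variation,
and per-group confidence ellipses on score planes.

## Worked example

```
$ python examples/dental_tissue_metrics.py
whole-crown metrics (measured vs closed form):
  Ve          189.49      189.36
  Vcdp        261.64      261.80
  ...
  SEDJ        158.18      157.08
  3D AET  1.198 mm   3D RET 18.73   %Vcdp 58.0
  VBI 55.7% -> mesotaurodont
occlusal basin plane at z = 5.32 mm (dimple floor constructed at 5.40 mm)
```

The phantom is a hemispherical enamel cap (1 mm thick) over a 5 mm
dentine hemisphere on a bifurcating-canal root, voxelized at 0.15 mm.
Measured volumes sit within 2% of the sphere/cylinder closed forms and
the EDJ surface within 3% of 2πR²; the VBI of 55.7% falls in the
mesotaurodont band. The other scripts in `examples/` demonstrate the
diaphyseal profile, the SDF thickness map, trait clustering, and the
craniometric PCA in the same build-phantom / measure / compare style.

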