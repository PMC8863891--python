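# Methods

## The model

`dryskull` implements the dry-skull estimation chain for jaw biomechanics
in extinct archosaurs, together with a strain-limited gape model.

**Muscle force.** A reconstructed muscle's force capacity is proxied by its
physiological cross-sectional area, estimated as volume over length:

    CSA  = V / L                      [mm^2]
    Fmus = CSA × σ × c                [N]

with σ the isometric muscle stress (default 0.3 N/mm², the standard
dry-skull value for vertebrate skeletal muscle) and c a correction factor
(default 1.5) compensating for force underestimated by ignoring
architecture such as pennation. Pennation is *only* represented by this
scalar; fibre architecture is not modelled. All adductors are assumed
simultaneously and fully active. With the `bilateral` flag (default on)
forces are summed over both sides of a symmetric skull, i.e. doubled, once,
at this stage — never again downstream.

**Resultant force.** The component of Fmus that actually adducts the
mandible is obtained by resolving the line of action against the
dorsoventral axis through its sagittal (α) and coronal (β) insertion
angles:

    Fres = Fmus × cos α × cos β

Angles are measured between the vertical axis and the projection of the
insertion→origin vector onto the sagittal or coronal plane. Signs are
folded away (only cosines matter); an angle of 90° means a horizontal line
of action, which cannot adduct and is rejected.

**Bite force.** The mandible is a third-class lever about the jaw joint:

    Fbite = Fres × L_in / L_out

with the inlever the joint→insertion distance and the outlever the
joint→bite-point distance. Both are straight-line 3D distances; callers
wanting sagittal-projected levers project their landmarks first. Per-muscle
contribution percentages are identical at every bite point because the
common outlever cancels; the package therefore reports a single
contribution column. Mechanical advantage at a bite point is defined as
ΣFbite/ΣFres — the Fres-weighted mean of the per-muscle lever ratios — not
a single lever ratio.

**Gape limits.** Jaw opening is rigid rotation of the mandible about the
line through the two jaw-joint centres (for a single midline joint, a pure
mediolateral axis through it). Each adductor is reduced to two straight
cylinders joining the anteriormost ("1") and posteriormost ("2") extents of
origin and insertion; curved wrapping paths are deliberately not modelled
during opening because their stretch cannot be tracked objectively.
Cylinder lengths at the resting gape (default 5°, the posture of the
reconstruction) define strain 1.0. The jaw opens in 0.5° increments; the
optimal and maximum gape limits are the first sampled angles at which any
adductor cylinder reaches 130% and 170% of resting length — the
length–tension bounds of sarcomere cross-bridge overlap. Detection is on
the sampling grid, first frame at-or-above threshold, with no sub-step
interpolation (this mirrors keyframe-based animation workflows; a
convention of last-frame-below would differ by one step). The depressor
(mDM) shortens during opening and never limits gape; its elongation at the
resting posture relative to its shortest (maximum-gape) state is reported
as a post-hoc plausibility check against the same 1.7 ceiling.

The opening sense is auto-detected as the rotation sense that lengthens the
adductors on average under a 1° probe; geometry where neither sense does
(e.g. an insertion diametrically opposite its origin) is rejected with an
instruction to set `opening_sign` explicitly.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `stress_sigma` | 0.3 | N/mm² | standard isometric stress for vertebrate skeletal muscle |
| `correction_factor` | 1.5 | — | conventional dry-skull correction for unmodelled architecture; 1.0 gives uncorrected forces |
| `bilateral` | on | — | skulls are modelled as symmetric; per-side values = half |
| `resting_gape` | 5 | deg | small open angle at which muscle lengths are unstrained |
| `step` | 0.5 | deg | opening-cycle sampling increment; limits are grid multiples |
| `StrainLimits.optimal` | 1.3 | — | upper strain of optimal tension |
| `StrainLimits.maximum` | 1.7 | — | strain at which tension fails |

## Numerical choices

- Mesh volume uses the divergence theorem (signed tetrahedra against the
  origin), orientation-normalised by absolute value. Closedness is
  *enforced*, not repaired: every undirected edge must appear exactly twice
  with opposite winding, and violations name the offending edges.
- All computation is in full double precision; printed-style rounding to
  one decimal happens only at the reporting edge.
- Ties in limit detection (several cylinders crossing on the same frame)
  report all crossing cylinders, smallest id first.
- A zero-force muscle set yields an all-zero bite table with contributions
  set to 0; mechanical advantage is then undefined and raises.
- `LeverSet` rejects non-positive levers and outlevers that do not strictly
  decrease anterior→posterior for the standard three bite points;
  `lever_lengths` itself will happily measure 0 for an insertion at the
  joint (measurement and transmission have different contracts).

## The synthetic generator

`make_taxon` emulates exactly the statistics the chain consumes: a
bilateral jaw (joints ±30 mm off the midline by default, skull length
150 mm, matching a mid-sized oviraptorid), eight adductor cylinder pairs
plus one retroarticular depressor, three palatal bite points with
outlevers decreasing anterior→posterior, and per-muscle volumes *solved*
from target forces so the full pipeline recovers the targets to machine
precision. It does **not** emulate: anatomical muscle shapes, curved
paths, bone collision, asymmetry, or measurement noise. Passing round-trip
tests therefore demonstrates the chain's internal consistency and
correctness of the arithmetic, not robustness to real measurement error.
`make_planar_gape_model` builds the degenerate single-cylinder sagittal
jaw whose strain obeys the law of cosines
`l(θ)² = r_o² + r_i² − 2 r_o r_i cos(φ₀ + θ − θ_rest)`, so every
strain-limit crossing is analytically invertible — this is the oracle the
gape scan is validated against. `make_muscle_mesh` emits closed n-gon
prisms whose enclosed volume is solved exactly, rigidly re-posed per seed.

## Reference tables and their reproducibility

The package ships the published per-muscle measurement and force tables,
lever arms, bite-force tables, mechanical advantage and gape summaries for
*Incisivosaurus*, *Citipati*, *Khaan* and *Conchoraptor* as plain CSVs
(`dryskull.fixtures`), exactly as printed (0.1-unit precision). Two facts
about these tables, established by recomputation, shape the tests:

1. **Printed inputs are rounded.** Forces recomputed from the printed
   volumes/lengths/angles deviate from the printed forces by up to ~0.4 N
   for the largest muscles (the 0.05-unit input rounding propagates as
   roughly F×0.05/L). Whole-table reproduction holds to ~0.3% at worst in
   the sums for three taxa.
2. **The *Citipati* bite table embeds unprinted levers.** Its printed
   per-muscle bite forces imply inlevers uniformly 0.8–2.2 mm shorter than
   the printed ones; recomputing its totals from the printed inputs
   therefore lands ~3.4% high at every bite point. The other three taxa
   close to <0.1%. Comparisons involving the *Citipati* bite table are
   annotated accordingly in the tests.

The published gape angles (25.0°/49.5° etc.) depend on attachment
coordinates available only in the study's deposited 3D scenes, not in the
printed tables; they ship as fixture metadata, and the gape scanner is
validated against the analytic planar oracle instead.

## Known limitations

- No palinal (anteroposterior sliding) jaw motion; rotation only.
- No muscle force–length or activation dynamics beyond the two strain
  thresholds; no bite-point reaction-force decomposition.
- Mesh repair is out of scope; open meshes are an error by design.
- Rhamphotheca (beak) geometry, which would shift bite points and
  mechanical advantage, is not modelled.
- Surface areas for cross-taxon scaling are caller-supplied; the package
  only measures a cranium mesh's area if one is explicitly provided.

## Problem sizes

The test suite and the reproduction script run entirely at desk scale: 4
taxa × 8 muscles × 3 bite points for the force chain, 200 randomised
planar jaws for the gape oracle, icospheres up to subdivision 4 (~5k
faces) for volumetrics. A full run takes well under a minute.
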