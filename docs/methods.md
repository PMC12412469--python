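# Methods

## The model

`hector` scores steric complementarity between protein surfaces through a
compressed, rotation/translation-invariant representation of local surface
shape, and uses it to retrieve and align candidate binding scaffolds from a
fingerprint database.

**Dot surfaces.** A molecular surface is discretized as one dot per triangle
of a triangulated surface, placed at the face centroid and carrying the
outward unit face normal and the face area. The working density is ~20
dots/Å². Structures can be surfaced by ingesting an externally triangulated
mesh or by the built-in fallback: a Gaussian atomic density (radii dilated by
the 1.4 Å probe) is sampled on a regular grid, the level-1 isosurface is
triangulated by marching cubes, and vertices are eroded back along the
analytic density gradient by the probe radius. Dilate-then-erode approximates
rolling a probe over the van der Waals surface; the default grid spacing
(0.5 Å) is calibrated so the realized dot density lands near 20 dots/Å².
Erosion directions come from the analytic gradient rather than mesh vertex
normals because the latter crumple under strong erosion (high-curvature
regions); residually inverted triangles are re-oriented against their dilated
parent face.

**Patches and fingerprints.** A patch is the set of dots inside a cylinder
erected on a center dot's normal: radial distance < `r_max` and |axial
offset| < `h_max`/2, both strict. Member dots in the local frame (origin at
the center, z along the normal) are projected to cylindrical coordinates
(r, θ, l) with l = k·z; integrating θ out by histogram accumulation onto an
(r, l) grid yields a map that cannot see rigid motion or the arbitrary local
x/y choice. k = +1 (*forward*) fingerprints database subjects; k = −1
(*inverse*) fingerprints query epitopes — an inverse map is the fingerprint of
the patch's ideal steric complement.

Two parameter generations are shipped as presets:

| | r span (Å) | l span (Å) | res (Å) | bins | map freq | dot skip | post |
|---|---|---|---|---|---|---|---|
| v0.1 | [0, 12) | [−6, 6) | 0.4 | 30×30 | 1:40 | 1:8 | bilinear blur |
| v0.2 | [0, 10) | [−10, 10) | 0.2 | 50×100 | 1:5 | 1 | radial fade, 0.5 Å inflation |

The v0.2 radial fading multiplies radial bin i by the logistic weight
w(i) = 1/(1 + exp(slope·(i + 0.5 − fade_radius))) with fade radius 40 bins
and slope 0.3: ~1 at the patch center, exactly ½ at the fade radius, decaying
at the rim. The exact functional form behind the published
"fade radius / slope" pair is not uniquely determined; this logistic-on-bin-
index choice is a documented default. Surface inflation (0.5 Å along each
dot's own normal) absorbs coordinate uncertainty and is applied to both query
and subject sides before mapping.

The v0.1 bilinear blur is a mass-conserving local average: each bin keeps
half its mass and shares the rest equally with its four edge neighbours,
with reflecting boundaries. This preserves constants and total mass to
machine precision and spreads an impulse over at most its four neighbours;
it is one of several kernels consistent with the loose published description
of the interpolation step (which v0.2 dropped entirely).

**Binning conventions.** Half-open bins [i·res, (i+1)·res); l shifted by
+h_max/2 so bin 0 starts at −h_max/2. Inverse maps are binned as the exact
axial mirror of forward binning. For every dot not sitting exactly on a bin
boundary this equals direct binning of −z, and it makes the inverse/forward
duality exact bin-for-bin — which matters because the patch center (z = 0)
always sits on a boundary when the axial bin count is even. For the same
reason the whole-surface mapper forces the center dot's local coordinates to
exact zero: otherwise matrix-product round-off would decide a boundary bin
and break exact translation invariance.

**R-factor.** Complementarity between a forward subject map F and an inverse
query map I:

* first generation (v0.1): R = Σ |F/ΣF − I/ΣI| — an L1 metric on
  sum-normalized maps; 0 for identical-up-to-scale maps. The typeset source
  formula is ambiguous; the crystallographic reading Σ|F−I|/ΣI is available
  behind a flag.
* second generation (v0.2): R = −(1/N)·Σ (2FI + C)/(F² + I² + C), C = 10⁻⁴.
  Every term lies in (0, 1] and equals 1 iff the two entries match, so
  R ∈ [−1, 0) with −1 exactly iff F = I. The published formula is the
  positive overlap; it is negated here so *lower is better* in both
  generations, matching all cutoff conventions (e.g. R_avg < −0.82).

All reductions run in 64-bit; the database stores maps in 32-bit.

## The search

Given two inverse query maps separated by d_q, the funnel is:

1. **candidate selection** — top 5% lowest-R subject maps per query (of the
   whole multi-structure database; per-structure mode by flag), or a fixed
   lowest-N count;
2. **pair assembly** — same-structure candidate pairs with
   | ‖c_i − c_j‖ − d_q | ≤ tol (default ±0.01 Å);
3. **average R-factor cutoff** (default −0.82, disable with `None`);
4. **clique alignment** — Kabsch superposition of the 4-point clique
   {both centers, both normal endpoints at length L} onto the query clique;
   RMSD cutoff 0.5 Å. L (default 1 Å, or d_q/2 in "spacing" mode) rescales
   the orientation weight relative to spacing;
5. **ranking** by pair score 3·R_avg + RMSD, ascending, with lexicographic
   (source, i, j) tie-breaks everywhere so results are bit-reproducible;
6. optional **structural screening** of each aligned pose: occupancy grids at
   1 Å voxels (voxel centers inside any van der Waals sphere), clash = count
   of doubly occupied voxels (cutoff 20, i.e. ~20 Å³ of interpenetration —
   calibrated so a 5 Å backbone overlap of two helices fails), and
   interfacial residue count = subject residues with Cα within 8 Å of any
   target atom (minimum 25).

The distance filter runs before the R_avg cutoff; the final survivor set is
order-invariant, order only affects cost. A sequential variant (the
first-generation protocol) takes the lowest-50 subjects for the first query
and pairs each with every same-structure subject inside a ±3 Å band,
scoring the second query on those.

Three-query searches run all C(3,2) pairwise combinations independently.

## Synthetic fixtures and the benchmark

`make_split_pair` cuts a sphere of radius `size` (default 14 Å) by a seeded
smooth height field z = f(x, y) (a sum of Gaussian bumps, peak slope
bounded; steeper cuts are rejected). Both halves carry their spherical shell
plus the *same* interface sample, so interface dots coincide exactly with
antiparallel normals: exact steric complements with known correspondences.
Returned correspondences are the *certified core* — interface dots at least
10.5 Å from the interface rim, whose 10 Å patches see only complementary
surface. Nearer the rim the halves' outer shells enter the patch cylinder
and dilute the match (measured R-factor drifts from −0.95 at the center to
−0.2 at the rim); those dots still coincide but are not certified. At
default settings the subject half carries ≈7,300 forward maps, inside the
range where the retrieval benchmark is meaningful yet one case runs in tens
of seconds on one core.

The benchmark mirrors the split-protein protocol: 10 query maps are chosen
on half A among dots within 1 Å of half B, restricted to the interface
*interior* (at least ~one patch radius from the interface boundary —
boundary patches see the exterior shell inside their cylinder and carry a
diluted signal) and spread by farthest-point sampling with a seeded start.
All 45 query pairs run the two-vs-all search without hard cutoffs, and a
retrieved subject pair is a true positive when both its centers land within
3 Å of the corresponding query centers *in the shared lab frame* — split
fixtures, like split-protein crystal fragments, keep both halves in one
frame. A transported mode (subject centers mapped through the hit's
alignment transform first) exists for cross-frame use but is deliberately
not the benchmark default: the clique alignment places subject centers onto
query centers by construction, so after a tight RMSD cutoff the transported
3 Å test is nearly always satisfied and measures pose self-consistency, not
retrieval of the correct region. The enrichment factor per query pair is

EF = (n_correct_in_top100 / 100) / (n_possible / n_pairs_within_band),

with ordered same-structure pairs in both denominator counts; a case reports
the mean over pairs where EF is defined. The random-score null replaces all
R-factors with uniform draws *and* zeroes the RMSD weight (a geometric
residual is signal, not noise), skipping alignment; its expected EF is 1
provided the assembled pool exceeds the top-100 depth, so the null check
widens the distance band accordingly.

**What the fixtures do and do not show.** The split solid gives exactly
complementary, noise-free interfaces with generic dot positions — ideal for
verifying the mapping algebra, the retrieval funnel, and rank statistics.
It does not emulate atomic texture, chemical complementarity, surface
reconstruction error, or the irregular interfaces of natural complexes;
passing here shows the machinery concentrates true geometric complements at
the top of the ranking, not that any particular protein pair will dock.

**A known limitation of EF on these fixtures.** The 0.5 Å inflation moves
the two halves' interface dots in opposite directions, which offsets a true
subject pair's spacing from the query spacing by up to a few tenths of an Å
on a curved interface. With the thin ±0.01 Å band this starves some query
pairs of any assembled hit in the noise-free case, while *added* coordinate
noise repopulates the band with coarse hits that the 3 Å true-positive rule
accepts — so EF can paradoxically rise with moderate noise even though the
underlying complementarity signal degrades strictly monotonically (mean
true-pair R −0.976 → −0.722 from 0 to 2 Å of smooth deformation). Signal
degradation is therefore property-tested on the true-pair R-factor, not on
EF.

Coordinate noise for that property is modelled as a smooth random
displacement field (long-wavelength cosine modes at a given RMS amplitude),
i.e. correlated conformational-type error; per-dot white jitter is a
different regime — it blurs the density maps themselves.

## Numerical choices

* Strict inequalities at patch boundaries; half-open bins; assertions (not
  clipping) for dots outside the map span.
* Candidate counts: exactly ⌈fraction·N⌉ (or min(count, N)); all ties broken
  lexicographically on (score, source id, patch index).
* Kabsch via SVD with determinant correction (proper rotations only);
  collinear 4-point cliques are flagged degenerate, with the RMSD still
  returned. The test suite cross-checks against an independent Horn
  quaternion oracle.
* Whole-surface fingerprinting is chunk-vectorized (256 centers at a time)
  and agrees with the per-patch route except for dots exactly on boundaries,
  which generic surfaces do not produce.
* HDF5 databases are written with object-time tracking disabled and sorted
  source order, so identical inputs give byte-identical files; one file holds
  one parameter set, enforced by a parameter hash.

## Problem sizes

Defaults used by the test suite and the acceptance script: split solids of
radius 14 Å at 20 dots/Å² (≈7,300 subject maps per case, 10 cases), a
radius-12 Å sphere for throughput arithmetic, radius-4 Å spheres for
invariance checks, 500-map random databases for the funnel oracle, and 100
null-model repetitions. These sizes were chosen so each property is measured
on a fixture large enough to be in the intended operating regime while a
full run stays in the minutes range on a single core.
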