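# Methods

## Scope and model structure

The package treats a vascular network as a geometric graph: nodes with 3D
positions (µm) and segments with a mean lumen diameter and a centerline
arc length. Four model layers build on it:

1. steady-state blood flow (pressures, flows, hematocrit, viscosity),
2. intravascular oxygen transport on the converged flow field,
3. voxel-grid morphometry (distance, length-density and surface-density maps),
4. phenotype statistics (niche classes, heterogeneity indices, clustering).

Internal units are µm, mmHg, µl/s, cP and s throughout; conversions to SI
or reporting units happen only at I/O boundaries. The Poiseuille
conductance constant is derived from exact unit algebra
(1 mmHg = 133.322387415 Pa), so closed-form checks agree with SI
arithmetic to rounding.

## Blood flow

Each segment carries Hagen–Poiseuille flow; mass conservation at the
junctions yields a weighted graph Laplacian solved sparsely (Dirichlet
pressures at boundary nodes, optional Neumann flow injections for
networks with measured boundary data). Assumptions: steady state, rigid
vessels, blood as an effective single-phase fluid per segment whose
apparent viscosity carries all non-Newtonian behavior.

Microvascular rheology uses the standard empirical closed forms, with all
coefficients in `RheologyParams` so alternates can be swapped:

* **in-vivo apparent viscosity** µ(D, H_D): relative viscosity at
  H_D = 0.45 of `6·e^(−0.085D) + 3.2 − 2.44·e^(−0.06·D^0.645)`, a shape
  exponent C(D), and the wall-layer factor (D/(D−1.1))² applied as in the
  in-vivo formulation. Strictly increasing in H_D; at H_D = 0 it reduces
  to plasma viscosity times the wall factor.
* **Fahraeus law** for tube hematocrit: H_T/H_D = H_D +
  (1−H_D)(1 + 1.7e^(−0.415D) − 0.6e^(−0.011D)); the ratio is clamped at 1
  (the fitted form exceeds 1 only below ≈2.6 µm, outside the physiologic
  range of this model).
* **phase separation** at diverging bifurcations: the logit law with
  A = −13.29[(D_α²−D_β²)/(D_α²+D_β²)](1−H_D)/D_f, B = 1 + 6.98(1−H_D)/D_f,
  X0 = 0.964(1−H_D)/D_f. The complementary daughter receives the
  remaining red-cell flux, so conservation is exact by construction.
  Junctions with more than two outflows apply the bifurcation law
  recursively over flow-ranked daughters, the "rest" pool entering with
  the root-mean-square of the remaining diameters.

Hematocrit is propagated in topological order of the flow digraph, which
is acyclic because pressure strictly decreases along flowing segments; a
fixed-point sweep exists as a fallback for degenerate (exactly tied)
pressures. At converging junctions the feed hematocrit is the
flux-weighted mixture and the effective feeder diameter the flux-weighted
mean of the inflow diameters (the law needs a single feeder diameter; the
choice is ours and is documented here).

The outer loop alternates µ(H_D) → pressure solve → phase-separated H_D
with under-relaxation 0.5, up to 200 iterations, tolerance 10⁻⁴
(relative for pressure, absolute for hematocrit). After convergence one
final µ → (P, Q) → H_D pass makes the reported hematocrit exactly
consistent with the reported flow field, so red-cell conservation holds
to machine precision on the output.

**Numerical floors.** Two thresholds with different meanings:

* `ZERO_FLOW_REL = 10⁻⁹` (relative to the largest flow): flows below this
  are solver roundoff — dead-end sprouts and hydraulically balanced
  branches — and are excluded from the advection digraph; such segments
  carry H_D = 0 and no oxygen. The sparse solve leaves roundoff residues
  up to ~10⁻¹¹ relative on these segments, so a floor well above that
  (yet orders of magnitude below any physical flow) keeps their flip-
  flopping sign out of the fixed point. Outer-loop convergence is judged
  on perfused segments for the same reason.
* `PERFUSION_FLOOR = 10⁻¹⁰ µl/s` (absolute): the physiological cutoff
  below which a segment counts as unperfused; applied before all
  hemodynamic medians, CVs and the niche classification.

**Boundary pressures.** When every boundary node carries a measured
pressure, those are used directly and the optimizer is bypassed. When
measured data are absent, boundary nodes are ranked by the diameter of
their attached segment and pressures are initialized by linear
interpolation in log-diameter between the venous and arterial anchors
(large-bore vessels feed, small ones drain); rank order breaks exact
diameter ties. A damped correction loop then shrinks any residual global
imbalance — with pure-pressure boundaries the nodal solve conserves mass
to solver precision, so the loop normally exits at the first check. The
anchors (40/15 mmHg), inlet discharge hematocrit (0.45) and inlet PO2
(50 mmHg) are package defaults chosen once as physiologic for
tumor-feeding microvessels; they are configuration, not fitted values.

## Oxygen transport

Oxygen content per ml of blood is α_b·P (dissolved; α_b blends the
red-cell and plasma solubilities by tube hematocrit) plus
H_D·C_bind·S_Hb(P) (bound; Hill curve). The tissue is partitioned into
domains proportional to segment length, so the wall flux per segment is
J_wall = M_c·m_tissue·L/ΣL. ΣL runs over *eligible* segments by default,
making the delivered total equal the demand exactly; a switch normalizes
over all segments instead. Eligibility (H_D > 0.01, vstt < 25 s)
restricts wall flux to vessels that transport significant oxygen.
Extravascular diffusion and tissue PO2 fields are out of scope.

Given the saturation values the nodal balance is linear, and because the
flow digraph is a DAG it is lower-triangular in topological order. The
solver therefore sweeps nodes in that order and solves, per node, the
monotone scalar equation a·P + b·S_Hb(P) = advected-in (Brent's method on
a guaranteed bracket, saturation fully implicit). The first sweep is
exact; the second certifies the fixed point (tolerance 10⁻⁹ mmHg on the
largest tension change). Outlet boundary nodes use their feeding
segments' composition for the exiting blood.

When demand exceeds convective supply on a branch the nodal tension is
clamped at zero (with a warning) and the shortfall is accumulated in
`unmet_demand`, so the oxygen books always close:
(inlet − outlet advected O2) = ΣJ_wall − unmet_demand, exactly. With
servable demand `unmet_demand = 0` and the classical balance holds.

Parameters: n_hill = 2.7, P₅₀ = 37 mmHg, α_pl = 2.82×10⁻⁵
ml O2·ml⁻¹·mmHg⁻¹ are hemoglobin/plasma standards. α_RBC = 3.38×10⁻⁵
(same units) and C_bind = 0.5 ml O2/ml RBC are standard physiological
values; both are configurable. M_c (tissue consumption, ml O2 g⁻¹ s⁻¹)
is tumor-line specific and deliberately has **no default**; tests and the
acceptance script use 1.2×10⁻⁴, a representative breast-xenograft rate.
Tissue mass defaults to density (1 g/ml) × tumor volume when not given
explicitly. Per-segment PO2 is the arithmetic mean of the endpoint
tensions — the simplest reduction consistent with nodal bookkeeping.

## Morphometry

Rasterization sets a voxel iff its center lies within D/2 of a segment
chord. The distance map is the exact Euclidean distance transform
(voxel-center to nearest vessel-voxel center) at the map resolution —
the centerline-voxel convention, chosen over distance-to-surface and
documented here. Density maps assign each segment's full arc length (and
lateral surface πDL) in equal shares to the voxels its centerline
traverses, supersampled at spacing/4; a box kernel (default 20³ voxels of
8 µm = a 160 µm window) divided by the in-bounds window volume yields
L_v (mm/mm³) and S_v (mm²/mm³). Border windows are normalized by their
in-bounds volume to avoid rim artifacts. Shares are conserved exactly for
networks inside the grid (tested to 10⁻⁶ relative). Volume density is
Σ(πD²/4·L)/Vol.

## Phenotype

Classes over perfused segments, thresholds configurable: Class 1 =
Vel < 50 µm/s and PO2 < 10 mmHg; Class 2 = Vel ≥ 50 µm/s and
PO2 ≥ 10 mmHg; Class 3 = the two mixed quadrants; Class 4 (functional
shunts: Vel ≥ 2× median, D ≥ 2× median, L ≤ 0.5× median, medians over
the same network's perfused vessels) takes precedence because its
criteria co-occur with Class 2's. Where published descriptions of the
middle classes conflict, the convention with explicit inequalities
(Class 2 = hyperperfused + normoxic) is adopted.

CV uses the sample (n−1) standard deviation — small ensembles; the
population alternative is a one-line change. CV correlations use Pearson
r with two-sided p, significance at 0.05; constant columns are reported
as missing rather than zero. Group comparison is the two-sided
Mann–Whitney U test. Clustering is UPGMA (average linkage) on Euclidean
distances of z-scored features (mixed units make scaling mandatory);
flat labels come from a cluster count or a distance threshold, and the
cophenetic correlation coefficient is reported with a warning flag at
≤ 0.8.

## Synthetic networks

`make_line`, `make_bifurcation_tree` and `make_lattice` are fully
determined validation topologies. `make_tumor_like` emulates the salient
statistics of tumor microvasculature: interior points sampled in a sphere
with the rim shell (outer 25% of the radius) boosted 3× in density, a
Euclidean minimum spanning tree plus 15% short loop edges, log-normal
diameters (median 10 µm, σ = 0.5 — positively skewed) smoothed along
neighbors, uniform tortuosity 1.1, and surface boundary nodes attached by
wide stub segments. MST leaves act as blind-ended sprouts: they are
degree-1 but *not* boundary (explicit `is_boundary` flags distinguish
them), so they receive no boundary pressure and carry no flow — which is
what produces the large unperfused fraction characteristic of tumors.

What the generator does **not** emulate: real angiogenic branching
statistics, vessel cooption or remodeling, spatially correlated diameter
hierarchies along arterio-venous paths, or co-registered tissue context.
Passing tests therefore demonstrate solver correctness and the intended
qualitative regime (rim/core contrast, skewed diameters, perfusion-
limited hypoxia), not biological fidelity of any particular tumor.

## Problem sizes

The test suite runs networks of tens to a few hundred segments, voxel
grids up to 32³ for exact-oracle checks, and 100-replicate clustering
ensembles; the acceptance script uses 20 random lattices (≤ 50 segments)
for the dense-oracle comparison and a six-tumor ensemble of ~220-segment
networks. These sizes were chosen so every oracle (dense solves,
brute-force distance transforms, exhaustive rank enumeration) remains
exact and fast; the solvers themselves are sparse and scale to much
larger graphs.

## Known limitations

* No extravascular oxygen diffusion: tissue PO2 is undefined by design.
* Steady-state only; no pulsatility, vessel adaptation or remodeling.
* The phase-separation law is empirical for bifurcations; the recursive
  extension to higher-order junctions is a modeling choice.
* Anoxic regimes report a clamped (zero) tension and the unmet demand
  rather than redistributing flux — a flux-limited formulation would
  require the extravascular coupling that is out of scope.
* The mesentery loader expects a documented text conversion of the
  published dataset; the dataset itself is not redistributed.
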