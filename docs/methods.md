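# Methods

## Model

Microtubules (MTs) are represented as ordered chains of vertices,
minus end first, with every element exactly ℓ long. The engine is a
fixed-time-step stochastic process: all events are Bernoulli trials
with per-step probabilities, so a probability P corresponds to a
physical rate −ln(1−P)/Δt for readers who want real time units. A
Gillespie-style continuous-time scheme was deliberately not used: the
severing rule is stated per time step ("at all later time steps"), so
the step is the natural unit.

One step performs, in order: (1) nucleation; (2) per-MT dynamics in
ascending id order — spontaneous plus-end transitions first, then one
growth or shrinkage move, then minus-end shrinkage where active; (3)
severing over all registered crossovers; (4) step-counter increment.
The fixed ordering plus a single PCG64 generator make trajectories
bit-identical for identical (domain, parameters, seed).

### Growth, membrane, collisions

A growing plus end proposes a tip advance of one element along its
current direction and resolves, with priority:

1. **Membrane.** If the advance would exit the domain, the first
   boundary intersection along the ray is computed analytically (slab
   method for boxes, half-space scan for prisms, quadratics for sphere
   and cylinder). Shallow hits (incidence angle < θ_edge, measured
   from the tangent plane) deflect: the direction is projected into
   the tangent plane and renormalized. Steep or degenerate (head-on)
   hits trigger a catastrophe with probability P_edge_cat; if that
   coin fails, deflection is retried, with a uniformly random tangent
   direction substituted in the exactly-degenerate case. On curved
   boundaries a deflected step can still exit; the deflection loop is
   iterated up to 4 times, after which the direction update is kept
   but no element is added that step. Since all domains are convex and
   both endpoints of every element are kept inside, whole elements are
   inside by convexity.

2. **Contact.** Otherwise, if the proposed tip lies within d_contact
   of a foreign element (nearest-element query on a uniform spatial
   hash with cell size max(ℓ, d_contact); the MT's own two most recent
   elements are excluded to avoid self-contact artifacts), the
   collision angle θ = arccos|d₁·d₂| decides: θ < α bundles (the
   growth direction is set to ±target, the sign minimizing the turning
   angle — the nematic sign ambiguity has to be resolved somehow, and
   minimal turn preserves growth continuity); otherwise an induced
   catastrophe with probability P_cat, else a crossover: the element
   is appended straight through and a crossover record (crossing MT +
   element, host MT) is registered. Bundling and induced catastrophes
   never create records.

3. **Extension** otherwise.

Because contact is evaluated at the proposed tip point with
d_contact = ℓ/2, a target crossed mid-step can escape detection; see
Limitations.

### Severing

Each live crossover record is tested independently with probability
P_cross per step, in record-creation order; several severings of one
MT in a step are resolved sequentially with indices re-mapped. A
severed MT splits at the cut element: the minus-side fragment keeps
its identity and its new plus end starts shrinking; the plus-side
fragment gets a fresh id, keeps the old plus-end state, and its new
minus end shrinks by one element per step until the fragment dies.
Element count is conserved by the split, and only the crossing MT is
ever cut — the host is untouched. Records die with their crossing
element (indices are maintained under end-shrinkage and splitting) or
with the host MT. Host-side element identity is not tracked, so a
record survives severing of its host as long as the host's original
id persists; with host turnover this is a second-order approximation.

### Parameters

| parameter | default | meaning |
|---|---|---|
| ℓ | 0.2 µm | element length; one element added/removed per step |
| t_steps | 10,000 | steps per trajectory (protocol-dependent) |
| P_spont_cat | 0.002 | spontaneous catastrophe / step |
| P_rescue | 0.01 | rescue / step |
| P_cat | 0.5 | induced catastrophe on steep collision |
| P_cross | 0.005 / 0 | severing per crossover per step (wild type / katanin mutant) |
| α | 40° | bundling (zippering) threshold |
| k_nuc | 0.5 | expected nucleations / step (Poisson) |
| d_contact | 0.1 µm | contact radius |
| θ_edge | 80° | deflect below, catastrophe-test at/above |
| P_edge_cat | 1.0 | edge-catastrophe probability |
| R | 50 | replicates, seeded seed…seed+R−1 |

P_cross = 0.005 and 0 are the two biological regimes of interest; the
remaining values are this package's defaults — shallow-angle
zippering thresholds near 40° and catastrophe-dominated steep
collisions are the standard choices for cortical-array models, and
k_nuc = 0.5 in the default domains yields steady states of roughly
100–300 MTs. All are configurable. Default domains: rectangle box
40×15×15 µm (aspect 2.67), square box 20×20×15 µm, sphere r = 10 µm —
within the 15–40 µm range of microwells such experiments use.
Nucleation is uniform in the volume by default; a surface mode
(uniform membrane point, tangent orientation, minimally tilted inward
where the membrane curves away) is provided because cortical
nucleation is membrane-associated in vivo.

Minus ends are static by default; `minus_shrink_every` adds optional
treadmilling (one element every k steps). Minus ends created by
severing always shrink one element per step — that is part of the
severing rule, not the treadmilling option.

## Quantification

**Segment route.** Elements within `shell_depth` (default 0.5 µm) of
one of the two opposite z-extremal analysis faces are clipped to the
shell slab (planar faces exactly; hemispherical caps of a sphere by
element midpoint — elements are much shorter than the shell) and
orthogonally projected into the face frame, whose first axis is the
domain's +x (the rectangle's long axis = 0°). The weighted nematic
resultant gives S2 ∈ [0,1] and ΘS2 ∈ (−90°, 90°], computed with the
algebraic double-angle identities (cos 2θ = (dx²−dy²)/L² etc.) so
that symmetric configurations cancel exactly in floating point.
Weights are projected segment lengths — equivalent to element counts
when all elements have length ℓ, and well-defined after clipping.
Per-face values are reported plus a weight-weighted mean S2 over both
faces and the axis of the combined resultant; the two faces are
almost-independent measurements of one array, and weighting by
projected polymer keeps a nearly-empty face from dominating. ΘS2 is
reported only when S2 exceeds 1e−9; below that the axis is undefined.

**Image route.** Per-pixel gradients by central differences; the
fibril orientation at a pixel is the gradient rotated 90°; the
unit-trace nematic tensor averages fibril orientations weighted by
gradient magnitude, and anisotropy is its eigenvalue difference.
Gradient-magnitude weighting makes the measure exactly invariant
under affine intensity rescaling I → aI + b (a > 0), which pixel-
intensity weighting would not be; pixels with |∇I| ≤ 1e−9·max|∇I|
are excluded, and an all-constant image is flagged undefined. ROIs
are polygons in (row, col) pixel coordinates, ≥ 9 pixels.

**Renderer.** Projected segments are rasterized by dense point
sampling with bilinear splatting (unit intensity per unit length),
convolved with a Gaussian PSF (default σ = 0.15 µm at 0.1 µm pixels),
with optional Poisson shot noise at a chosen photon budget. It exists
to close the loop: on noise-free parallel arrays of ≥ 10 µm filaments
the image route recovers the segment-route angle to within ~1° and
anisotropy > 0.9 (shorter segments damp image anisotropy through
line-end caps, a property of the gradient tensor itself).

## Statistics

KS two-sample uses the exact pooled-ECDF supremum (statistic) and the
asymptotic Kolmogorov tail at effective size n₁n₂/(n₁+n₂). The Kuiper
two-sample statistic V = D⁺ + D⁻ operates on angles mapped to the
unit circle by (θ+90)/180 mod 1 (nematic, 180°-periodic) and is
invariant under common rotations; its asymptotic tail uses the
standard small-sample-corrected series. Both offer permutation
p-values (pooled relabeling, vectorized; default below n = 30 per
sample). Because D and V live on a coarse lattice, many permutations
tie exactly with the observed statistic and counting ties as extreme
would make the test conservative; the tie mass is split by a uniform
draw instead, which makes the permutation p exactly calibrated
(uniform under the null) while never exceeding the conservative
count. The uniformity procedure draws
`n_rep` uniform samples of matching size and reports the median
Kuiper p (default 99 draws; a single draw — the minimal version of
the procedure — makes p itself a random variable, hence the median
aggregation; n_rep = 1 is retained). Bootstrap CIs are percentile;
subsampling curves resample without replacement so the full-size
point reduces to the plain statistic.

## Synthetic-data generators

`quantify.fixtures` provides parallel arrays (S2 = 1), orthogonal
grids (S2 = 0 exactly), isotropic sets (E[S2] ≈ √(π/4n)) and
biased square-diagonal sets (S2 = (b−1)/(b+1)); these are the
analytically-solvable inputs used throughout the tests. The simulator
itself is the generator of realistic inputs. What none of this
emulates: real confocal images (uneven labeling, out-of-focus light,
cell-to-cell variability), walls regrowing around protoplasts, actin,
or MT-dependent nucleation. Passing tests therefore validate the
model's internal consistency and its statistical machinery, not
agreement with any particular cell's data.

## Problem sizes

The canonical contrast protocol (`protocols.severing_shape_cohort`)
runs rectangle and square domains with P_cross ∈ {0.005, 0} at
t_steps = 2,000 and R = 20 replicates per cell — a deliberate
desk-scale version of the full 10,000-step, 50-replicate protocol;
by 2,000 steps the rectangle/square order contrast is fully
developed. The severing-law Monte Carlo uses 10,000 trials; test
calibration uses 2,000 null repetitions with 9,999 permutations.

## Known limitations

* Contact detection samples the proposed tip point only; with
  d_contact = ℓ/2 roughly half of true mid-step piercings go
  unregistered (no bundle, catastrophe or crossover). This thins the
  crossover registry and hence the severing channel.
* At these defaults, bundling plus confinement dominate array
  ordering: the rectangle orders strongly (S2 ≈ 0.7) and the square
  weakly (S2 ≈ 0.2) *with or without* severing, and the measured
  severing effect on S2 at t = 2,000, R = 20 is indistinguishable
  from zero in both shapes. The severing rule itself is verified
  exactly (split arithmetic, geometric waiting-time law); a regime
  where severing is the pivotal ordering channel — as the biological
  comparison suggests — would require a different rate combination
  (e.g. weaker induced catastrophe), which this package does not
  presume.
* No tubulin-pool depletion, no pausing state, no MT-based
  nucleation, rigid (non-deformable) boundaries, no actin.
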