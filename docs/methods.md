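# Methods

This note records the models, conventions and design choices behind each
stage of the pipeline, what the synthetic phantoms do and do not emulate,
and the known limitations.

## Conventions

Images are row-major rasters, origin top-left, 0-based, grayscale on the
0–255 scale (held as float64 in memory; files are 8-bit). All geometry is
computed in pixels and converted to µm through a single `pixel_pitch_um`
per run. Logarithms are base 10 throughout the photometric model: the base
cancels in every slope and ratio, but must be fixed for the offset k to be
meaningful. Foreground connectivity is 8-connected, background
4-connected.

## Skeletonization

Thinning is the classic two-subiteration scheme: one parallel pass deletes
removable pixels on north/west corners and south/east boundaries, the
second pass the mirrored set, until a full double pass removes nothing.
Three amendments make the advertised invariants exact rather than typical:

* isolated compact components (e.g. a 2×2 square) satisfy both deletion
  rules simultaneously and would vanish; the component's pixel closest to
  its centroid is restored, so the 8-connected component count is always
  preserved;
* residual 2×2 blocks (possible in diagonal-dense surroundings) are
  cleaned by deleting a locally simple pixel, falling back to a global
  component-count check where the local crossing-number test is too
  conservative;
* spur pruning (terminal branches shorter than 5 px by default) is a
  separate, optional step applied before graph building — the thinning
  itself never shortens real branches beyond the unavoidable ~radius tip
  erosion.

For ideal straight tubes of width 3–21 px the skeleton stays within 1 px
of the true centerline (exact for odd widths).

## Vessel graph and branch levels

Node pixels are skeleton pixels whose circular neighborhood contains ≥ 3
distinct branch arcs; the surrounding "bushy" 3-neighbor pixels are
absorbed into the junction cluster (bounded by the local vessel radius so
two nearby real junctions are never merged). Edge lengths are pixel
counts along an ideal 8-connected path, with the gap that junction
clusters absorb added back; diameters come from the Euclidean distance
transform of the mask as 2·d_bg − 1, which is exact for odd-width bands.
Thinning a junction of a vessel of diameter D perturbs the skeleton over
a region of roughly D/2, so the raw traced graph is simplified:
pass-through nodes are dissolved, micro-edges between split junction
halves contracted, and terminal spurs shorter than ~0.75·D + 3 px removed
— in that order, so a fragmented long branch is consolidated before any
length-based decision. Two safety nets (reattachment of dead-ended
traces by edge splitting, and a completeness sweep for hook-terminated
lines) guarantee that every skeleton pixel is represented and the graph
has exactly as many components as the skeleton. Anastomoses are out of
scope: a cycle raises a clear error, since hepatic portal trees are
treated as acyclic.

The Root is found by a deliberately simple, displacement-tolerant heuristic: among the three
bifurcations with the largest node diameter (maximum incident-edge mean
diameter), the one farthest from the image border wins, with ties broken
by diameter and then row-major order. Levels are assigned path-wise:
Dijkstra distances (edge weight = pixel length) from the Root; through
each Root-incident branch, the farthest reachable leaf defines a level-1
path; bifurcations on level-L paths seed level L+1 for their unclaimed
branches; an edge keeps the level of the first path that claims it, and
everything beyond level 5 is recorded as level 5. Disconnected satellite
fragments (optionally kept for embolic particles that separated from the
main tree) are classed level 5.

## Photometric concentration model

Calibration is ordinary least squares of A = log₁₀(G_B/G) on log₁₀(c·d)
(slope ε, intercept k); the background G_B is estimated as the median
grayscale outside a 5-px dilation of the vessel mask. ε defaults to
0.249 (doxorubicin) when no calibration data are given.

Propagation solves the ratio form for each target edge restricted to
levels P1–P2 by default (distal vessels are noise-dominated). Per-edge
grayscale is averaged over the edge's skeleton pixels after trimming one
incident-vessel radius at each junction, where overlapping lumina
contaminate the signal. The source aggregates G_s and d_s are
*geometric* means over the Root-incident edges: the model is linear in
log G and log d, so only log-space averaging keeps the aggregate on the
model when source diameters differ (arithmetic means bias every c_t by a
common factor, ~10% on phantoms with a thick trunk and thinner first
branches). Estimates above 2·c₀ are clipped and flagged rather than
silently truncated.

## Extravascular diffusion

Profiles are cast perpendicular to the local skeleton tangent (PCA over a
10-px window), starting at the first background position whose bilinear
support is fully extravascular, and sampled every 0.25 px. The profile
abscissa is the distance to the vessel wall taken from the background
distance transform — robust to the staircase jaggedness of a rasterized
wall — made non-decreasing along the ray. G₀ is the mean of the first
three samples; the depth search runs on a 3-sample moving average and
takes the *largest* threshold crossing (robust to noise dips), linearly
interpolated, with censoring flagged when the profile never falls below
threshold. D(n%) is non-increasing in n by construction. Coverage
subtracts a background frame (or the modal grayscale) and counts
corrected intensities ≥ 1 as signal, split by the vessel mask. The IVIVC
is a least-squares line through user-supplied (G_n/G₀, C_n/C₀) pairs; no
in-vivo values are bundled.

## Adversarial segmentation network

The generator is a U-Net (channel widths doubling with depth, 64–512 at
full scale) whose skip connections pass through a dual-attention block:
channel attention (global average pooling → reduction-4 bottleneck →
per-channel sigmoid gate) plus spatial attention (channel mean and max
maps → 3×3 convolution → per-pixel gate), fused by addition — the two
gates respectively re-weight feature maps and image positions, which is
what low-contrast vessel boundaries need. The discriminator is a stack
of conv–BatchNorm–ReLU–pool blocks on (image, mask) pairs ending in a
global-pooled sigmoid. Training alternates a discriminator step
(real/fake BCE) with a generator step (per-pixel BCE + λ·adversarial,
λ = 0.1; λ = 0 reduces to plain supervised training and drops the
adversarial terms from the log). Adam with learning rate 1e-4 at full
scale; reduced-width test networks (8-16-32 channels) train with 1e-3,
the appropriate step size for their much smaller parameter count. All
layers and their backward passes are implemented in numpy (single
precision) with gradients verified against finite differences to ~1e-9;
training is bit-reproducible at a fixed seed and thread count.
Augmentation follows the scheme of flips, rotations at every 4° in
(4°, 360°) — read as including the 4° start, i.e. 89 distinct angles,
exposed in `rotation_angles()` — with bilinear image / nearest-neighbor
mask resampling, rotation fill set to the background median to avoid
dark-corner artifacts, and photometric jitter applied to the image only.

The classical fallback (background-subtracted adaptive threshold, opening,
largest-component retention, hole filling) exists so the downstream
stages run without any training.

## Synthetic phantoms

The generator emulates a hepatic portal tree imaged by bright-field and
fluorescence stereomicroscopy on a 1024² canvas at 20 µm/px (a ~2 cm
field). Branch diameters follow the study's printed classes
(P1 ≈ 600 ± 80 µm down to P5 = 55 ± 7 µm, tapering monotonically along
any path); at this pitch branch lengths are a realistic 8–20× the local
diameter, which is what makes the topology recoverable — at finer pitches
the same diameters fuse sibling subtrees into unresolvable blobs. The
trunk enters from the left border and ends near the canvas center,
mirroring an acquisition centered on the injection site (this also makes
the farthest-from-border Root rule provably correct). Each bifurcation
spawns `branching_factor` children — one near-straight main continuation
and wide-angled (55–70°) side branches — so a tree of depth n has
1 + b + … + bⁿ⁻¹ edges. Ground-truth branch levels are computed on the
generator's own tree with the same path-based rule the classifier uses,
with exact rasterized lengths; a ≥ 12 px margin between the farthest and
second-farthest leaf of every subtree is enforced by rejection sampling
so that the few pixels of skeletonization jitter cannot flip an
assignment. Trees whose tubes would fuse (pairwise collisions, sibling
fusion zones, or insufficient uniquely-owned tube area) are resampled; an
impossible request raises an error naming the offending level.

The bright-field channel darkens tube interiors per the attenuation model
with d equal to the branch diameter (a flat lumen profile: with 3-px-wide
P5 tubes, a chord profile would alias sub-pixel centerline offsets into
~13% grayscale bias that no measurement could undo), takes the darkest
value where tubes overlap, and adds i.i.d. Gaussian noise (σ = 6 by
default). Per-edge concentrations decay geometrically with level
(×0.8 per level from 5 mg/mL at the trunk). The fluorescent channel is a
uniform intravascular plateau plus an exponential radial halo
G(x) = G_wall·exp(−x/λ) with λ = 100 µm by default — chosen because it
gives a closed-form diffusion depth D(n%) = λ·ln(100/n) to test against.
Pinholes left in wedges between diverging tubes by the discrete radius
test are filled (a lumen has no holes).

What the phantoms do *not* emulate: uneven illumination and vignetting,
anastomoses/loops, pulsatile or flow-dependent contrast, partial-volume
blur at vessel walls, embolic-bead granularity, and physically accurate
diffusion–advection (the halo is a stationary closed form, not a
transport simulation). Tests passing on phantoms therefore validate the
algorithmic chain — geometry recovery, the algebra of the photometric
inversion, the depth estimator — not robustness to every artifact of real
microscopy; the manual-correction layer and the configurable thresholds
are the pressure valves for real data.

## Problem sizes used by the test and acceptance runs

Chosen as the smallest sizes at which the checked properties are
meaningful: 100 random 72² blob masks and tube widths 3–21 for thinning;
200 random ≤ 10-node graphs against exhaustive path enumeration; 25
noise-free phantoms for level agreement; 6 phantoms for the photometric
round trip plus 100 noisy 48-sample calibration fits (σ_G = 2); λ ∈ {50,
100, 200} µm × 10 phantoms for diffusion depths; and for the adversarial
network a reduced 8-16-32-channel configuration trained on 16 augmented
128² patches (≤ 200 epochs), compared against the classical fallback on
4 held-out patches over 3 seeds.

## Known limitations

* Loops are rejected, not analyzed; real anastomoses require manual
  correction before topology.
* Diameters below ~3 px are quantization-limited; concentration mapping
  is restricted to P1–P2 for exactly this reason.
* The numpy network trains on a single CPU core; full-width (64–512)
  training at realistic dataset sizes is out of reach — the architecture
  is validated at reduced width.
* The D(n%) estimator assumes an approximately monotone profile; under
  heavy noise the largest-crossing rule biases depths outward.
* The bead-count estimate for embolized vessel cross-sections is not
  implemented: no defensible formula reproduces the reported counts
  exactly, so the quantity is omitted rather than guessed.
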