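# vasq

Quantitative analysis of spatiotemporal drug release in vascularized tissue
images.

In transarterial chemoembolization (TACE), drug-loaded embolic agents are
injected into the feeding vasculature of a liver tumor; how the drug then
distributes — how far it reaches down the vessel tree, how much stays inside
the vessels, and how deep it diffuses into the surrounding matrix — decides
the treatment's local efficacy. `vasq` implements a semiautomated image
pipeline for answering those questions from paired bright-field and
fluorescent microscopy of drug-containing vascular networks (e.g. perfused
decellularized liver scaffolds):

1. **Segmentation** — a dual-attention U-Net trained adversarially
   (generator + convolutional discriminator, written from scratch in
   numpy), or a classical adaptive-threshold fallback, produces a binary
   vessel mask.
2. **Skeletonization** — two-subiteration (Zhang–Suen) thinning reduces the
   mask to a single-pixel-wide, connectivity-preserving centerline.
3. **Topology** — the skeleton becomes a graph of root / bifurcation / leaf
   nodes and edges with pixel-count lengths and distance-transform
   diameters. The injection Root is the most interior of the three
   thickest bifurcations, and every branch is classified into levels
   P1…P5: the shortest-path (Dijkstra) farthest leaf through each
   Root-incident branch defines a P1 path, branches stemming from P1 paths
   are P2, and so on, capped at P5.
4. **Photometry** — intravascular drug concentration from the modified
   Beer–Lambert model

   A = log₁₀(G_B / G) = ε·log₁₀(c·d) + k,

   with G the grayscale inside the vessel, G_B the background, c the drug
   concentration (mg/mL), d the optical path (vessel diameter, µm), and ε
   the light-attenuation coefficient (ε = 0.249 for doxorubicin by
   default; `fit_calibration` refits it from microfluidic channel data).
   Edge-to-edge propagation uses the ratio form
   log₁₀(G_t/G_s) = ε·[log₁₀(c_s/c_t) + log₁₀(d_s/d_t)], in which k
   cancels, with the Root-incident source edges pinned at the injected
   concentration c₀.
5. **Diffusion** — extravascular spread from the fluorescent channel:
   perpendicular intensity profiles from the vessel wall, diffusion depths
   D(n%) (the largest distance where intensity still reaches n% of the
   wall-adjacent value), intravascular/extravascular coverage areas, and
   the in vitro–in vivo correlation (IVIVC) line through paired
   G_n/G₀ vs C_n/C₀ ratios.

Because the microscopy data this kind of study uses are rarely shareable,
the package ships a first-class **synthetic phantom generator**
(`vasq.phantom`) that draws branching vascular trees with full ground truth
— mask, skeleton, graph, branch levels, per-edge concentrations, and
exponential extravascular halos — so every stage is testable end to end.

## Worked example

```python
import numpy as np
from vasq.phantom import PhantomSpec, generate_phantom
from vasq.skeleton import skeletonize, prune_spurs
from vasq.topology import build_graph, detect_root, classify_levels
from vasq.photometry import CalibrationModel, propagate_concentration

bundle = generate_phantom(PhantomSpec(seed=0, noise_sd_gray=0.0))
skel = prune_spurs(skeletonize(bundle.truth_mask), 5)
graph = build_graph(skel, bundle.truth_mask, pixel_pitch_um=20.0)
root = detect_root(graph)
classify_levels(graph, root)

levels = sorted(set(e.level for e in graph.edges.values()))
print("edges:", len(graph.edges), "levels:", levels)

cmap = propagate_concentration(
    bundle.truth_graph, bundle.bright_field,
    CalibrationModel(epsilon=0.249, k=0.0), c0=5.0,
)
errs = [abs(c - bundle.truth_concentration[e]) / bundle.truth_concentration[e]
        for e, c in cmap.concentration.items()]
print(f"P1-P2 edges mapped: {len(cmap.concentration)}, "
      f"max round-trip error: {100 * max(errs):.4f} %")
```

Output:

```
edges: 31 levels: [1, 2, 3, 4]
P1-P2 edges mapped: 21, max round-trip error: 0.0000 %
```

The phantom's tree has 31 resolvable branches classified into levels 1–4;
all 21 P1–P2 edges get their generating concentration back exactly because
the noise-free forward rendering and the inverse ratio form are algebraic
mirrors of each other.

The same pipeline is available from the shell:

```bash
vasq phantom --out phantom_dir --seed 0
vasq segment --image phantom_dir/bright_field.tif --out mask.png
vasq skeleton --in mask.png --out skel.png
vasq topology --skel skel.png --mask mask.png --out graph.json
vasq run --config run.yaml        # full pipeline with manifest
```

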