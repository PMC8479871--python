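# memwave

Entire-membrane analysis of excitable signaling waves on small adherent
cells.

Lipid-signaling domains (e.g. PIP3-enriched patches) travel as excitable
waves over the plasma membrane of amoeboid cells.  When actin polymerization
is inhibited the cell relaxes to a truncated sphere adhered to the coverslip,
and the rim of the adhered ventral disc — the **contact perimeter**, the most
strongly curved part of the membrane — pins and guides these waves.
`memwave` implements the full analysis chain needed to quantify this on
whole-cell 4D fluorescence recordings, together with a synthetic-cell
generator that makes every stage testable with known ground truth and no
external data.

## What it computes

Given a 4D stack (t, z, y, x; defaults 0.2666 µm lateral, 0.5 µm axial,
10 s frames) or a per-node signal on a triangulated membrane:

1. **Reconstruction** — the membrane is localized per ray as the radial
   argmax of the temporal standard deviation of the fluorescence,
   triangulated (spherical Delaunay) at ≈0.3 µm² mean area per node, and the
   per-node intensity time series extracted.  Adherent nodes and the contact
   perimeter latitude θ_adh are detected from the supporting plane.
2. **Mapping** — equal-area Mollweide maps, x = (2√2/π)·φ·cos γ,
   y = √2·sin γ with 2γ + sin 2γ = π·sin θ solved by Newton–Raphson, plus
   azimuth–time kymographs of bottom/center/top latitude bands.
3. **Fluctuation (DFA1)** — per node, the mean-removed series is cumulated
   and detrended in non-overlapping windows of τ = 4…18 samples
   (T_max = 180 s); F(τ) ~ τ^α gives the scaling exponent α (≈0.5 white
   noise, ≈2 noise-free oscillation).  The latitude profile of α is
   summarized by a weighted polynomial fit evaluated at the ventral center
   (α_min) and the contact perimeter (α_adh); Δα = α_adh − α_min separates
   noise-dominated (Δα > 0) from oscillatory (Δα < 0) ventral membranes.
4. **Phase** — complex Morlet wavelet ψ(t) = ω^(−1/2)·e^(iωt)·e^(−t²/2)
   (ω = 2π, analysis window 60–330 s), ridge extraction of the dominant
   period, per-node instantaneous phase, phase-singularity detection by
   discrete winding numbers on mesh faces (net charge is always zero on the
   closed surface), greedy singularity tracking, and pinned/free
   classification against the contact perimeter.
5. **Kinematics** — shape descriptors via
   r_a = A_adh/A_mem = sin²Ω / (3 + cos Ω) inverted numerically for the
   contact angle Ω; domain tracking through a degree-3 spherical-harmonic
   projection; chord-step velocities split into polar/azimuthal components
   with speed ratio v_a = ⟨v_φ⟩/⟨v_θ⟩ (≈1 for isotropic propagation); and
   population reduction to the linear law v_a = m·r_a + n₀.

The `synthetic_cell` module generates truncated-sphere cells with horizontal
waves, vertical waves, transient spots, pinned spirals, white noise, or
isotropically wandering domains, and renders them to voxel stacks through a
Gaussian point-spread function, so every stage above can be verified by round
trips against known parameters.

## Worked example

```python
import numpy as np
from memwave import (SceneSpec, make_scene, alpha_map, alpha_profile,
                     shape_descriptors, phase_map, find_singularities,
                     track_and_classify)

spec = SceneSpec(radius=3.0, contact_angle=np.pi/3, pattern="pinned_spiral",
                 period=200.0, noise_sd=0.1, duration=600.0, seed=1)
mesh, signal, truth = make_scene(spec)

geom = shape_descriptors(mesh)
prof = alpha_profile(alpha_map(signal, mesh), mesh)
pmap = phase_map(signal, mesh)
per_frame = [find_singularities(pmap, mesh, t)
             for t in range(pmap.phase.shape[1])]
tracks = track_and_classify(per_frame, mesh)
```

This prints (via the calls shown in `scripts/` and the report fields):

```
nodes: 377, mean node area: 0.281 um^2
A_mem = 106.0 um^2, A_adh = 21.2 um^2, r_a = 0.200, Omega = 57.3 deg, V = 0.095 pL
alpha_min = 1.76, alpha_adh = 1.76, delta_alpha = +0.00
track 0: charge +1, lifetime 28 frames, mean dist to perimeter 2.96 um, pinned=False
track 1: charge -1, lifetime 28 frames, mean dist to perimeter 0.20 um, pinned=True
```

Reading: the cell is a 3 µm sphere truncated at Ω = 60° (recovered 57.3°
through the printed area-ratio model); the spiral drives the whole membrane,
so α ≈ 1.8 everywhere and Δα ≈ 0; singularity tracking finds exactly the
topologically required pair of opposite charges, and the one sitting 0.2 µm
from the contact perimeter is classified pinned while its counter-rotating
partner wanders freely on the upper membrane.

A shell interface wraps the same calls:

```sh
memwave simulate --pattern horizontal_wave --radius 3 --omega-deg 60 \
    --period 200 --duration 1800 --noise-sd 0.2 --seed 1 --out scene/
memwave dfa --cell scene/cell.h5 --out dfa/
memwave run --config run.toml
```

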