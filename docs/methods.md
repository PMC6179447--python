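# Methods

## Model of the map

Every stage assumes the observed density is a superposition of Gaussian
kernels centred on atoms: the contribution of a source at distance d is
k(d) = exp(−1.5‖d/σ‖²). The same kernel serves three roles — the
smoothed field that mean shift climbs (sources = map grid points,
σ = 1 Å), the density profile sampled along a traced path, and the
forward model of the synthetic-map simulator (sources = fixture atoms,
σ = σ_sim). Grids are regular and orthogonal; all geometry is done in
world ångströms, with voxel (i, j, k) at `origin + voxel_size·(i,j,k)`.
Anisotropic voxel sizes are supported throughout rather than resampled
away. Non-orthogonal cells are rejected: the single-particle maps this
tool targets are orthogonal, and supporting skew cells would complicate
every geometric step for no practical gain.

## Stage parameters

| parameter | default | units | role |
|---|---|---|---|
| `sigma` (mean shift) | 1.0 | Å | kernel bandwidth of the smoothed field |
| `threshold_fraction` | 0.5 / 0.25 | — | seed threshold as a fraction of the contour level (the earlier tracer generation used 1.0/0.5) |
| `convergence_tol` | 0.01 | Å | per-seed stop criterion |
| `merge_radius` | 0.5 | Å | single-linkage radius for merging converged seeds |
| `edge_cutoff` | 5.0 | Å | proximity-graph connection radius (just above the 3.8 Å Cα–Cα bond) |
| `top_k_paths` | 100 | — | paths summed in the tree score |
| `tabu_tenure` | 20 | moves | FIFO tabu-list length |
| `move_budget` | 500 | moves | candidate moves evaluated per iteration (sampled with the seeded RNG beyond this) |
| `resample_step` | 1.0 | Å | arc-length sampling of the traced path |
| `min/max_spacing` | 2.8 / 4.5 | Å | hard window on the consecutive-residue arc gap |
| `spacing_weight` | 0.1 | z²/Å² | soft prior toward the 3.8 Å virtual bond |
| `gap_open` | 1.0 | z² | cost per unmodeled terminal residue |
| `radius` (consensus) | 3.5 | Å | agreement radius of the confidence score |
| `n_consensus` | 100 | models | consensus pool size |

Notes on the less obvious choices:

* **3σ neighborhood cutoff** for the kernel sums truncates tails below
  1.2·10⁻⁶ of the peak; the smoothed field is effectively exact there.
* **Merged-mode representative** is the member with the highest smoothed
  density, not the centroid, so LDPs stay on ridges of the field.
* **Tree score.** The score of a spanning tree is the summed length of
  its top-K leaf-to-leaf paths. K = 100 is calibrated to
  production-scale LDP clouds (roughly a thousand points, i.e. K ≈ 10%
  of them). When the cloud is small and K exceeds the number of leaf
  pairs, the objective degenerates: growing extra leaves adds summands,
  so the search drifts toward caterpillar-shaped trees and the longest
  path shrinks. `run_sweep` therefore scales K with the cloud,
  `min(100, max(2, n_ldps // 10))`, preserving the production ratio at
  every size. `TabuParams` used directly still defaults to K = 100.
* **Spacing prior.** The DP match term −(ẑ_density − ẑ_volume)² cannot
  pin the register on contrast-poor density (a map simulated from
  uniform-weight atoms is nearly flat along the chain, and real maps
  have flat stretches too); with only the hard window the optimal
  assignment compresses to ~3.3 Å mean spacing and drifts off register.
  The quadratic prior `spacing_weight·(gap − 3.8)²` encodes the tightly
  distributed virtual Cα–Cα bond; 0.1 z²/Å² costs ≈0.05 at the window
  edges, well under typical match-score differences, and
  `spacing_weight=0` restores the pure density-matching objective.
* **Residue volumes** are standard mean side-chain-inclusive volumes
  (G 60.1 ų … W 227.8 ų), z-normalized over the 20 residues so only
  relative size matters; threading scores are consequently invariant to
  linear rescaling of the raw map values.
* **Interior gaps.** Consecutive placed residues must respect the hard
  spacing window — the DP does not jump over interior path regions.
  Only terminal residues may be left unmodeled (at `gap_open` each),
  which is what partial-coverage maps need; allowing interior skips
  would break the output invariant that every consecutive-residue gap
  lies in [2.8, 4.5] Å.
* **Determinism.** Ties are broken by lexicographic node order
  everywhere (MST edge order, longest-path endpoints, DP backtracking
  keeps the run start on equal scores). The only RNG is the tabu move
  sampler; each sweep combination derives its own seed from the base
  seed by counter, so any subset of a sweep is individually
  reproducible and concurrent execution cannot change results.

## Sweep presets

Presets differ in seed thresholds and tabu effort: the `2016` preset
thresholds at {1.0, 0.5}× contour, the `2017` preset at {0.5, 0.25}×
with 10× the tabu iterations, and `fast` is a desk-scale profile
(2 thresholds × 2 cutoffs × 3 tabu seeds → 24 models, consensus pool
24) sized so a 30-residue fixture sweeps in well under a minute on one
core. Production-scale grids generating thousands of models are
configuration, not code: every grid axis and both caps (`n_models_keep`,
default 500; `n_consensus`, default 100) are fields of `SweepConfig`.

## What the synthetic fixtures do and do not show

`simulate_map` renders Cα positions only (optionally weighted by
residue volume to create sequence-correlated contrast), with
σ_sim = half the nominal resolution (a "4 Å map" uses σ_sim = 2 Å, which
makes helices the continuous tubes they are in real maps). It omits
noise, CTF artefacts, B-factor variation, solvent, and neighboring
chains. Passing tests therefore demonstrate that the tracing logic is
correct — modes found, trees built and refined, register assigned
optimally under the stated objective, metrics exact — on maps that obey
the method's own generative assumption. They do not demonstrate
robustness to experimental noise, to side-chain density (which is what
makes the LDP count exceed the residue count on real maps), or to the
segmentation errors of multi-chain maps, all of which are properties of
real data the fixtures deliberately exclude. The end-to-end tests use a
30-residue helix (σ_sim = 2 Å, voxel 1 Å) and a mixed-composition
sequence with small G/A termini — a realistic single-helix construct —
as the standard recovery problem; the acceptance script reports its
measured quantities at that problem size.

## Degenerate inputs and numerical edges

Empty structures, all-zero maps, sub-minimum paths, and graphs whose
largest component has fewer than two nodes raise explicit errors. A
mean-shift seed in a zero-density region stays in place. A constant
density profile z-normalizes to all zeros (guarding the zero-variance
division). The map writer stores float32 values (MRC mode 2), the
origin in the ORIGIN header, and the contour level in a map label, so a
read→write→read round trip is lossless; axis-permuted files are
normalized to X, Y, Z at read; origins fall back to NSTART×voxel when
the ORIGIN record is zero. PDB coordinates carry the format's three
decimals.

## Known limitations

* Single chain per map; no segmentation is provided or attempted.
* The tracer ends at ranked Cα models: no full-atom building and no
  refinement-based re-ranking.
* GDT-TS and RMSD are computed frame-fixed by default (models live in
  the map frame, like fitted reference structures); a Kabsch
  superposition flag exists for frame-free comparisons. The
  LGA-style per-cutoff superposition search is not implemented.
* Consensus counts duplicate models as-is; near-identical sweep
  combinations can inflate agreement. De-duplication before consensus
  is deliberately not applied.
* β-sheet-rich topologies create many short cross-strand connections in
  the proximity graph and remain the hard case for any tree-based
  tracer; the hairpin fixture exercises the topology but at desk scale.
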