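# polarscore

Quantification of receptor polarization and migration behavior in 2D
fluorescence micrographs of migrating lymphocytes.

A chemokine-stimulated T cell polarizes: CD44 gathers in the uropod (the
trailing projection), low-affinity LFA-1 is restricted to the trailing edge,
and the cell migrates with measurable speed and directionality. Screens for
polarization-defective mutants need those phenotypes turned into per-cell
numbers. `polarscore` provides that measurement stack:

* **single-cell detection** — Gaussian smoothing, global Otsu threshold,
  hole filling, 8-connected labeling, then area / solidity / border filters
  (fused cell clumps are rejected, not split, so only singly detected cells
  are scored);
* **a per-cell receptor clustering index** — the statistic at the package's
  core (below);
* **trailing-edge localization calls** — is a marker's signal concentrated in
  the rear half of the cell, with the rear axis defined by a uropod
  reference stain, by motion, or supplied directly;
* **migration-track metrics** — path length, net displacement, mean speed,
  directionality ratio, turning angles, rose-plot coordinates;
* **two-group statistics** — Shapiro-Wilk normality per group, then
  Student's t (both groups normal) or Mann-Whitney U (otherwise; exact
  U-distribution for tie-free samples with min(n) ≤ 8);
* **a synthetic-micrograph generator** with full ground truth, so the entire
  pipeline is testable without any external image data.

## The clustering index

For one cell and one channel, take the brightest 10% of the cell's pixels
(n = max(2, round(0.1 · area)), deterministic tie-breaks) and compute their
mean pairwise Euclidean distance *Dα*. Normalize it between two reference
configurations of the same n points:

* *S*<sub>l</sub> — n points packed row-major into a ⌈√n⌉-sided square
  lattice block (for n = 100, a 10 × 10 pixel square): maximal clustering;
* *S*<sub>u</sub> — n points placed at equal arclength along the cell's
  traced outer boundary: maximal dispersion.

The index is

&nbsp;&nbsp;&nbsp;&nbsp;ci = (*S*<sub>u</sub> − *Dα*) / (*S*<sub>u</sub> − *S*<sub>l</sub>)

so ci ≈ 1 for a tight receptor cap and ≈ 0 for a perimeter-uniform ring.
Values outside [0, 1] are possible for unusual geometries and are flagged,
never clipped. The synthetic generator controls polarization through a von
Mises angular concentration κ on the membrane stain, and mean ci rises
strictly with κ — the parameter-recovery surface for the whole pipeline.

## Worked example

`examples/02_clustering_index.py` renders one polarized and one unpolarized
synthetic cell and scores them:

```
polarized (kappa=8): n=66 top-decile px, D_alpha=5.43 px, S_l=4.34, S_u=18.23, ci=0.922
uniform ring (kappa=0): n=66 top-decile px, D_alpha=15.57 px, S_l=4.34, S_u=18.23, ci=0.191
```

Both cells have the same geometry, so they share the packed bound (4.34 px)
and the perimeter bound (18.23 px). The polarized cell's brightest decile
sits in one compact cap — its mean pairwise distance (5.43 px) is close to
the packed bound, giving ci = 0.92 — while the unpolarized cell's brightest
pixels ring the whole membrane, giving ci = 0.19.

The other scripts in `examples/` demonstrate each capability end to end
(field rendering, segmentation + scoring, polarity calls, track metrics,
and the full two-condition pipeline). The same functionality is scriptable
from the shell:

```sh
polarscore simulate --out bench/ --seed 1
polarscore segment --input field.tif --channels cd44,lfa1 --out mask.tif
polarscore score --field field.tif --mask mask.tif --channels cd44,lfa1 --out scores.csv
polarscore run --config analysis.toml --out results/ --seed 1
```

## Layout

```
src/polarscore/   io, detect, cluster, polarity, tracks, stats, synth, pipeline, cli
tests/            unit + property + end-to-end acceptance tests
examples/         one short narrative script per capability
docs/methods.md   models, assumptions, parameter choices, limitations
```
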