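# memclust

Quantitative analysis of high-speed AFM (HS-AFM) topography movies of
membrane-protein clusters, plus the FRAP and electrolyte-screening
calculations that accompany such experiments:

- **preprocess** — per-line flattening, drift alignment, isodata
  (intermeans) thresholding, three-frame walking-average mask denoising,
  protein/lipid/mica surface-coverage fractions, and selection of
  isolated (never merging/splitting) cluster traces.
- **contour_dynamics** — polar radial profiles R(θ, t) of a cluster
  boundary, radius-change maps ΔR(θ, t), mean leading-edge velocity μv,
  and line tension λ from the capillary-wave equipartition of boundary
  Fourier modes (⟨a_k² + b_k²⟩ ∝ 1/(λ·(k² − 1)), k ≥ 2).
- **particle_geometry** — single-particle refinement by nf-fold
  rotational symmetrization (internal symmetry value, isv), symmetry
  classification from the angular harmonic spectrum, tilt from the
  least-squares protomer plane, Delaunay neighbor pairs, signed
  interaction angles (clockwise-positive, bounded by ±180/nf), angle
  density maps, and Gaussian distance statistics.
- **cluster_metrics** — 2D packing fraction (cross-sections 38/43 nm²),
  pentamer composition ratios, and PCA + 2-component Gaussian-mixture
  cluster typing on the standard 8-feature table.
- **frap** — FRAP trace normalization, effective bleach radius from
  f(x) = 1 − K·exp(−2x²/re²), recovery half-time, and
  D = (re² + rn²)/(8·τ½).
- **physchem** — Debye screening length.
- **synthetic_data** — ground-truth-annotated generators: cluster movies
  whose boundaries fluctuate with a known line tension, nf-fold
  particles with edge-localized tilt, and FRAP series with a known
  diffusion coefficient. Every estimator is validated closed-loop
  against these generators.

Line tension is expressed in thermal units (kB·T per nm), so the mode
variance is dimensionless and temperature cancels from the estimator.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact printed
values and closed-loop statistical recovery at stated tolerances).

## CLI

```sh
# render a synthetic movie (TIFF + JSON ground-truth sidecar)
memclust simulate --out movie.tif --line-tension 100 --n-frames 200 --seed 1

# contour dynamics: mean leading-edge velocity + line tension fit
memclust contour --input movie.tif --dtheta 2 --kmax 12 --out results/

# particle geometry from rough seed positions (CSV: frame,x,y,species)
memclust particles --input movie.tif --seeds seeds.csv --out results/

# FRAP (either a recorded series or a self-simulated one)
memclust frap --simulate-d 1.5 --out results/

# Debye length at 150 mM monovalent salt
memclust debye -i 0.15

# full pipeline from a JSON config
memclust run --config config.json
```

Movies are 32-bit float TIFF stacks (heights in nm) with a JSON sidecar
(`movie.json`) carrying `pixel_size_nm`, `frame_interval_s`, and — for
synthetic data — the full ground truth. HDF5 stacks (`frames` dataset)
are also read.

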