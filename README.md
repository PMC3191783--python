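# rmcflow

Level-set image segmentation by **Riemannian mean curvature flow**, with two
interchangeable numerical engines and a self-contained evaluation pipeline.
The package targets biomedical image analysis — the motivating case is
outlining a skin lesion in epiluminescence microscopy — but applies to any
grayscale image in which a single smooth object must be delineated from a
user-supplied seed.

## The model

A segmentation function `u(x, τ)` evolves on the unit square under the
edge-weighted, ε-regularized curvature flow

    ∂u/∂τ = √(ε² + |∇u|²) ∇·( g(|∇I⁰|) ∇u / √(ε² + |∇u|²) ),
    u = 0 on ∂Ω,   u(·, 0) = u₀,

where `I⁰` is the input image, `g(v) = 1/(1 + v²/β)` is the Perona–Malik
edge detector evaluated on the Gaussian-presmoothed image gradient, and `u₀`
is a smooth bump supported on a seed disk placed inside the object.
Diffusion is strong in flat image regions and collapses near edges, so the
level lines of `u` sharpen onto the object boundary; at the end of the scale
horizon `T` the half-maximum level line of `u` is the segmentation.

Cell-centered finite volumes give a five-point scheme whose per-step matrix
`I + Δτ·A` is an M-matrix (discrete maximum principle).  Three scale
discretizations share that spatial core:

* **explicit** forward Euler (CFL-limited; mainly a reference),
* **semi-implicit** (`Algorithm SI` style): coefficients frozen at the
  previous step, one linear solve per step by restarted **GMRES with an
  algebraic-multigrid V-cycle preconditioner** (smoothed aggregation,
  exact Galerkin coarse operators, default tolerance 1e-10),
* **fully implicit** Crank–Nicolson: one nonlinear system per step solved by
  **Jacobian-free Newton–Krylov** (finite-difference Jacobian probes,
  backtracking line search, default tolerance 1e-10), with an L-stable
  damped start-up step to suppress Crank–Nicolson ringing of the seed.

The semi-implicit scheme is first-order accurate in `Δτ`, Crank–Nicolson
second-order, so matched error budgets pair `Δτ_SI = Δτ_I²` — e.g.
`Δτ_I = 0.4 ⇒ Δτ_SI = 0.16`, giving `⌈T/Δτ⌉` = 1 vs 3 steps at `T = 0.4`.
Contours are scored with the Hausdorff distance
`d_H(C₁, C₂) = max{max_a min_b ‖a−b‖, max_b min_a ‖a−b‖}` between finite
point sets.

## Worked example

`examples/` contains one short script per capability.  Comparing the two
engines at matched discretization error on a 128×128 phantom with a known
contour (`examples/03_compare_engines.py`) prints:

```
engine            dtau  steps       d_H
semi_implicit     0.16      3    0.0046
implicit          0.40      1    0.0044
```

Both engines land on the true boundary to within better than one grid cell
(`h ≈ 0.0078`): the implicit engine needs a single nonlinear solve where the
semi-implicit one takes three linear solves.  The per-step solver effort
(`examples/02_segment_and_score.py`) is also reported:

```
scale steps run   : 3 (dtau = 0.16)
  step 1: k_gmres =  25, AMG levels = 6
  step 2: k_gmres =  20, AMG levels = 5
  step 3: k_gmres =  18, AMG levels = 6
Hausdorff distance: 0.0046  (grid spacing h = 0.0078)
```

GMRES counts fall step by step because each solve starts from the previous
scale step — the signature of a run approaching its steady shape.

A thin CLI wraps the same library calls:

```bash
rmcf phantom --n 256 --seed 7 --out-image ph.png --out-contour truth.csv
rmcf segment --image ph.png --scheme si --dtau 0.16 --t 0.4 --out-contour seg.csv
rmcf evaluate seg.csv truth.csv
rmcf compare --phantom-n 128 --dtau-implicit 0.4
```

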