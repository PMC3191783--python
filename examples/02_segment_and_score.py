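"""Segment a phantom with the semi-implicit engine and score the contour.

One linear system per scale step, solved by GMRES preconditioned with an
algebraic-multigrid V-cycle.  The final contour is the half-maximum level
line of the segmentation function, scored against the phantom's exact
boundary with the Hausdorff distance.
"""

from rmcflow import (
    ModelParams,
    SchedulePlan,
    extract_contour,
    generate_phantom,
    hausdorff_distance,
    run_segmentation,
)

phantom = generate_phantom(n=128, seed=7)
params = ModelParams()  # epsilon = beta = 1, T = 0.4
plan = SchedulePlan("semi_implicit", dtau=0.16, T=0.4)

state, record = run_segmentation(phantom, params, plan,
                                 seed_center=(0.5, 0.5), seed_radius=0.15)
contour = extract_contour(state.u, 0.5 * state.u.max(), phantom.grid)
d_h = hausdorff_distance(contour, phantom.truth_contour)

print(f"scale steps run   : {len(record)} (dtau = {plan.dtau})")
for step in record.steps:
    print(f"  step {step.step}: k_gmres = {step.solver.iterations:3d}, "
          f"AMG levels = {step.solver.levels}")
print(f"Hausdorff distance: {d_h:.4f}  (grid spacing h = {phantom.grid.hx:.4f})")
# d_H of a few grid cells means the recovered contour tracks the true
# object boundary to sub-percent accuracy of the domain size.
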