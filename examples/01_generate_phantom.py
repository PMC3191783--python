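"""Generate a synthetic test image with an analytically known contour.

The phantom emulates a dark, smoothly lobed lesion on a light background.
Because the object boundary is given by an analytic radius function, every
segmentation result can be scored against exact ground truth.
"""

from rmcflow import generate_phantom
from rmcflow.io import save_contour_csv, save_image

phantom = generate_phantom(n=256, noise_sigma=0.0, seed=7)
save_image("phantom.png", phantom.image)
save_contour_csv("phantom_contour.csv", phantom.truth_contour)

print(f"image size        : {phantom.image.shape[1]} x {phantom.image.shape[0]}")
print(f"intensity range   : [{phantom.image.min():.2f}, {phantom.image.max():.2f}]")
print(f"truth contour     : {len(phantom.truth_contour)} vertices "
      f"(spacing under one cell)")
print(f"object radius r0  : {phantom.shape.r0}")
# The contour CSV holds (x, y) rows in unit-square coordinates; feed it to
# `rmcf evaluate` to score any segmentation of phantom.png against the truth.
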