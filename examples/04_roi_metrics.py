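"""ROI-mask filtering, Pearson mask correlation, sharpness, common neurons."""

import numpy as np
from scipy import ndimage

import fovalign as fa

# Size filter: neurons must cover >= 60 px, screening out spine-sized blobs.
scene = fa.generate_scene(n_neurons=12, frame_shape=(200, 200), seed=6)
render = fa.render_session(scene, noise_sigma=2, seed=7)
roi = render.mask
print(f"{roi.n_rois} ROIs survive the 60-px filter; "
      f"sizes {min(map(len, roi.rois))}..{max(map(len, roi.rois))} px")

# Pearson correlation of flattened masks; the 2x2 worked example gives -1/3.
a = np.array([[255, 0], [0, 0]], np.uint8)
b = np.array([[0, 255], [0, 0]], np.uint8)
print(f"2x2 disjoint single-pixel masks: r = {fa.mask_correlation(a, b):+.4f} "
      f"(exactly -1/3); identical masks: r = "
      f"{fa.mask_correlation(roi.image, roi.image):.1f}")

# Spectral sharpness drops monotonically with blur.
fov = render.image.astype(float)
for sigma in (0, 1, 2, 4):
    img = ndimage.gaussian_filter(fov, sigma) if sigma else fov
    rep = fa.sharpness(img, fov)
    print(f"blur sigma {sigma}: sharpness {rep.value:.4f} "
          f"(threshold M/1000 = {rep.threshold:.1f})")

# Common-neuron counting via transformed centroids.
other = fa.render_session(scene, active_fraction=0.5, seed=9)
count, pairs = fa.count_common_neurons(other.mask, roi)
print(f"\nsession with half the neurons active shares {count} neurons with "
      f"the full render (ground truth: {other.mask.n_rois})")
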