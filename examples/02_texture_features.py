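"""Standardize one ROI and compute the 165-feature texture catalog.

The ROI passes through the standardization chain (derotation, 0.5 mm
resampling, bilinear detrending, 0-1 rescaling), is expanded into the
original/gradient/Laplacian transform stack, and each of the three images
yields 55 features in five classes.
"""

import fibrotex as fx

params = fx.SyntheticParams(severity=3.0, tilt_deg=6.0, seed=3)
roi = fx.generate_reticular_roi(params, pixel_spacing_mm=0.7)
print(f"raw ROI: {roi.shape} px at {roi.pixel_spacing_mm} mm/px, tilt {roi.tilt_deg} deg")

stack = fx.build_transform_stack(roi)
print(f"standardized stack: {stack.shape} px at {stack.pixel_spacing_mm} mm/px")

features = fx.extract_feature_vector(stack)
print(f"catalog size: {len(features)} features "
      f"({sum(1 for k in features if k.startswith('original.'))} per image)\n")

show = [
    "original.histogram.mean",
    "original.gmm.sd_low",          # width of the dark SPIO-loaded population
    "original.gmm.separation",      # how bimodal the intensity histogram is
    "original.voronoi.mean_area",   # nodule size in the tessellation
    "gradient.voronoi.mean_moment2",
    "laplacian.histogram.mode_over_iqr",
]
for name in show:
    print(f"{name:38s} {features[name]:10.4f}")
print("\nIn fibrotic livers the bright-septum population grows: the intensity")
print("histogram becomes bimodal (larger separation, smaller sd_low) and the")
print("Voronoi tessellation locks onto smaller, more regular nodules.")
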