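"""Extract the 45-feature radiomic vector from one lesion.

The vector covers 4 shape, 6 intensity, 19 GLCM, 11 GLSZM and 5 NGTDM
descriptors, computed on the ROI after isotropic resampling, [0,1]
normalization and uniform 32-level gray quantization.
"""

from radiosurv import extract_all, generate_lesion, normalize_intensity

volume, mask = generate_lesion(
    shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0),
    radius_mm=12.0, texture_scale_mm=3.0, seed=42,
)
vector = extract_all(normalize_intensity(volume), mask)

print(f"{len(vector)} features extracted\n")
for name, value in vector.items():
    print(f"  {name:42s} {value:12.4f}")
print("\nshape_volume_mm3 is the lesion volume; glcm_contrast and "
      "ngtdm_coarseness describe how rapidly gray levels vary across "
      "neighbouring voxels (finer texture -> higher contrast, lower "
      "coarseness).")
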