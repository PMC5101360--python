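"""From a rendered colony image to a single 128-dimensional feature row.

A synthetic 'bad' colony (soft edges, bright blobs) is pushed through the
keypoint detector; all of its descriptors are averaged into the one mean
descriptor that represents the image in classification.
"""

import numpy as np

from colonyqc import (
    SyntheticImageConfig,
    extract_descriptors,
    generate_colony_image,
    mean_descriptor,
)

img = generate_colony_image(SyntheticImageConfig(label="bad", seed=8))
print(f"image: {img.shape}, intensities in [{img.min():.2f}, {img.max():.2f}]")

ds = extract_descriptors(img, image_id="demo-bad")
print(f"keypoints detected: {ds.n_keypoints}; descriptor width: "
      f"{ds.descriptors.shape[1]}")

row = mean_descriptor(ds)
print(f"mean descriptor: shape {row.shape}, first entries "
      f"{np.round(row[:4], 2).tolist()}")
print("this single vector is the image's representation for the classifier")
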