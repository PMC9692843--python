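"""Derive the three cluster-ready representations of one patch.

grayscale -> binarize at 0.6 -> 8-connected components -> region table and a
distinctly colored component image.
"""

from testaclust import (WallClass, compute_representations, default_params,
                        generate_image)

wc = WallClass("U", "small_verrucae")
img = generate_image(wc, default_params(wc, seed=3))
rep = compute_representations(img)

print(f"image {img.id}")
print(f"  foreground fraction: {rep.binary.mean():.3f}")
print(f"  connected components (testa cells): {rep.n_components}")
print(rep.region_table[["label", "area", "perimeter", "eccentricity"]]
      .head(5).to_string(index=False))
# Each row is one cell of the testa surface: its pixel area, boundary
# perimeter, and eccentricity (0 = circular).  The component count and these
# statistics form the 10-element 'colored' feature vector.
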