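"""Generate a labelled synthetic seed-testa dataset and write it to disk.

Each image is a 250 x 250 grayscale patch whose anticlinal wall undulation
and periclinal sculpture follow the requested morphology class.
"""

from testaclust import WallClass, default_params, generate_dataset
from testaclust.synthetic import write_dataset

spec = [
    (WallClass("straight", "granule"), 5),
    (WallClass("omega", "large_verrucae"), 5),
]
images = generate_dataset(spec, seed=42)
csv_path = write_dataset(images, "scratch/example_dataset")

print(f"generated {len(images)} images; labels in {csv_path}")
for img in images[:3]:
    print(f"  {img.id}: {img.truth.label}, mean gray {img.raster.mean():.3f}")
# Mean gray differs between the two classes because heavier sculpture and
# denser, thicker walls image darker; that contrast is what the downstream
# clustering picks up.
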