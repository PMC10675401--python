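"""Separate the protein (DAB) and DNA (haematoxylin) stains of an IHC image.

Converts RGB to optical density, solves the per-pixel two-stain
non-negative least-squares problem with the published haematoxylin/DAB
basis, quality-filters on the mean protein-channel intensity, and tiles the
protein plane into 512x512 patches.
"""

from locfuse import (
    SyntheticConfig,
    extract_patches,
    quality_filter,
    simulate_dataset,
    unmix_stains,
)

_, _, images, _ = simulate_dataset(SyntheticConfig(n_per_class=1, seed=5))
image = next(iter(images.values()))

accepted, mean = quality_filter(image)
print(f"{image.protein_id}: mean protein intensity {mean:.1f} "
      f"-> {'accept' if accepted else 'reject'} (threshold 13)")

channels = unmix_stains(image)
patches, shortfall = extract_patches(channels)
print(f"protein plane {channels.protein.shape}, dna plane {channels.dna.shape}")
print(f"{len(patches)} effective 512x512 patch(es); shortfall={shortfall}")
for p in patches:
    print(f"  origin {p.origin}, patch mean {p.pixels.mean():.1f}")
# A 512x512 source yields at most one window; a 3000x3000 slide yields up
# to 15 of the 25 grid positions, scanned row-major.
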