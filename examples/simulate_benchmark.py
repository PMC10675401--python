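"""Generate a small synthetic paired benchmark and look at its structure.

The generator emulates a four-compartment localization benchmark: per class
it draws sequences from a tilted residue/dipeptide profile, builds a noisy
one-hot PSSM per sequence, and renders a two-stain IHC image whose DAB
texture (dominant spatial frequency, stained density) depends on the class.
"""

import numpy as np

from locfuse import SyntheticConfig, simulate_dataset

config = SyntheticConfig(n_per_class=3, seed=7, separation=1.0)
records, pssms, images, labels = simulate_dataset(config)

print(f"{len(records)} proteins, classes: {sorted(set(labels.values()))}")
for r in records[:4]:
    img = images[r.id]
    print(
        f"  {r.id:16s} L={len(r):4d}  PSSM {pssms[r.id].scores.shape}  "
        f"image {img.pixels.shape}  mean RGB {img.pixels.mean():.1f}"
    )

# determinism: the same config always regenerates the identical dataset
records2, _, images2, _ = simulate_dataset(config)
same = all(
    a.sequence == b.sequence for a, b in zip(records, records2)
) and all(np.array_equal(images[r.id].pixels, images2[r.id].pixels) for r in records)
print(f"bit-identical on re-run: {same}")
# Sequence lengths and image sizes match the configured conditions; the
# reported means show DAB+haematoxylin staining darkening the white slide.
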