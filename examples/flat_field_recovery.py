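"""Recovering a known vignetting profile from a tile stack.

A structure-free specimen is imaged through optics with 30 % radial
vignetting; the flat-field estimator must recover the injected gain from
the nine tiles alone.  Prints the RMS error per channel.
"""

import numpy as np

from srhkit import PhantomSpec, estimate_flat_field, generate_phantom, tile_phantom

spec = PhantomSpec(archetype="generic", seed=3, image_size=522, nuclear_density=0,
                   matrix_protein=5.0, matrix_lipid=2.0,
                   illumination="radial", vignette_strength=0.3)
mosaic, truth = generate_phantom(spec)
manifest, tiles = tile_phantom(mosaic, truth, tile_fov_um=180, overlap_fraction=0.05)
print(f"{len(tiles)} tiles of {tiles[0].shape[0]} px, 30% corner vignetting injected")

flat = estimate_flat_field(tiles)
target = truth.injected_gain / truth.injected_gain.mean()
for ch, name in enumerate(("lipid", "protein")):
    rms = np.sqrt(np.mean((flat.gain[ch] - target) ** 2))
    print(f"{name:8s} channel: recovered gain RMS error {100 * rms:.2f}%")
print("sub-percent error means dividing tiles by the estimated gain removes "
      "the vignette to within the phantom's own noise")
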