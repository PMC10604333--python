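"""Cut a raster slide into 224 px tiles and drop background-dominated ones.

The demo slide is half white background, half tissue-coloured: four
candidate tiles exist, but only the two in the tissue column reach the
70% minimum-tissue requirement.
"""

import numpy as np

from histofed import TilingConfig, extract_patches, tissue_fraction

tissue = np.tile(np.array([0.6, 0.4, 0.5]), (448, 224, 1))
white = np.ones((448, 224, 3))
slide = np.concatenate([white, tissue], axis=1)

print(f"slide {slide.shape[0]}x{slide.shape[1]}, "
      f"overall tissue fraction {tissue_fraction(slide):.2f}")
patches = extract_patches(slide, TilingConfig(), slide_id="demo")
print(f"{len(patches)} of 4 candidate tiles survive the 70% tissue filter:")
for p in patches:
    print(f"  {p.patch_id}  tissue fraction {tissue_fraction(p.pixels):.2f}")
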