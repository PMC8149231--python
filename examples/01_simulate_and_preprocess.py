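"""Simulate one speckle image per tissue class and run the enhancement chain.

Prints the gray-level statistics before and after despeckling + contrast
stretch: the stretch widens the dynamic range, the median filter narrows the
pixel-to-pixel spread.
"""

from immunotexture import DEFAULT_RECIPES, binarize, despeckle, generate_speckle_image, stretch_contrast

for label, recipe in DEFAULT_RECIPES.items():
    raw = generate_speckle_image(recipe, size=256, seed=42)
    enhanced = stretch_contrast(despeckle(raw, kernel=3), 1.0, 99.0)
    mask = binarize(enhanced)
    print(
        f"{label:10s} raw range=({raw.pixels.min():3d},{raw.pixels.max():3d}) "
        f"std={raw.pixels.std():5.1f} | enhanced range=({enhanced.pixels.min():3d},"
        f"{enhanced.pixels.max():3d}) std={enhanced.pixels.std():5.1f} "
        f"| bright fraction={mask.mean():.2f}"
    )

print(
    "\nCancer images have the widest gray range (widened gray-level "
    "distribution); the binarized bright fraction is QC only."
)
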