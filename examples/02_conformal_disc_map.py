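"""Map one wing onto the common unit disc and inspect the conformal map.

The wing boundary is cleaned and hinge-clipped, approximated by a
curvature-adaptive polygon, and mapped onto a diameter-100 disc raster by a
Schwarz-Christoffel map; area distortion concentrates at the periphery.
"""

import numpy as np

from discmorph import (
    DiscMaskSpec, VariationSpec, WingTemplate, area_distortion_field, clean_mask,
    clip_hinge, curvature_profile, extract_contour, generate_wing,
    place_polygon_vertices, pushforward_image, solve_riemann_map, wing_area,
)

wing = generate_wing(WingTemplate(), VariationSpec(), t=0.5, shape=(240, 320), seed=3)
mask, _ = clean_mask(wing.mask)
contour = clip_hinge(extract_contour(mask), wing.anchors)
polygon = place_polygon_vertices(contour, curvature_profile(contour), 32)
rmap = solve_riemann_map(polygon)

spec = DiscMaskSpec(100)
disc = pushforward_image(wing.image, mask, rmap, spec)
field = area_distortion_field(rmap, spec)
centers = spec.pixel_centers()
rim = np.abs(centers) > 0.9
core = np.abs(centers) < 0.3

interior = rmap.base_point + 0.4 * (rmap.vertices[::4] - rmap.base_point)
w = rmap.forward(interior)
rt = np.abs(np.asarray(rmap.inverse(w)) - interior).max()

print(f"wing area: {wing_area(mask)} px mapped onto {int(disc.valid.sum())} disc pixels")
print(f"forward/inverse round-trip error at interior points: {rt:.1e} px")
print(f"area distortion (source px per unit disc area): "
      f"center median {np.nanmedian(field[core]):.0f}, rim median {np.nanmedian(field[rim]):.0f}, "
      f"rim max {np.nanmax(field[rim]):.0f}")
# Distortion is strongly position dependent: the elongated wing tips are
# compressed onto few rim pixels (rim max far above the center level),
# which is how the conformal representation down-weights boundary shape
# relative to interior vein pattern.
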