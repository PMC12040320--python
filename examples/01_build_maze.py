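"""Build the standard city-block maze and query its layout.

Six square blocks in a 2x3 grid inside a walled platform leave 17
alleys (9 vertical, 8 horizontal) and 12 intersections; collinear
alleys form 7 corridors.
"""

from placerep import build_standard_maze, region_lookup, same_corridor

geom = build_standard_maze()
n_v = sum(a.orientation == "vertical" for a in geom.alleys)
print(f"alleys: {len(geom.alleys)} ({n_v} vertical, {len(geom.alleys) - n_v} horizontal)")
print(f"intersections: {len(geom.intersections)}")
print(f"corridors: {len(geom.corridors)}")
print(f"walkable bins at {geom.bin_size_cm:.1f} cm: {geom.n_bins_walkable}")

center_alley = geom.alleys[4]
x, y = center_alley.rect.center
print(f"point ({x:.1f}, {y:.1f}) cm lies in region {region_lookup(geom, x, y)}")
print("V00 and V02 collinear (same corridor):", same_corridor(geom, "V00", "V02"))
print("V00 to V22 alley-graph distance:", geom.alley_graph_distance("V00", "V22"), "alleys")
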