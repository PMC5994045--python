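"""Historical-range estimation: MCP over occurrences, habitat clip, buffers.

A synthetic fixture provides occurrence points whose convex hull is a known
200 x 100 km rectangle and a habitat polygon covering its left half, so the
truth is exact: MCP 20,000 km2, clipped potential range 10,000 km2.
"""

from declinomics import rangegeo, synthio

fixture = synthio.gen_range_fixture(seed=4)

scenarios = [
    rangegeo.RangeScenario(
        name=f"buffer_{int(b)}m",
        points=fixture.points,
        habitat=fixture.habitat,
        buffer_distance_m=b,
        extant_area_km2=500.0,
    )
    for b in (0.0, 500.0, 1_000.0, 5_000.0)
]
table = rangegeo.scenario_table(scenarios)
print(table.to_string(index=False))
# potential_area_km2 grows with the buffer distance (forest-edge dilation);
# occupancy_percent is the 500 km2 extant range over each potential range.
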