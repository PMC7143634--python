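"""Generate a synthetic city and look at its pieces.

Builds a seeded 12x12 jittered street grid with 3 fire stations and
clustered monthly incidents, then prints the basic element counts a real
dataset of this kind would have.
"""

import fireshed as fs

features, stations, incidents = fs.fixture_city(
    seed=7, rows=12, cols=12, n_stations=3, n_hotspots=2, months=6)

g = fs.build_topology(features)
print(f"street network: {len(g.edges)} edges, {len(g.nodes)} intersections, "
      f"{g.total_length/1000:.1f} km")
print(f"stations      : {len(stations)} (ids {[s for s, _, _ in stations]})")
print(f"incidents     : {len(incidents)} over "
      f"{incidents['date'].dt.to_period('M').nunique()} months")

# every incident lies exactly on a street
dmax = max(fs.project_to_network((r.x, r.y), g)[1]
           for r in incidents.itertuples())
print(f"largest incident-to-street distance: {dmax:.2e} m "
      "(generated on-network by construction)")
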