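"""Panel calibration and the 14 vegetation indices.

Calibrates raw digital numbers against the grey reference panel, then
computes all supported vegetation indices for one canopy spectrum.
Higher NDRE/RERVI signal denser, greener (better-fertilised) canopy.
"""

import indicot as ic
from indicot.spectral import PanelReference

# panel digital numbers recorded by the sensor during the calibration pass
panel = PanelReference(digital_number={b: 30000.0 for b in ic.BAND_NAMES})
dns = {"blue": 2500, "green": 5200, "red": 3100, "red_edge": 12000, "nir": 21000}
bands = {b: ic.empirical_line_calibrate(dns[b], panel, b) for b in ic.BAND_NAMES}
print("calibrated reflectance:", {b: round(v, 4) for b, v in bands.items()})

vis = ic.compute_all_vis(bands)
for name in ("NDVI", "NDRE", "RERVI", "MRETVI", "OSAVI"):
    print(f"{name:8s} {vis[name]: .4f}")
# NDVI near 0.7 indicates a well-developed canopy; NDRE ~0.2-0.3 a healthy
# chlorophyll (nitrogen) level for cotton at mid-season.
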