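"""Collimator-angle optimization on the island-blocking worked example.

Two 10x10 mm targets separated by a 30 mm gap along BEV X: at collimator 0
every spanning leaf pair must stay open across the gap (500 mm^2); rotating
the collimator 90 deg aligns the separation with the leaf travel and the
gap closes (200 mm^2).
"""

import numpy as np

from vmatgeo import Arc, Lesion, get_machine, scan_collimator

lesions = [
    Lesion("left", "left", np.array([[x, y, z] for x in (-25, -15)
                                     for y in (-1, 1) for z in (-5, 5)], float)),
    Lesion("right", "right", np.array([[x, y, z] for x in (15, 25)
                                       for y in (-1, 1) for z in (-5, 5)], float)),
]
machine = get_machine("HD120")
static_beam = Arc("static", couch_deg=0, gantry_start_deg=0, gantry_stop_deg=0,
                  direction="CW", full=True)

scan = scan_collimator(lesions, [0, 0, 0], static_beam, machine,
                       gantry_step_deg=360, coll_step_deg=5)

areas = dict(zip(scan.angles_deg, scan.total_areas_mm2))
print(f"aperture area at collimator   0 deg: {areas[0.0]:6.1f} mm^2")
print(f"aperture area at collimator  90 deg: {areas[90.0]:6.1f} mm^2")
print(f"optimal collimator angle: {scan.best_angle_deg:g} deg "
      f"(smallest summed MLC opening area)")
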