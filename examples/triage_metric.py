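"""Shrapnel-proximity triage on hand-built detections.

One image with all four classes detected: midpoint distances from the
shrapnel box to vein/artery/nerve are computed with the Euclidean
distance formula, the minimum is the triage distance, and a set of
such records is gated against multiples of the average artery box
size (the reference diameter).
"""

from shrapod import BBox, Detection
from shrapod.triage import gate, reference_diameter, triage_image

dets = [
    Detection(BBox(0, 0, 10, 10, "shrapnel"), 0.9),   # midpoint (5, 5)
    Detection(BBox(25, 35, 10, 10, "vein"), 0.8),     # midpoint (30, 40)
    Detection(BBox(55, 75, 10, 10, "artery"), 0.8),   # midpoint (60, 80)
    Detection(BBox(1, 8, 10, 10, "nerve"), 0.8),      # midpoint (6, 13)
]
record = triage_image(dets, image_id=0)
print(f"d_vein   = {record.d_vein:6.2f} px")
print(f"d_artery = {record.d_artery:6.2f} px")
print(f"d_nerve  = {record.d_nerve:6.2f} px")
print(f"triage distance = {record.d_min:.2f} px (closest: {record.closest})")

# Gate a population of records against the artery reference size.
ref = reference_diameter([BBox(0, 0, 70, 70, "artery"),
                          BBox(0, 0, 80, 80, "artery")])
print(f"\nreference artery diameter = {ref:.0f} px")
# Move only the shrapnel further away to vary the triage distance.
population = [record] + [
    triage_image([Detection(d.box.translate(dx, dx), d.confidence)
                  if d.label == "shrapnel" else d for d in dets], image_id=i)
    for i, dx in enumerate([40, 90, 150], start=1)
]
summary = gate(population, ref)
for m, pct in summary.flagged_pct.items():
    print(f"  flagged at {m:4.2f} x ref (<{m * ref:5.1f} px): {pct:5.1f}%")
# The flagged fraction can only grow as the gate multiplier widens.
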