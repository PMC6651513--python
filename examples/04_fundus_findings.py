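"""Segment vessels, localize the optic disc and extract hard exudates.

Runs the fundus branch on an ME phantom: the TMAX tensor fusion
(elementwise max of Txx and Tyy) highlights vessels of every
orientation; the disc is the brightest disc-shaped region; exudates are
small bright blobs away from both.
"""

import numpy as np

from retfuse import PhantomSpec, dice, generate_fundus_phantom
from retfuse.pipeline import analyze_fundus
from retfuse.synthetic import DEFAULT_FUNDUS_SHAPE

scan, truth = generate_fundus_phantom(
    PhantomSpec(shape=DEFAULT_FUNDUS_SHAPE, label="me", seed=13)
)
findings = analyze_fundus(scan)

print(f"vessel dice vs truth:  {dice(findings.vessels, truth.vessels):.3f}")
print(f"exudate dice vs truth: {dice(findings.exudates, truth.exudates):.3f}")
tr, tc, _ = truth.disc
if findings.disc:
    dr, dc, rad = findings.disc
    print(f"disc found at ({dr}, {dc}), truth ({tr}, {tc}), "
          f"error {np.hypot(dr - tr, dc - tc):.1f} px")
print(f"exudate mask disjoint from vessels: {not (findings.exudates & findings.vessels).any()}")
# Vessel and disc knowledge is what keeps bright vessel reflexes and the
# disc itself out of the exudate mask.
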