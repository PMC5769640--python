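"""Quick-look hovering-plate benchmark (reduced resolution).

A flat plate (chord 23.85 mm) sweeps sinusoidally through still mineral oil
inside a closed tank at f = 0.25 Hz, pivot radius 0.1625 m, stroke
amplitude 23.5 degrees, pitching 45 degrees from vertical at mid-stroke.
The cycle-averaged lift coefficient and resistive drag coefficient are the
package's quantitative anchors (benchmark values ~0.82 and ~1.33; the full
coarse preset, used by scripts/acceptance.py, runs at 256^2).

This example uses a 96^2 grid so it finishes in well under a minute; expect
the lift to read low at this resolution.
"""

import wingflow as wf
from wingflow import analysis

case = wf.validation_case("coarse", nx=96, ny=96)
records, _ = wf.run_case(case)

window = case.record_window
cl = analysis.CoefficientSeries.from_records(records, "CL")
cd = analysis.CoefficientSeries.from_records(records, "CD")
mean_cl = analysis.time_average(cl, window)
mean_cd = analysis.time_average(cd, window)

print(f"grid {case.nx}x{case.ny}, {case.n_cycles:g} cycles, "
      f"window tau in [{window[0]}, {window[1]})")
print(f"mean C_L = {mean_cl:.3f}   (benchmark ~0.82; grid-limited here)")
print(f"mean C_D = {mean_cd:.3f}   (benchmark ~1.33, resistive convention)")
# C_D converges quickly with grid (pressure drag on a bluff plate); C_L is
# carried by the leading-edge vortex and needs the finer preset grids.
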