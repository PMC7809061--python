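"""Render edge stimuli on the mechanoreceptor grid.

Builds an oriented-edge template and the two stimulus movies (a 300 ms
indentation and a 550 ms scan) and prints their basic geometry.  The
template value is 1 on the edge line and falls off as a Gaussian of the
perpendicular distance (width w = 0.05 normalized units = 0.3 mm).
"""

import numpy as np

from tactilesnn import edge_template, make_indent_movie, make_scan_movie
from tactilesnn.stimulus import NOISELESS, ScanTrajectory

tpl = edge_template(theta_deg=30.0)
above_half = (tpl.values > 0.5).sum()
print(f"edge template at 30 deg: {tpl.grid.n_sites} mechanoreceptors, "
      f"{above_half} within the half-maximum band")

indent = make_indent_movie(tpl, noise=NOISELESS)
print(f"indent movie: {indent.n_steps} frames of {indent.frames.shape[1]} sites "
      f"({indent.duration_ms:.0f} ms at dt = {indent.dt_ms} ms)")
peak = indent.frames[1500]
print(f"  peak force during hold: {peak.max():.1f} (arbitrary units); "
      f"ramp midpoint is half of that: {indent.frames[250].max():.1f}")

scan = make_scan_movie(tpl, ScanTrajectory(), noise=NOISELESS)
t_half = scan.meta["ramp_on_ms"] + 250.0
print(f"scan movie: {scan.n_steps} frames; edge moves 24 mm/s, so after "
      f"{t_half:.0f} ms it has crossed {ScanTrajectory().offset_mm(np.array([t_half]))[0]:.1f} mm "
      "of the 12 mm patch")
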