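"""Run the full RT-QIBC chain on one synthetic imaging site.

Simulates a site, renders live and fixed images through the camera
model, corrects, segments, quantifies, tracks, annotates events,
registers the fixed snapshot (shifted by a plate-replacement offset)
back to the live movie, matches fixed cells to their own tracks, and
prints event-aligned records.
"""

import numpy as np

from rtqibc import SimConfig
from rtqibc.pipeline import run_rtqibc_site

config = SimConfig(field_size_px=(300, 300), n_cells_initial=25, n_frames=60, seed=8)
result = run_rtqibc_site(config, noise=True, fixed_offset_px=(12.0, -7.0))

print(f"registration recovered offset {result.registration_offset} (true (12, -7))")
print(f"matched fixed cells: {len(result.records)} of {len(result.fixed_truth)} at fixation")
rec = result.records
s_cells = rec[np.isfinite(rec["time_since_s_entry_min"])]
print(f"records with an annotated S entry: {len(s_cells)}")
cols = ["track_id", "match_distance_px", "time_since_s_entry_min", "CDT1IF_median", "EDU_total"]
print(s_cells[cols].head().round(2).to_string(index=False))
print("Each row is one fixed cell joined to its own live history: its")
print("end-point stains indexed by minutes since its S-phase entry.")
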