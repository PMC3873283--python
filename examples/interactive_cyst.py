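"""Rescue a failed trace over a large cystoid lesion with one grader pick.

A phantom with a large fluid-filled cyst elevating the inner retinal
surface reproduces the classic failure of unguided boundary tracing: the
shortest path refuses the climb over the domed roof and shortcuts along
the strong fluid/retina edge at the lesion base. Adding a single must-pass
pick at the dome apex re-routes the path over the roof, restoring
sub-pixel accuracy across the whole scan width — the interactive loop a
human grader would drive.
"""

import numpy as np

from octseg import ConstraintSet, InteractiveSession, default_profiles
from octseg.phantom import generate_bscan, surface_cyst_phantom

spec, apex_col = surface_cyst_phantom(seed=0)
image, _ = generate_bscan(spec)
truth = spec.truth["ILM"]
profiles = default_profiles()

session = InteractiveSession(image, profiles["ILM"])
free = session.segment()
err = free.boundary.positions - truth
half = 66
print(
    f"unguided trace: mean |error| over the lesion span "
    f"= {np.nanmean(np.abs(err[apex_col - half:apex_col + half])):.1f} px"
)

# the grader clicks the edge candidate at the top of the cyst
cand_rows = np.nonzero(session.candidates.segment_ids[:, apex_col] > 0)[0]
apex_row = int(cand_rows[np.argmin(np.abs(cand_rows - truth[apex_col]))])
print(f"grader pick: column {apex_col}, row {apex_row}")

pinned = session.segment(ConstraintSet(must_pass=[(0, apex_row, apex_col)]))
err2 = pinned.boundary.positions - truth
print(
    f"after one pick: full-width RMSE = {np.sqrt(np.nanmean(err2 ** 2)):.3f} px "
    f"(re-route #{pinned.iterations})"
)
print(
    "\nThe unguided path sits tens of pixels below the true inner surface "
    "over the cyst;\none constraint pins the apex and the re-routed path "
    "follows the roof within a pixel everywhere."
)
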