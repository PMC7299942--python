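"""Concatenate split acquisition sessions and undo per-frame drift.

Serial FIB-SEM imaging sometimes stops and resumes, leaving two stacks that
must be concatenated; consecutive frames also drift laterally by a few
pixels.  Alignment shifts each frame onto its predecessor at the integer
offset that maximizes their mutual information, within a small bound
(0.5% of the frame size, the conventional "small" setting).
"""

import numpy as np

import stereogold as sg
from stereogold.preprocessing import _shift_frame

rng = np.random.default_rng(0)
yy, xx = np.mgrid[:200, :200]
frame = np.clip(120 + 80 * np.sin(xx / 6.0) * np.cos(yy / 9.0)
                + rng.normal(0, 6, (200, 200)), 0, 255).astype(np.uint8)

# two sessions: 3 + 2 frames, with known drifts applied
session1 = sg.ImageStack(np.stack([frame,
                                   _shift_frame(frame, 1, 0),
                                   _shift_frame(frame, 1, -1)]),
                         voxel_size=(2.43, 2.43, 15.0))
session2 = sg.ImageStack(np.stack([_shift_frame(frame, 0, 1),
                                   _shift_frame(frame, -1, 1)]),
                         voxel_size=(2.43, 2.43, 15.0))

stack = sg.concatenate_stacks([session1, session2])
print(f"concatenated stack: {stack.n_frames} frames "
      f"({session1.n_frames} + {session2.n_frames})")

aligned, result = sg.align_stack_translation(stack, max_translation_fraction=0.005)
print("per-frame offsets applied (row, col):")
for k, (dy, dx) in enumerate(result.offsets):
    print(f"  frame {k}: ({dy:+d}, {dx:+d})")
print()
print("Frame 0 is the fixed reference; each following offset is the shift "
      "that best re-registers that frame onto the aligned one before it — "
      "the negatives of the drifts that were applied above.")
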