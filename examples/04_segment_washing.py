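"""Segment washing on a hand-made probability field.

Washing sums the per-voxel softmax scores over each segment and assigns the
class with the highest total to all of the segment's voxels — per-voxel
label noise inside a segment is voted away, and the output is homogeneous
along the vessel tree.
"""

import numpy as np

from arterylabel import SoftmaxVolume, VolumeGrid, argmax_labels, segment_wash

# one 5-voxel segment, two artery classes (1 and 2) plus background (0)
probs = np.zeros((3, 5, 1, 1), dtype=float)
probs[:, 0, 0, 0] = [0.1, 0.6, 0.3]   # voxel votes: class 1
probs[:, 1, 0, 0] = [0.1, 0.3, 0.6]   # class 2
probs[:, 2, 0, 0] = [0.1, 0.5, 0.4]   # class 1
probs[:, 3, 0, 0] = [0.1, 0.2, 0.7]   # class 2
probs[:, 4, 0, 0] = [0.1, 0.25, 0.65] # class 2
field = SoftmaxVolume(probs, (1.0, 1.0, 1.0))
seg_ids = VolumeGrid(np.ones((5, 1, 1), dtype=np.int32))

plain = np.asarray(argmax_labels(field).data).ravel()
washed = np.asarray(segment_wash(field, seg_ids).data).ravel()

sums = probs.sum(axis=(1, 2, 3))
print("per-voxel argmax:   ", plain, " (heterogeneous)")
print("per-class sums:     ", np.round(sums, 2))
print("washed labels:      ", washed, f" (all {washed[0]}: the class with "
      "the highest total softmax)")
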