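"""The classical baseline: a random forest classifying voxels one by one.

Features are the image intensity, the vessel-channel radius value and the
normalized voxel coordinates; 50 trees, an equal number of voxels per class
sampled from each subject.  With explicit coordinates the forest localizes
easily on phantoms — but it has no notion of shape or context, which is
what the convolutional model adds on real data.
"""

import numpy as np

from arterylabel import (aggregate_labels, build_detailed_taxonomy,
                         generate_cohort, prepare_subject, rf_baseline,
                         scores, voxel_confusion)

subjects = generate_cohort(6, {"A": 6}, base_seed=3)
preps = [prepare_subject(s, "aggregated") for s in subjects]
train, test = preps[:5], preps[5:]

clf = rf_baseline([(p.subject.image, p.vessel, p.gt) for p in train],
                  per_class_voxels=200, trees=50, seed=0)

prep = test[0]
pred = clf.predict_labels(prep.subject.image, prep.vessel)
rep = scores(voxel_confusion(prep.gt, pred, n_classes=13))
print(f"held-out voxel-wise mF1 {rep.mf1:.3f}, bAcc {rep.bacc:.3f} "
      f"({rep.n_skipped_classes} classes without support skipped)")
print(rep.per_class.to_string())
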