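"""Train the multi-scale classifier on a small phantom cohort and evaluate.

A deliberately small run (8 subjects, 5 epochs, several minutes on one CPU):
it demonstrates the full loop — cohort, geometry, dual-scale patches,
training, whole-volume tiled prediction, washing, voxel- and segment-wise
scores — not a converged model; see scripts/acceptance.py for the full
desk-scale experiment.
"""

from arterylabel import run_experiment

res = run_experiment(n_subjects=8, n_test=2, tag_counts={"A": 4, "B": 4},
                     constellation="aggregated", input_mode="image+vessel",
                     per_segment=4, epochs=5, seed=0)

print(f"trained on {res.n_train_patches} dual-scale patches")
print(res.history.to_string(index=False))
print(f"\nheld-out voxel-wise  mF1 {res.voxel_plain.mf1:.3f}  "
      f"bAcc {res.voxel_plain.bacc:.3f}   (plain argmax)")
print(f"held-out voxel-wise  mF1 {res.voxel_washed.mf1:.3f}  "
      f"bAcc {res.voxel_washed.bacc:.3f}   (after segment washing)")
print(f"held-out segment-wise mF1 {res.segment.mf1:.3f}  "
      f"bAcc {res.segment.bacc:.3f}")
print("\nmF1 = unweighted mean per-class F1; bAcc = mean per-class recall;")
print("background and non-annotated classes are excluded from both")
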