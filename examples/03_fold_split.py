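"""Stratified 4-fold cross-validation at the study scale.

242 subjects in two strata (72 + 170): every fold holds out
floor(72/4) + floor(170/4) = 18 + 42 = 60 test subjects, the remaining 182
train; the 2 leftover subjects (72 mod 4 + 170 mod 4) appear in every
training set and never in a test set.
"""

from arterylabel import make_folds

subjects = [(f"a{i:03d}", "A") for i in range(72)] + \
           [(f"b{i:03d}", "B") for i in range(170)]
split = make_folds(subjects, k=4, seed=0)

for f, (train, test) in enumerate(split.folds):
    tags = [split.strata[s] for s in test]
    print(f"fold {f}: train {len(train):3d}  test {len(test):2d} "
          f"({tags.count('A')} A + {tags.count('B')} B)")

all_test = {s for _tr, te in split.folds for s in te}
print(f"\nsubjects never tested: {len(subjects) - len(all_test)} "
      "(the floor-division leftovers, always in training)")
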