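"""A miniature end-to-end grading run (~3 minutes).

Trains the identification net and a small grading net on phantoms of
the two extreme grades, then pushes held-out images through the full
chain: identification -> refinement -> ROI crop -> grading.  Prints the
predicted grade and the class probabilities for a few test cases.
"""

import numpy as np

from echograde import grade_net as gn
from echograde import phantom as ph
from echograde import pipeline as pl
from echograde import roi_net as rn

grades = ["3"] * 50 + ["5"] * 50
imgs, masks, labels = ph.render_batch(grades, seed=23, size=96)
labels = np.asarray(labels)
perm = np.random.default_rng(0).permutation(len(imgs))
imgs, masks, labels = imgs[perm], masks[perm], labels[perm]

roi = rn.build_roi_net(rn.RoiNetConfig(input_size=96, base_filters=8,
                                       transitional_filters=32, seed=0))
rn.train_roi_net(roi, (list(imgs[:80]), list(masks[:80])),
                 rn.TrainConfig(epochs=8, learning_rate=0.05, seed=0))

patches = [pl.extract_roi_patch(i, m, out_size=96) for i, m in zip(imgs[:80], masks[:80])]
grader = gn.build_g_cnn(gn.GNetConfig(input_size=96, base_filters=8,
                                      fc_sizes=(64, 32, 5), seed=0))
gn.train_g_cnn(grader, (patches, list(labels[:80])),
               rn.TrainConfig(epochs=4, learning_rate=0.03, lr_decay=0.9, seed=0))

models = pl.PipelineModels(roi=roi, grade=grader)
correct = 0
for i in range(80, 88):
    pred, inter = pl.run_pipeline(imgs[i], models, "Refined ROI-CNN")
    probs = ", ".join(f"{g}:{p:.2f}" for g, p in zip(gn.GRADE_VALUES, inter["probs"]))
    flag = "ok " if pred == labels[i] else "MISS"
    correct += pred == labels[i]
    print(f"{flag} true {labels[i]}  predicted {pred}   [{probs}]")
print(f"\n{correct}/8 correct on held-out extreme-grade phantoms")
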