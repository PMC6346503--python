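"""Generate a small phantom dataset and inspect its morphology gradient.

Writes 10 images + masks + manifest to ./phantom_demo and prints the
boundary-irregularity statistic (perimeter^2 / 4 pi area; 1.0 for a
perfect disk) per grade: it should increase from grade 3 (smooth oval)
to grade 5 (spiculated), which is exactly the signal the grading
network learns.
"""

import numpy as np

from echograde import phantom as ph

frame = ph.generate_dataset(n_per_grade=2, out_dir="phantom_demo", seed=42, size=96)
print(f"wrote {len(frame)} phantoms to ./phantom_demo")
print(frame.to_string(index=False))

rng = np.random.default_rng(0)
print("\nmean boundary irregularity (50 samples per grade):")
for grade in ph.GRADE_VALUES:
    vals = []
    for _ in range(50):
        spec = ph.sample_phantom_spec(grade, rng, size=96)
        _, mask, _ = ph.render_phantom(spec)
        vals.append(ph.shape_compactness(mask))
    print(f"  grade {grade}: {np.mean(vals):.2f}")
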