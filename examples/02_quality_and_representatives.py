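"""Flag a poorly clustered PWM and build a representative motif.

A cluster of ten related PWMs is contaminated with one random outlier.
The Z-score filter counts, for each PWM, how often the other members
find it dissimilar (Z < -1); the most-counted top 15% become removal
candidates and are removed when enough co-members support the flag.
The representative motif averages the surviving members in the
exemplar's coordinate frame.
"""

import numpy as np

from pwmclust import (FamilySpec, PWMCollection, assess_cluster,
                      generate_family, representative_motif,
                      similarity_matrix)
from pwmclust.synthetic import random_outlier_pwm

family, _ = generate_family(
    FamilySpec("TGACTCAT", n_members=10, concentration=50, name="FAM"),
    seed=4)
outlier = random_outlier_pwm("OUTLIER", 8, np.random.default_rng(99))
coll = PWMCollection(list(family) + [outlier])

S = similarity_matrix(coll)
report = assess_cluster(S, cluster_id="demo")
print(f"cluster of {report.n_members}: mean similarity "
      f"{report.mean_score:.3f}, label {report.label!r}")
print(f"low-Z counts: { {k: v for k, v in report.low_z_counts.items() if v} }")
print(f"candidates: {report.candidates}; removed: {report.removed}")

keep = coll.subset([m for m in report.members if m not in report.removed])
after = assess_cluster(S.submatrix(keep.names), "demo-filtered")
print(f"mean similarity after removal: {after.mean_score:.3f}")

rep = representative_motif(keep, anchor="FAM_1")
print(f"representative motif ({len(rep.pwm)} columns, "
      f"{len(rep.members)} members): consensus {rep.pwm.consensus()}")
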