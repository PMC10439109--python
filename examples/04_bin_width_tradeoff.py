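"""How bin width trades fidelity for speed at fixed tolerance.

The guaranteed linking tolerance is (tolerance - bin_width): finer bins
reproduce alignment-based scores exactly, coarser bins miss fragment pairs
near the tolerance edge. This sweep scores the same jittered spectrum pairs
at several bin widths and reports agreement with the precise aligned cosine
(score within 0.001 and identical match counts).
"""

import numpy as np

from blink import (
    SpectrumSet,
    aligned_cosine,
    perturb_pair,
    preprocess_set,
    random_library,
    score_sets,
)

TOL = 0.01
rng = np.random.default_rng(21)
q_raw = random_library(60, (6, 10), (50.0, 2000.0), min_spacing=0.025,
                       id_prefix="q", rng=rng)
r_raw = SpectrumSet(
    [perturb_pair(s, 1.0, jitter=0.009, intensity_noise=0.3,
                  new_id=f"r_{i:03d}", rng=rng) for i, s in enumerate(q_raw)],
    role="reference",
)
q, _ = preprocess_set(q_raw)
r, _ = preprocess_set(r_raw)
oracle = [aligned_cosine(q[i], r[i], TOL - 0.001) for i in range(len(q))]

print(f"{'bin width':>10} {'eff. tol':>9} {'agreement':>10}")
for bw in [1e-5, 1e-4, 1e-3, 2e-3, 5e-3, 1e-2]:
    res = score_sets(q, r, bin_width=bw, tolerance=TOL)
    agree = sum(
        abs(res.scores[i, i] - s) < 0.001 and res.matches[i, i] == m
        for i, (s, m) in enumerate(oracle)
    )
    print(f"{bw:>10g} {TOL - bw:>9g} {agree / len(q):>9.1%}")
print("\nagreement holds until the bin width erodes the effective tolerance")
print("below the m/z jitter of the data; 0.001 Da is the recommended default.")
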