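"""Analog search: finding a homolog whose every fragment is mass-shifted.

A methylene homolog (+14.016 Da on every fragment and the precursor) shares
no fragment m/z with the original spectrum, so the regular cosine is zero.
Scoring in neutral-loss coordinates (precursor m/z minus fragment m/z)
aligns the two perfectly; the combined result takes the better channel per
pair.
"""

from blink import SpectrumSet, analog_score_all, perturb_pair, preprocess_set, random_library

base = random_library(1, (8, 8), (80.0, 600.0), id_prefix="compound", seed=3)[0]
homolog = perturb_pair(base, shared_fraction=1.0, mass_shift=14.016,
                       new_id="compound_CH2", seed=4)

query, _ = preprocess_set(SpectrumSet([base]))
ref, _ = preprocess_set(SpectrumSet([homolog], role="reference"))

regular, shifted, combined = analog_score_all(query, ref, mode="precursor")

print(f"query:     {base.id} (precursor {base.precursor_mz:.4f})")
print(f"reference: {homolog.id} (precursor {homolog.precursor_mz:.4f})")
print(f"regular cosine:       {regular.scores[0, 0]:.4f}  matches {regular.matches[0, 0]}")
print(f"neutral-loss cosine:  {shifted.scores[0, 0]:.4f}  matches {shifted.matches[0, 0]}")
print(f"combined (max):       {combined.scores[0, 0]:.4f}  matches {combined.matches[0, 0]}")
print("\nthe homolog is invisible to the regular channel but scores 1.0 in")
print("neutral-loss coordinates: every precursor-to-fragment loss is identical.")
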