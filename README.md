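# blink — blur-and-link cosine scoring of tandem mass spectra

Spectral library search in metabolomics and proteomics rests on the cosine
similarity between MS/MS spectra: fragments of two spectra are aligned
within an m/z tolerance, and the dot product of their unit-normalized
intensity vectors scores how alike the compounds are. Conventional
implementations align each pair of spectra in a loop, which becomes the
bottleneck as libraries reach millions of spectra.

`blink` implements the blur-and-link approach: instead of aligning
fragments, every spectrum set is discretized into a sparse matrix over
fine integer m/z bins (rows = bins, columns = spectra), one side is
*blurred* with a uniform kernel that copies every occupied bin across a
tolerance-wide window, and a single sparse matrix product yields the
cosine scores of **all** query × reference pairs at once. A second product
over parallel fragment-count matrices yields matching-ion counts. With bin
width `b` and tolerance parameter `t` the kernel half-width is
`round(t / b) − 1` bins, so fragment pairs closer than the **effective
tolerance** `t − b` are always linked and pairs further apart than `t`
never are. At the defaults (`b` = 0.001 Da, `t` = 0.01 Da) the method
reproduces a loop-based aligned cosine at 0.009 Da tolerance, agreeing on
more than 99 % of scores and match counts on realistic data, and exactly
when fragments are tolerance-separated.

The package is aimed at people matching high-resolution centroided MS/MS
data against spectral libraries: it reads and writes MGF, supports analog
search (neutral-loss coordinates or any fixed mass shift), includes the
precise greedy-alignment cosine for ground truth and for rescoring top
hits, and ships a synthetic-spectrum generator so every property can be
validated without downloading reference libraries.

## Worked example

```python
import numpy as np
from blink import (SpectrumSet, classify_similar, hits_frame, perturb_pair,
                   preprocess_set, random_library, score_sets)

rng = np.random.default_rng(0)
query_raw = random_library(50, (6, 15), (50.0, 1200.0), id_prefix="q", rng=rng)
ref_raw = SpectrumSet(
    [perturb_pair(s, shared_fraction=0.8, jitter=0.004, intensity_noise=0.3,
                  new_id=f"r_{i:03d}", rng=rng)
     for i, s in enumerate(query_raw)], role="reference")

query, _ = preprocess_set(query_raw)   # noise filter, sqrt, unit-normalize
ref, _ = preprocess_set(ref_raw)
result = score_sets(query, ref, bin_width=0.001, tolerance=0.01)
print(hits_frame(result, min_score=0.7, min_matches=6).head(5))
```

which prints (see `examples/01_score_synthetic_library.py`):

```
scored 50 x 50 spectrum pairs
42 pairs called similar (score >= 0.7, matches >= 6)

top 5 hits (each query's planted partner should rank first):
query_id ref_id    score  matches
 q_00018  r_018 0.990852        8
 q_00043  r_043 0.953502        6
 q_00010  r_010 0.952801        8
```

Each row is one query/reference pair: `score` is the cosine of the
sqrt-scaled, unit-normalized intensity vectors with fragments linked
within tolerance, and `matches` is the number of linked fragment pairs.
Pairs with score ≥ 0.7 and ≥ 6 matching ions are the conventional
"similar" calls. The planted partners (80 % shared fragments, 0.004 Da
jitter) all rank first for their queries.

Other narrative examples in `examples/`:

- `02_analog_search.py` — a +14.016 Da homolog scores 0 in the regular
  channel but 1.0 in neutral-loss coordinates.
- `03_rescore_top_hits.py` — precise rescoring of a fast hit list removes
  borderline hits; the fast score never falls below the aligned cosine.
- `04_bin_width_tradeoff.py` — agreement with the aligned cosine stays at
  100 % until the bin width erodes the effective tolerance below the m/z
  jitter of the data.

## Command line

```sh
blink simulate --n 200 --seed 1 --out lib.mgf
blink score --query query.mgf --ref lib.mgf --bin-width 0.001 --tolerance 0.01 \
            --min-score 0.7 --min-matches 6 --out hits.tsv
blink rescore --hits hits.tsv --query query.mgf --ref lib.mgf --out precise.tsv
```

`blink score --analog precursor` adds the neutral-loss channel for analog
search; `--analog delta --delta 14.016` searches a fixed mass offset.

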