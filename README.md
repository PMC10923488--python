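# gazesal

Quantitative comparison of **human visual attention** with **deep-learning
saliency** on facial images of genetic conditions.

When clinicians assess a face for dysmorphic features, where do they look —
and does a classifier trained to recognise the same conditions "look" at the
same places?  `gazesal` implements the full analysis chain for answering
such questions with eye-tracking data: it turns fixation streams into
attention heat maps, removes the universal eyes/nose/mouth gaze bias,
computes occlusion-saliency maps for any plugged-in classifier, equalises
map coverage, and compares maps with IoU and symmetric KL divergence,
pooling per-image results with a random-effects meta-analysis.

Because raw eye-tracking recordings of this kind are rarely shareable, the
package ships a first-class synthetic-study generator with known ground
truth (group gaze profiles, per-participant idiosyncrasy, condition-specific
feature regions, and a deterministic prototype classifier ensemble), so the
entire pipeline is testable end to end.

## The quantities

For two maps \(x, y \ge 0\) on the same grid:

* **IoU** binarizes both maps (nonzero → 1) and returns
  \(|A \cap B| / |A \cup B| \in [0, 1]\).
* **Symmetric KL** restricts both maps to the union of their supports,
  rescales each to a probability distribution, and returns
  \(\tfrac12\,[\mathrm{KL}(p\|q) + \mathrm{KL}(q\|p)]\) in nats.

Saliency is the **occlusion** kind: a \(20\times20\) box is slid with stride
10 over the image; each placement zeroes the covered pixels and records the
drop in the classifier's probability for the target label (clipped at 0); a
pixel's saliency is the mean drop over the boxes covering it.  Before
comparison, a **coverage threshold** keeps only the top-ranked saliency
pixels so the saliency map has the same number of active in-face pixels as
the human map it is compared against.

Per-image uncertainties come from a participant-level bootstrap; per-image
estimates \(y_i\) with variances \(v_i\) are pooled by DerSimonian–Laird:
\(\tau^2 = \max\!\big(0, (Q - (k{-}1))/C\big)\), weights
\(w_i^* = 1/(v_i + \tau^2)\).

## Worked example

```sh
python examples/03_compare_groups.py
```

```
 low threshold (7.0% of face region): mean IoU 0.225, mean KL 13.08 nats
high threshold (3.5% of face region): mean IoU 0.139, mean KL 15.77 nats
```

The synthetic cohort gives clinicians part of their gaze budget on each
image's condition-specific feature while non-clinicians attend only the
landmarks.  At the low noise threshold (7% of the face region retained) the
groups still overlap substantially; restricting to peak attention (3.5%)
exposes their different priorities — IoU falls and KL rises.  And

```sh
python examples/04_response_table_statistics.py
```

recomputes the bundled published response counts: clinicians call images
affected/unaffected correctly 85.6% of the time versus 76.9% for
non-clinicians (Pearson χ², p = 0.0032).

The other examples cover single-map preprocessing (`01`), occlusion
saliency and coverage matching (`02`), and the full orchestrated study
(`05`).  The same orchestration is scriptable from the shell:

```sh
gazesal simulate study/ --seed 7
gazesal all study/ out/ --seed 7    # comparisons.csv, pooled.csv, ...
```

`out/` then contains the comparison table (IoU/KL ± bootstrap SD per image,
pair, and threshold level), the pooled random-effects rows, accuracy and
chi-square tables, per-participant self-consistency scores, and an
exclusion log accounting for every skipped cell.

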