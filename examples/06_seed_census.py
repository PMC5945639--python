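"""Seed-count census against the exhaustive random-word null.

Counts a seed word's (overlapping) occurrences over all UTRs and places the
count within the distribution of all 16,384 same-length words.  Negative z
means the seed is rarer than a typical 7mer (depleted); positive z means it
has been accumulated.
"""

import numpy as np

from ripuse import MIR100_5P, depletion_score
from ripuse.sites import SiteType

rng = np.random.default_rng(5)
bases = np.array(list("ACGT"))
word = MIR100_5P.site_words()[SiteType.SEVENMER_M8]

# construct a UTR set from which the seed word has been excluded
depleted = {}
i = 0
while len(depleted) < 300:
    seq = "".join(rng.choice(bases, size=500))
    if word not in seq:
        depleted[f"t{i}"] = seq
    i += 1

s = depletion_score(depleted, MIR100_5P, SiteType.SEVENMER_M8)
print(f"excluded-word set : observed {s.observed}, null mean {s.null_mean:.1f} "
      f"+- {s.null_sd:.1f}, z = {s.z:.2f}, percentile {s.percentile:.1f}")

# plant the word three times per transcript instead
tripled = {t: q[:50] + word + q[60:250] + word + q[260:450] + word + q[460:]
           for t, q in depleted.items()}
s2 = depletion_score(tripled, MIR100_5P, SiteType.SEVENMER_M8)
print(f"triple-planted set: observed {s2.observed}, z = {s2.z:.2f}")
# A strongly negative z reproduces a depleted seed; a large positive z a
# seed accumulated across the transcriptome.
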