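"""Vote cross-sample consensus EMFs (sudo_EMFs) from the per-sample candidates.

Determines per-labeling-group m/z cutoffs, extracts sudo_EMFs by iterative
highest-score formula seeding, rescues profile-matching samples, filters
isotopologues by cross-sample m/z spread, merges sudo_EMFs sharing >= 50% of
their peaks, and votes lipid categories.  Writes sudo_emfs.tsv.
"""

import collections
import importlib
import logging

if __name__ == "__main__":
    logging.basicConfig(level=logging.INFO)
    cfg = importlib.import_module("01_simulate_study").config()
    from lipidvote.pipeline import stage_vote

    sudos = stage_vote(cfg)
    cats = collections.Counter(s.category for s in sudos)
    print(f"{len(sudos)} sudo_EMFs; category counts: {dict(sorted(cats.items()))}")
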