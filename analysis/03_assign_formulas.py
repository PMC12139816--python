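"""Assign elemental formulas to the consensus peaks of every sample.

Enumerates the reduced formula cache (C<=60, H<=120, N<=3, O<=15, P<=2,
[M+H]+ m/z <= 1000), searches each sample's peaks for (formula, adduct)
seeds, extends isotopologue series per the sample's labeling scheme, and
keeps candidates with e-value <= 0.1.  Writes candidates.tsv/.json under
results/study/.
"""

import importlib
import logging

if __name__ == "__main__":
    logging.basicConfig(level=logging.INFO)
    cfg = importlib.import_module("01_simulate_study").config()
    from lipidvote.pipeline import stage_assign

    per_sample = stage_assign(cfg)
    n = sum(len(v) for v in per_sample.values())
    lipid_hits = sum(
        1
        for cands in per_sample.values()
        for c in cands
        if c.categories - {"NOT_LIPID", "NOT_CATEGORIZED"}
    )
    print(
        f"{n} candidates across {len(per_sample)} samples; "
        f"{lipid_hits} carry a lipid classification"
    )
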