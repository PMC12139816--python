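"""Differential and category-level statistics over the voted sudo_EMFs.

Median-normalizes IMF intensities per sample, imputes missing cells to half
the global minimum, sums IMFs per EMF (log2), fits the blocked moderated
linear model (condition + labeling + block group), computes fold changes as
the ratio of linear-scale averages, runs the exact sign-binomial category test
with Bonferroni correction, and writes the differential, category, and
weighted-correlation tables plus figures under results/study/.
"""

import importlib
import logging

if __name__ == "__main__":
    logging.basicConfig(level=logging.INFO)
    cfg = importlib.import_module("01_simulate_study").config()
    from lipidvote.pipeline import stage_stats

    res = stage_stats(cfg)
    cats = res["categories"]
    print(cats.to_string())
    sig = cats[cats.p_adj < 0.05]
    if len(sig):
        print(f"\ncategories enriched at adjusted p < 0.05: {', '.join(sig.index)}")
    print(f"EMFs with raw p <= 0.1 in the blocked model: "
          f"{int(res['differential'].significant.sum())} of {len(res['differential'])}")
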