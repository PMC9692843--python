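"""Overlap relations, threads, and the SI..PD agreement grouping.

Compares clustering runs pairwise through contingency (overlap) tables,
categorizes each overlap by Jaccard similarity, chains categorized
relations across three or more runs into threads, and condenses the six
proposed runs into the six-level agreement partition.
"""

import numpy as np

from testaclust import ClusteringRun, OverlapConfig
from testaclust.consensus import (agreement_grouping, all_pairwise_relations,
                                  combination_count, find_threads,
                                  relations_frame)

# Six runs over 12 images: four runs agree, one merges clusters, one is noisy.
ids = tuple(f"img{i}" for i in range(12))
base = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
merged = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1])
noisy = np.array([0, 1, 0, 0, 1, 1, 2, 1, 2, 2, 0, 2])


def run(code, labels, k):
    return ClusteringRun(code=code, method="kmeanspp",
                         representation="grayscale", k=k, labels=labels,
                         seed=0, image_ids=ids)


runs = [run("EG", base, 3), run("SG", base, 3), run("ET", base, 3),
        run("ST", base, 3), run("EC", merged, 2), run("SC", noisy, 3)]

config = OverlapConfig(report_floor=1)
relations, n_tables = all_pairwise_relations(runs, config)
print(f"pairwise tables: {n_tables} (C(6,2) = {combination_count(6, 2)})")
print(relations_frame(relations).head(6).to_string(index=False))

threads = find_threads(relations)
print(f"threads spanning >= 3 runs: {len(threads)}; longest spans "
      f"{max(t.runs_spanned for t in threads)} runs")

part = agreement_grouping(runs)
print("agreement counts:", part.counts)
# Images whose cluster-mates coincide in all six runs are SI (strongly
# identical); each run that disagrees about an image lowers its level, down
# to PD (possibly different) when no two runs agree.
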