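"""Positive controls and predicted-target enrichment.

Host genes (genes a miRNA is encoded within and co-transcribed with) should
correlate positively with their miRNA; a co-expressed gene block should rank
its resident miRNA first by cumulative score; and among predicted target
pairs ranked by prediction strength, the fraction of negative correlations
should rise with strength — but only for the titration statistic.
"""

import numpy as np
from scipy import stats

from mirconnect import correlate_panel, detectability_filter
from mirconnect.enrichment import prediction_ratio_curve
from mirconnect.signatures import host_pair_correlations, hox_cumulative_scores
from mirconnect.synthetic import enrichment_panel_config, generate, predictions_from_truth

cfg = enrichment_panel_config(seed=0)
ds = generate(cfg)
profiles = detectability_filter(ds.mirna_matrix, limit=cfg.detection_limit,
                                min_samples=30)
tables = correlate_panel(profiles, ds.mrna_matrices, ds.probe_map,
                         ds.mirna_matrix.sample_ids,
                         methods=("spcc", "dpcc"), seed=0)

_, counts = host_pair_correlations(ds.host_pair_table, tables, cutoff=0.2)
print(f"host-gene pairs with normalised sPCC > 0.2: "
      f"{counts['positive']} of {len(ds.truth.host_pairs)}")

scores, rankings = hox_cumulative_scores(ds.truth.hox_blocks, tables)
top = rankings["HOXSYN"][0]
print(f"gene-block cumulative ranking: top miRNA = {top} "
      f"(planted resident: {ds.truth.hox_mirna})")

preds = predictions_from_truth(ds.truth, seed=0)
k_grid = np.arange(50, 501, 50)
for column in ("spcc", "dpcc"):
    curve = prediction_ratio_curve(preds, tables, column=column)
    rho = stats.spearmanr(curve.ratios, -k_grid).statistic
    print(f"{column}: neg/pos ratio over top-50..500 predictions = "
          f"{np.round(curve.ratios, 1).tolist()}  (Spearman vs strength {rho:+.2f})")
print()
print("Only the summed statistic's ratio climbs with prediction strength; the")
print("direct statistic sees the planted titration-only targets as noise.")
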