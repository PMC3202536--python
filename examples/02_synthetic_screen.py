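"""Genome-wide correlation screen on a synthetic cell-line panel.

Generates a small panel with planted titration-shaped suppression, runs the
summed and direct statistics for every detectable miRNA against every gene
(collapsing microarray probes across platforms), and measures how well each
method recovers the planted suppressed genes in its negative correlator lists.
"""

from mirconnect import correlate_panel, detectability_filter
from mirconnect.enrichment import ks_one_sided, neg_pos_log2_ratios
from mirconnect.synthetic import SyntheticConfig, generate, truth_report

cfg = SyntheticConfig(
    seed=0, n_mirnas=24, n_genes=900, singleton_pool_size=600,
    n_platforms=2, probes_per_gene=(1, 2),
)
ds = generate(cfg)
profiles = detectability_filter(ds.mirna_matrix, limit=cfg.detection_limit,
                                min_samples=30)
print(f"panel: {cfg.n_samples} samples, {cfg.n_genes} genes on "
      f"{cfg.n_platforms} platforms; {len(profiles)} of "
      f"{ds.mirna_matrix.n_entities} miRNAs detectable in >=30 samples")

tables = correlate_panel(profiles, ds.mrna_matrices, ds.probe_map,
                         ds.mirna_matrix.sample_ids,
                         methods=("spcc", "dpcc"), seed=0)

report = truth_report(ds.truth, {"fingerprint": ds.truth.fingerprint,
                                 "tables": tables}, top_n=100)
print(f"planted suppressed genes found in top-100 negative lists:")
print(f"  summed statistic recall : {report['spcc_recall']:.2f}")
print(f"  direct statistic recall : {report['dpcc_recall']:.2f}")

rs = neg_pos_log2_ratios(tables, "spcc", cutoff=0.3, normalize=True)
rd = neg_pos_log2_ratios(tables, "dpcc", cutoff=0.3)
d, p = ks_one_sided(rs, rd)
print(f"per-miRNA log2(neg/pos) mean: sPCC {rs.mean():+.2f} vs dPCC {rd.mean():+.2f}")
print(f"one-sided KS (sPCC right-shifted): D = {d:.2f}, p = {p:.2g}")
print()
print("The summed statistic recovers several-fold more planted targets and its")
print("negative correlations outnumber positive ones, while the direct method")
print("hovers at a balanced ratio (log2 ~ 0).")
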