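"""The summed-Pearson titration statistic on a single miRNA-gene pair.

A gene that a miRNA suppresses only in the cells that express the miRNA highly
shows almost no correlation over the whole panel, because in low-expression
cells the gene is governed by other regulation.  Ranking samples by miRNA
expression and summing the Pearson correlation over nested top-expression
subsets ("patterns") concentrates on exactly the samples that carry signal.
"""

import numpy as np

from mirconnect import build_patterns, direct_pcc, randomized_spcc, summed_pcc

rng = np.random.default_rng(0)
n = 59

# miRNA expression (log2 scale) and its standardised form
x = rng.normal(size=n)
z = (x - x.mean()) / x.std()

# the gene: suppressed proportionally to z in the top half of expressers,
# noisy and offset (mean-matched so the global covariance cancels) elsewhere
t = np.quantile(z, 0.5)
active = z > t
gene = 0.5 * rng.normal(size=n)
gene[active] -= 1.5 * (z[active] - t)
gene[~active] += 1.5 * ((z[active] - t) * z[active]).sum() / z[~active].sum()
gene[~active] += 1.0 * rng.normal(size=(~active).sum())

patterns = build_patterns(x, min_size=30)
spcc = summed_pcc(x, gene, patterns)
dpcc = direct_pcc(x, gene)
rspcc = randomized_spcc(x, gene, seed=0)

print(f"patterns summed        : {patterns.n_patterns} (sizes 30..59)")
print(f"direct PCC (dPCC)      : {dpcc:+.3f}")
print(f"summed PCC (sPCC)      : {spcc:+.2f}  -> normalised {spcc / 30:+.3f}")
print(f"randomized sPCC (rsPCC): {rspcc:+.2f}  -> normalised {rspcc / 30:+.3f}")
print()
print("The direct correlation sits near zero: panel-wide, suppression is")
print("cancelled by the unrelated variation of low-expression samples.  The")
print("summed statistic is strongly negative because every pattern contains")
print("the high-expression samples where the suppression acts; randomizing")
print("the sample ordering (the negative control) destroys the effect.")
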