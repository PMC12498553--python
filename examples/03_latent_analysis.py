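"""Classify, embed and explain the latent features.

Random-forest classification of the exercise condition from latent
coordinates, a 2-D t-SNE embedding, sparse LASSO associations between
conditions and standardized features, and PCA contribution rankings.
"""

import numpy as np

from cardiovae import (
    SimConfig,
    VAEConfig,
    classify_latent,
    embed_tsne,
    extract_latent,
    generate_dataset,
    lasso_associations,
    pca_contributions,
    preprocess,
    train,
)
from cardiovae.preprocess import log_transform

data = generate_dataset(SimConfig(n_per_group=30, seed=42))
pp = preprocess(data)
params, _ = train(pp, VAEConfig(seed=42))
latent = extract_latent(pp, params)

report = classify_latent(latent, pp.groups(), seed=42)
print("one-vs-rest metrics per condition:")
print(report.metrics.round(3))
print(f"minimum metric: {report.min_metric:.3f}")

emb = embed_tsne(latent, seed=42, overlay=data.x["Lactate"].loc[latent.index])
print(f"\nt-SNE perplexity used: {emb.perplexity}")

# sparse associations on standardized log-metabolite + TPM features
feats = log_transform(data.x).join(data.y)
feats = (feats - feats.mean()) / feats.std(ddof=1)
assoc = lasso_associations(feats, data.group, regularization=0.01)
d_row = assoc.coefficients.loc["D"]
print("\nstrongest associations with condition D (high-intensity interval):")
print(d_row.reindex(d_row.abs().sort_values(ascending=False).index)[:5]
      .round(3).to_string())

ranking = pca_contributions(feats, top_n=5)
print(f"\ntop PCA feature contributions ({ranking.n_components} components):")
for name in ranking.top:
    print(f"  {name}: {ranking.scores[name]:.3f}")
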