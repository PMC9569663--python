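"""The centroid-targeted perturbation step and its parameter sweep.

Clusters an encoded seed set with K-means, contracts each point towards its
own cluster centroid (x* = x + s (c - x)), adds noise, and measures
valid-molecule yield across (s, noise) configurations through the decode gate.
"""

import numpy as np

import kinogen as kg
from kinogen.perturb import PerturbationConfig, perturb_cloud, sweep_parameters

families = kg.synthetic_data.make_scaffold_families(n_families=3, per_family_n=30, seed=0)
records = [r for recs in families.values() for r in recs]
embedder = kg.SurrogateEmbedder(records)
seeds = {fam: recs[:10] for fam, recs in families.items()}

latent = embedder.encode([r for recs in seeds.values() for r in recs])
cfg = PerturbationConfig(k=3, s=0.8, noise_level=5.0, seed=0)
perturbed, model = perturb_cloud(latent, cfg, np.random.default_rng(0))
shift = np.linalg.norm(perturbed - latent, axis=1)
print(f"k={cfg.k} clusters, s={cfg.s}, noise level {cfg.noise_level}")
print(f"mean latent displacement per molecule: {shift.mean():.3f} (unit-norm space)")

grid = [
    {"k": 3, "s": 0.8, "noise_level": 5.0},
    {"k": 3, "s": 0.2, "noise_level": 5.0},
    {"k": 3, "s": 0.8, "noise_level": 30.0},
]
df = sweep_parameters(seeds, embedder, grid, sweep_seeds=range(5))
summary = df.groupby(["s", "noise_level"])[["valid_yield", "unique_novel"]].median()
print()
print(summary.to_string())
print()
print("valid_yield = fraction of seeds whose decode gate accepted;")
print("unique_novel = distinct decoded molecules absent from the seed set.")
print("Stronger contraction (s=0.8) explores neighbouring scaffolds and so")
print("yields novel molecules; s=0.2 mostly decodes back to the seeds.")
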