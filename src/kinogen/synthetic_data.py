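"""Synthetic fixtures: scaffold-structured SMILES families, latent blobs and
labeled descriptor-style tables.

Every stage of the pipeline can be exercised offline with these generators.
Scaffold families imitate the structure of curated kinase-inhibitor sets —
each family shares one heteroaromatic core (simple hinge-binder-like rings
such as aminopyrimidines and quinazolines) decorated with enumerated
substituents, so within-family fingerprint similarity exceeds between-family
similarity.  Latent blobs provide point clouds with known cluster structure
for the K-means and perturbation layers, and labeled tables with tunable
class separability exercise the likelihood classifiers.  No statistical
fidelity to any real compound collection is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .molecules import Family, MoleculeRecord, canonicalize

# Heteroaromatic cores with one open attachment point ([*:1] marked as %99
# ring-closure-free handle via simple string substitution).  Each family uses
# one core; decorations substitute the {R} slot.
_SCAFFOLD_CORES: tuple[str, ...] = (
    "Nc1nccc(n1)C{R}",       # 2-aminopyrimidine, 4-methylene handle
    "c1ccc2ncncc2c1{R}",     # quinazoline-like
    "c1ccc2[nH]cnc2c1{R}",   # benzimidazole
    "Nc1ccnc(n1)N{R}",       # diaminopyrimidine
    "c1ccc2ncccc2c1{R}",     # quinoline
    "c1cnc2[nH]ccc2c1{R}",   # 7-azaindole
    "Nc1nc(ns1)C{R}",        # aminothiadiazole, methylene handle
    "c1ccc2occc2c1{R}",      # benzofuran
    "c1ccc2sccc2c1{R}",      # benzothiophene
    "Nc1nccc(n1)c1ccccc1{R}",  # phenyl-aminopyrimidine
)

_DECORATIONS: tuple[str, ...] = (
    "",
    "C",
    "CC",
    "CCC",
    "CCO",
    "CCN",
    "C(C)C",
    "CC(C)O",
    "CCOC",
    "CCCN",
    "C(=O)N",
    "C(=O)NC",
    "CC(=O)N",
    "OC",
    "OCC",
    "NC",
    "NCC",
    "CCl",
    "CF",
    "CCF",
    "CC#N",
    "CCNC",
    "COC",
    "CCCO",
    "C(=O)NCC",
    "CN(C)C",
    "CCN(C)C",
    "CCOCC",
    "CC(C)N",
    "CCCC",
)


@dataclass(frozen=True)
class BlobSpec:
    """Gaussian blob layout: k clusters in d dimensions, centers mutually
    ``separation`` apart (pairwise, by construction on scaled simplex axes),
    isotropic ``spread`` per dimension, ``per_blob_n`` points each."""

    k: int = 3
    d: int = 196
    per_blob_n: int = 50
    separation: float = 50.0
    spread: float = 1.0
    seed: int = 0


def make_scaffold_families(
    n_families: int = 3,
    per_family_n: int = 20,
    seed: int = 0,
    family_names: Sequence[Family] | None = None,
) -> dict[Family, list[MoleculeRecord]]:
    """Generate labeled scaffold families of valid, unique, canonical SMILES.

    Each family is one core decorated with ``per_family_n`` substituents
    (deterministically chosen under the seed).  At generation time the
    within-family mean pairwise Tanimoto similarity is asserted to exceed the
    between-family mean, so the fixture genuinely carries family structure.
    """
    if n_families < 1 or n_families > len(_SCAFFOLD_CORES):
        raise ValueError(f"n_families must be in [1, {len(_SCAFFOLD_CORES)}]")
    if per_family_n > len(_DECORATIONS):
        raise ValueError(f"per_family_n must be <= {len(_DECORATIONS)}")
    from .molecules import KINASE_FAMILIES

    names = list(family_names) if family_names else list(KINASE_FAMILIES[:n_families])
    rng = np.random.default_rng(seed)
    out: dict[Family, list[MoleculeRecord]] = {}
    for fi, fam in enumerate(names):
        core = _SCAFFOLD_CORES[fi % len(_SCAFFOLD_CORES)]
        decos = rng.permutation(len(_DECORATIONS))[:per_family_n]
        recs = []
        seen: set[str] = set()
        for j, di in enumerate(decos):
            smi = canonicalize(core.format(R=_DECORATIONS[di]))
            if smi is None:
                raise ValueError(f"scaffold expansion produced invalid SMILES for {fam}")
            if smi in seen:
                continue
            seen.add(smi)
            recs.append(MoleculeRecord(smi, f"{fam.value}_{j:03d}", fam))
        out[fam] = recs
    _assert_family_structure(out)
    return out


def _mean_tanimoto(fps_a, fps_b, same: bool) -> float:
    from rdkit import DataStructs

    vals = []
    for i, fa in enumerate(fps_a):
        for j, fb in enumerate(fps_b):
            if same and j <= i:
                continue
            vals.append(DataStructs.TanimotoSimilarity(fa, fb))
    return float(np.mean(vals)) if vals else 0.0


def _assert_family_structure(families: dict[Family, list[MoleculeRecord]]) -> None:
    """Within-family mean pairwise Tanimoto must exceed the between-family mean."""
    if len(families) < 2:
        return
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    fps = {
        fam: [gen.GetFingerprint(Chem.MolFromSmiles(r.smiles)) for r in recs]
        for fam, recs in families.items()
    }
    fams = list(fps)
    within = np.mean([_mean_tanimoto(fps[f], fps[f], True) for f in fams])
    between = np.mean(
        [
            _mean_tanimoto(fps[fams[i]], fps[fams[j]], False)
            for i in range(len(fams))
            for j in range(i + 1, len(fams))
        ]
    )
    if within <= between:
        raise AssertionError(
            f"scaffold fixture lacks family structure: within {within:.3f} <= between {between:.3f}"
        )


def make_latent_blobs(spec: BlobSpec) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian blobs at mutually distant centers; returns (matrix, labels).

    Centers sit at ``separation / sqrt(2)`` along distinct coordinate axes, so
    every pair of centers is exactly ``separation`` apart.
    """
    if spec.k < 1:
        raise ValueError("k must be >= 1")
    if spec.separation <= 0 or spec.spread <= 0:
        raise ValueError("separation and spread must be > 0")
    if spec.k > spec.d:
        raise ValueError("need k <= d for axis-aligned centers")
    rng = np.random.default_rng(spec.seed)
    centers = np.zeros((spec.k, spec.d))
    for i in range(spec.k):
        centers[i, i] = spec.separation / np.sqrt(2.0)
    points = []
    labels = []
    for i in range(spec.k):
        points.append(centers[i] + rng.normal(0.0, spec.spread, size=(spec.per_blob_n, spec.d)))
        labels.extend([i] * spec.per_blob_n)
    return np.vstack(points), np.asarray(labels, dtype=int)


def make_labeled_table(
    n_per_class: int = 200,
    n_features: int = 20,
    signal_columns: Sequence[int] = (0,),
    effect_size: float = 2.0,
    n_classes: int = 2,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
):
    """Descriptor-style table with tunable class separability.

    Signal columns are shifted by ``effect_size`` (in units of the unit noise
    std) between consecutive classes; all other columns are pure standard
    normal noise.  Returns a DataFrame with a ``target`` column, matching the
    layout :func:`kinogen.likelihood.train` consumes.
    """
    import pandas as pd

    if effect_size < 0:
        raise ValueError("effect size must be >= 0")
    rng = np.random.default_rng(seed)
    blocks = []
    for cls in range(n_classes):
        X = rng.standard_normal((n_per_class, n_features))
        for col in signal_columns:
            X[:, col] += effect_size * cls
        df = pd.DataFrame(
            X,
            columns=list(feature_names) if feature_names else [f"f{j}" for j in range(n_features)],
        )
        df["target"] = cls
        blocks.append(df)
    return (
        pd.concat(blocks, ignore_index=True)
        .sample(frac=1.0, random_state=seed)
        .reset_index(drop=True)
    )
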