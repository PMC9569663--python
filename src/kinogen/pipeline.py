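"""End-to-end orchestration and post-processing of generative runs.

The full generation path is: encode the seed molecules, split the latent
cloud with K-means, contract every point towards its own cluster centroid and
add noise, decode each perturbed location under the validity gate, then
annotate every surviving molecule with its kinase-inhibition likelihood.
Post-processing stages filter the raw output into nested subsets:

1. raw            — everything that passed the decode gate;
2. unique-novel   — duplicates collapsed by canonical SMILES, molecules
                    already present in the known sets removed;
3. high-likelihood — likelihood strictly above the configured threshold;
4. high-similarity — the top-N molecules whose best Tanimoto similarity to
                     the target-family reference set is strictly above the
                     similarity threshold.

Every generated molecule carries the family of the seed it was perturbed
from, so each stage can be attributed to origin families (stage report).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import embedding as emb
from .likelihood import predict_likelihood
from .molecules import (
    DESCRIPTOR_NAMES,
    Family,
    MoleculeRecord,
    compute_descriptors,
    descriptor_table,
)
from .perturb import PerturbationConfig, perturb_cloud


@dataclass
class GeneratedRecord:
    record: MoleculeRecord  # family=GENERATED, origin_family set
    multiplicity: int
    seed_id: str
    likelihood: float = float("nan")
    best_tanimoto: float = float("nan")
    nearest_reference: str = ""


@dataclass
class GeneratedSet:
    records: list[GeneratedRecord]
    n_gates: int = 0
    n_accepted: int = 0
    n_zero_validity: int = 0

    @property
    def smiles(self) -> list[str]:
        return [g.record.smiles for g in self.records]


def run_generation(
    seed_sets: Mapping[Family, Sequence[MoleculeRecord]],
    config: PerturbationConfig,
    embedder: emb.Embedder,
    classifier=None,
) -> GeneratedSet:
    """Run the generative pipeline on per-family seed molecules.

    Clustering is fit once on the union of all families' encodings, so the
    clusters reflect latent structure rather than the family labels.  All
    randomness derives from ``config.seed``; two runs under one seed produce
    identical output.  Zero accepted gates yield an empty set with
    diagnostics, never a failure.
    """
    all_records: list[tuple[Family, MoleculeRecord]] = [
        (fam, r) for fam, recs in seed_sets.items() for r in recs
    ]
    if not all_records:
        raise ValueError("no seed molecules supplied")
    recs = [r for _, r in all_records]
    latent = embedder.encode(recs)
    rng = np.random.default_rng(config.seed)
    perturbed, _ = perturb_cloud(latent, config, rng)

    out = GeneratedSet(records=[])
    for i, (fam, rec) in enumerate(all_records):
        gate = emb.decode_with_gate(
            embedder,
            perturbed[i],
            rng,
            seed_id=rec.id,
            attempts=config.attempts,
            min_valid=config.min_valid,
            min_len=config.min_len,
        )
        out.n_gates += 1
        if gate.zero_validity:
            out.n_zero_validity += 1
        if not gate.accepted:
            continue
        out.n_accepted += 1
        for j, (smi, mult) in enumerate(gate.decoded):
            out.records.append(
                GeneratedRecord(
                    record=MoleculeRecord(
                        smi,
                        f"gen_{rec.id}_{j:03d}",
                        Family.GENERATED,
                        origin_family=fam,
                    ),
                    multiplicity=mult,
                    seed_id=rec.id,
                )
            )
    if classifier is not None and out.records:
        feats = descriptor_table([g.record for g in out.records])
        probs = predict_likelihood(classifier, feats.to_numpy(dtype=float))
        for g, p in zip(out.records, probs):
            g.likelihood = float(p)
    return out


def dedupe_and_novelty(
    generated: GeneratedSet,
    known_sets: Mapping[Family, Sequence[MoleculeRecord]] | Sequence[MoleculeRecord],
) -> GeneratedSet:
    """Collapse duplicates by canonical SMILES and drop non-novel molecules.

    The decoder is stochastic, so identical molecules recur across seeds;
    the survivor of each duplicate group is the first record in generation
    order (deterministic tie-break), with multiplicities summed.  Novelty
    means absence from every supplied known set.
    """
    if isinstance(known_sets, Mapping):
        known = {r.smiles for recs in known_sets.values() for r in recs}
    else:
        known = {r.smiles for r in known_sets}
    survivors: dict[str, GeneratedRecord] = {}
    for g in generated.records:
        smi = g.record.smiles
        if smi in known:
            continue
        if smi in survivors:
            survivors[smi].multiplicity += g.multiplicity
        else:
            survivors[smi] = GeneratedRecord(
                record=g.record,
                multiplicity=g.multiplicity,
                seed_id=g.seed_id,
                likelihood=g.likelihood,
                best_tanimoto=g.best_tanimoto,
                nearest_reference=g.nearest_reference,
            )
    return GeneratedSet(
        records=list(survivors.values()),
        n_gates=generated.n_gates,
        n_accepted=generated.n_accepted,
        n_zero_validity=generated.n_zero_validity,
    )


def _morgan_fp(smiles: str):
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    return gen.GetFingerprint(Chem.MolFromSmiles(smiles))


def similarity_report(
    generated: GeneratedSet,
    reference: Sequence[MoleculeRecord],
    threshold: float = 0.6,
    top_n: int = 100,
) -> tuple[GeneratedSet, GeneratedSet]:
    """Annotate max Tanimoto similarity to a reference set; select the
    high-similarity stage.

    Each generated molecule gets its maximum Tanimoto coefficient over the
    reference fingerprints (hashed circular substructure, radius 2, 2048
    bits) and the arg-max reference id.  The high-similarity stage is the
    top ``top_n`` by score among molecules scoring strictly above
    ``threshold``; ties break by score descending then canonical SMILES.
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    from rdkit import DataStructs

    ref_fps = [(_morgan_fp(r.smiles), r.id) for r in reference]
    for g in generated.records:
        fp = _morgan_fp(g.record.smiles)
        sims = [DataStructs.TanimotoSimilarity(fp, rf) for rf, _ in ref_fps]
        best = int(np.argmax(sims))
        g.best_tanimoto = float(sims[best])
        g.nearest_reference = ref_fps[best][1]
    eligible = [g for g in generated.records if g.best_tanimoto > threshold]
    eligible.sort(key=lambda g: (-g.best_tanimoto, g.record.smiles))
    high = GeneratedSet(
        records=eligible[:top_n],
        n_gates=generated.n_gates,
        n_accepted=generated.n_accepted,
        n_zero_validity=generated.n_zero_validity,
    )
    return generated, high


def select_high_likelihood(generated: GeneratedSet, threshold: float = 0.7) -> GeneratedSet:
    """Molecules whose likelihood is strictly greater than the threshold."""
    return GeneratedSet(
        records=[g for g in generated.records if g.likelihood > threshold],
        n_gates=generated.n_gates,
        n_accepted=generated.n_accepted,
        n_zero_validity=generated.n_zero_validity,
    )


def stage_report(stages: Mapping[str, GeneratedSet]) -> pd.DataFrame:
    """Per-origin-family percentage of each stage's molecules.

    Rows are stages in the given order, columns origin families; each row
    sums to 100 (up to rounding).  An empty stage produces a zero row with a
    warning.
    """
    import warnings

    fams = sorted(
        {
            g.record.origin_family.value
            for s in stages.values()
            for g in s.records
            if g.record.origin_family
        }
    )
    rows = {}
    for name, s in stages.items():
        counts = {f: 0 for f in fams}
        for g in s.records:
            counts[g.record.origin_family.value] += 1
        total = sum(counts.values())
        if total == 0:
            warnings.warn(f"stage {name!r} is empty; reporting zeros")
            rows[name] = {f: 0.0 for f in fams}
        else:
            rows[name] = {f: 100.0 * c / total for f, c in counts.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=fams)


def property_profile(
    generated: GeneratedSet | Sequence[MoleculeRecord],
    reference: Sequence[MoleculeRecord] | None = None,
) -> pd.DataFrame:
    """Drug-likeness summary of a molecule set, optionally beside a reference.

    Reports mean QED / SAS / logP and the distribution summaries (mean, min,
    max) of hydrogen-bond acceptors and donors, molecular weight, aromatic
    rings and rotatable bonds for each group.
    """
    def _group(records: Sequence[MoleculeRecord], name: str) -> dict:
        df = descriptor_table(list(records))
        row = {"group": name, "n": len(df)}
        for col in ("qed", "sas", "logp"):
            row[f"mean_{col}"] = float(df[col].mean())
        for col in ("hba", "hbd", "exact_mol_weight", "aromatic_rings", "rotatable_bonds"):
            row[f"mean_{col}"] = float(df[col].mean())
            row[f"min_{col}"] = float(df[col].min())
            row[f"max_{col}"] = float(df[col].max())
        return row

    gen_records = (
        [g.record for g in generated.records]
        if isinstance(generated, GeneratedSet)
        else list(generated)
    )
    rows = [_group(gen_records, "generated")]
    if reference:
        rows.append(_group(list(reference), "reference"))
    return pd.DataFrame(rows).set_index("group")


def run_manifest(
    config: PerturbationConfig,
    stages: Mapping[str, GeneratedSet],
) -> str:
    """Deterministic JSON manifest of a run: configuration, per-stage counts
    and sorted per-stage molecule listings.  Byte-identical across runs under
    one master seed."""
    payload = {
        "config": asdict(config),
        "stages": {
            name: {
                "count": len(s.records),
                "n_gates": s.n_gates,
                "n_accepted": s.n_accepted,
                "n_zero_validity": s.n_zero_validity,
                "molecules": sorted(
                    (
                        {
                            "smiles": g.record.smiles,
                            "origin_family": g.record.origin_family.value
                            if g.record.origin_family
                            else "",
                            "multiplicity": g.multiplicity,
                            "likelihood": None
                            if np.isnan(g.likelihood)
                            else round(g.likelihood, 12),
                            "best_tanimoto": None
                            if np.isnan(g.best_tanimoto)
                            else round(g.best_tanimoto, 12),
                        }
                        for g in s.records
                    ),
                    key=lambda m: (m["smiles"], m["origin_family"]),
                ),
            }
            for name, s in stages.items()
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True)
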