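"""Encoder/decoder contract over a continuous latent space, plus the decode gate.

The pipeline only ever assumes a two-method contract: encode a batch of SMILES
into an n x d latent matrix, and attempt to decode one latent vector into a
SMILES string.  A wrapper around an external pre-trained chemical
variational autoencoder can satisfy the same contract; the bundled
:class:`SurrogateEmbedder` provides a deterministic, desk-scale stand-in so the
navigation and gating layer can be exercised offline.

Surrogate design
----------------
Encoding: a hashed circular-substructure (Morgan) fingerprint, 2048 bits,
radius 2, multiplied by a fixed seeded Gaussian random projection to d
dimensions (default 196) and L2-normalised.  Structurally similar molecules
share fingerprint bits, so their projections land close in latent space.

Decoding: a stochastic softmax-weighted nearest-neighbour lookup over an
encoded candidate library.  Each decode attempt first succeeds or fails a
validity draw whose success probability falls off with distance from the
library's data manifold (a Gaussian-kernel density score); a failed draw
emits an unparsable string, mimicking the dominant failure mode of decoding
low-density latent locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .molecules import MoleculeRecord, canonicalize, is_valid

LATENT_DIM = 196

#: Fixed seed of the surrogate's random projection; part of the embedder
#: definition, not a run parameter.
_PROJECTION_SEED = 0x5EED

#: Emitted by the surrogate decoder for a failed validity draw.  Unparsable
#: (unclosed ring), so it can never leak through the gate's validity check.
INVALID_DECODE = "C1CC"


class Embedder(Protocol):
    """Minimal encode/decode contract an external model adapter must satisfy."""

    d: int

    def encode(self, records: Sequence[MoleculeRecord]) -> np.ndarray: ...

    def decode_attempt(self, z: np.ndarray, rng: np.random.Generator) -> str: ...


def _morgan_bits(smiles: str, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot fingerprint invalid SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.asarray(gen.GetFingerprint(mol), dtype=np.float64)


class SurrogateEmbedder:
    """Deterministic fingerprint-projection embedder with a library decoder.

    Parameters
    ----------
    library : candidate molecules the decoder can emit.  Deduplicated by
        canonical SMILES on construction.
    d : latent dimensionality (196 to match the external model's space).
    temperature : softmax temperature on squared latent distances; smaller
        values concentrate decoding on the nearest library molecule.
    density_quantile, density_gamma : calibration of the validity model;
        see :meth:`valid_probability`.
    """

    def __init__(
        self,
        library: Sequence[MoleculeRecord],
        d: int = LATENT_DIM,
        n_bits: int = 2048,
        radius: int = 2,
        temperature: float = 0.01,
        density_quantile: float = 0.05,
        density_gamma: float = 4.0,
    ) -> None:
        if not library:
            raise ValueError("surrogate decoder needs a non-empty candidate library")
        self.d = int(d)
        self.n_bits = int(n_bits)
        self.radius = int(radius)
        self.temperature = float(temperature)
        self.density_gamma = float(density_gamma)
        rng = np.random.default_rng(_PROJECTION_SEED)
        self._projection = rng.standard_normal((n_bits, d)) / np.sqrt(d)
        seen: dict[str, MoleculeRecord] = {}
        for rec in library:
            seen.setdefault(rec.smiles, rec)
        self.library: list[MoleculeRecord] = list(seen.values())
        self._lib_latent = self.encode(self.library)
        # kernel bandwidth from the library's own nearest-neighbour scale
        from scipy.spatial.distance import pdist, squareform

        dmat = squareform(pdist(self._lib_latent))
        np.fill_diagonal(dmat, np.inf)
        nn = dmat.min(axis=1)
        self._bandwidth = float(np.median(nn[np.isfinite(nn)])) or 1.0
        self_density = self._density(self._lib_latent)
        self._density_ref = float(np.quantile(self_density, density_quantile))

    def encode(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        """n x d latent matrix, one L2-normalised row per record."""
        fps = np.stack([_morgan_bits(r.smiles, self.n_bits, self.radius) for r in records])
        z = fps @ self._projection
        norms = np.linalg.norm(z, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return z / norms

    def _density(self, z: np.ndarray) -> np.ndarray:
        """Mean Gaussian-kernel density of rows of z over the library cloud."""
        z = np.atleast_2d(z)
        d2 = (
            np.sum(z**2, axis=1)[:, None]
            - 2 * z @ self._lib_latent.T
            + np.sum(self._lib_latent**2, axis=1)[None, :]
        )
        return np.exp(-d2 / (2 * self._bandwidth**2)).mean(axis=1)

    def valid_probability(self, z: np.ndarray) -> float:
        """Per-attempt probability that decoding ``z`` yields a valid SMILES.

        ``min(1, (rho(z)/rho_ref)**gamma)`` with rho the library kernel
        density and rho_ref a low quantile of the library's self-densities:
        on-manifold points decode almost surely, off-manifold points collapse.
        """
        ratio = self._density(z)[0] / self._density_ref
        return float(min(1.0, ratio**self.density_gamma))

    def _neighbour_weights(self, z: np.ndarray) -> np.ndarray:
        d2 = np.sum((self._lib_latent - z) ** 2, axis=1)
        logits = -(d2 - d2.min()) / self.temperature
        w = np.exp(logits)
        return w / w.sum()

    def decode_attempt(self, z: np.ndarray, rng: np.random.Generator) -> str:
        """One stochastic decode attempt at fixed z."""
        if rng.random() >= self.valid_probability(z):
            return INVALID_DECODE
        idx = rng.choice(len(self.library), p=self._neighbour_weights(z))
        return self.library[idx].smiles

    def decode_counts(self, z: np.ndarray, attempts: int, rng: np.random.Generator) -> tuple[int, dict[str, int]]:
        """Vectorised equivalent of ``attempts`` calls to :meth:`decode_attempt`.

        Returns (number of valid attempts, multiplicity per decoded SMILES).
        """
        p_valid = self.valid_probability(z)
        n_valid = int(rng.binomial(attempts, p_valid))
        if n_valid == 0:
            return 0, {}
        counts = rng.multinomial(n_valid, self._neighbour_weights(z))
        return n_valid, {
            self.library[i].smiles: int(c) for i, c in enumerate(counts) if c > 0
        }


@dataclass
class GateResult:
    """Outcome of the decode-validity gate for one latent location."""

    seed_id: str
    attempts: int
    n_valid: int
    accepted: bool
    zero_validity: bool
    decoded: list[tuple[str, int]] = field(default_factory=list)


def decode_with_gate(
    embedder: Embedder,
    z: np.ndarray,
    rng: np.random.Generator,
    seed_id: str = "",
    attempts: int = 500,
    min_valid: int = 100,
    min_len: int = 10,
) -> GateResult:
    """Decode one latent vector ``attempts`` times under the validity gate.

    Each attempt's output is checked by canonicalisation; valid decodes are
    counted towards ``n_valid``, then strings shorter than ``min_len`` raw
    SMILES characters are dropped from the retained set.  The location is
    accepted when ``n_valid >= min_valid``; locations with zero valid decodes
    are flagged for exclusion.  A decoder failure on one attempt counts as an
    invalid attempt and never aborts the gate.
    """
    counts: dict[str, int]
    if hasattr(embedder, "decode_counts"):
        n_valid_raw, raw_counts = embedder.decode_counts(z, attempts, rng)
        # library SMILES are canonical already, but re-check defensively
        counts = {}
        n_valid = 0
        for smi, c in raw_counts.items():
            can = canonicalize(smi)
            if can is None:
                continue
            n_valid += c
            counts[can] = counts.get(can, 0) + c
    else:
        raw: dict[str, int] = {}
        for _ in range(attempts):
            try:
                out = embedder.decode_attempt(z, rng)
            except Exception:
                continue
            if isinstance(out, str):
                raw[out] = raw.get(out, 0) + 1
        # canonicalize each distinct output once; repeats are cheap tallies
        canon_map = {s: canonicalize(s) for s in raw}
        counts = {}
        n_valid = 0
        for s, c in raw.items():
            can = canon_map[s]
            if can is None:
                continue
            n_valid += c
            counts[can] = counts.get(can, 0) + c
    retained = sorted(
        ((smi, c) for smi, c in counts.items() if len(smi) >= min_len),
        key=lambda t: (-t[1], t[0]),
    )
    return GateResult(
        seed_id=seed_id,
        attempts=attempts,
        n_valid=n_valid,
        accepted=n_valid >= min_valid,
        zero_validity=n_valid == 0,
        decoded=retained,
    )
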