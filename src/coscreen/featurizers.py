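"""Drug and protein featurization.

Drugs become fixed-length Morgan fingerprint bit vectors (default 2048 bits,
radius 2).  Proteins become per-residue embedding matrices (L x E) produced
by a pluggable provider; the built-in ``toy`` provider is a seeded random
projection of residue identity plus a k-mer context window, so it is
context-sensitive, deterministic, and needs no learned weights.  Real
protein-language-model adapters register through the same interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import ConfigError, DataError

# 20 canonical residues + X for anything non-canonical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: sequences longer than this are truncated from the C-terminus
DEFAULT_MAX_LENGTH = 2048


def canonical_residue_index(aa: str) -> int:
    """Map a residue letter to its alphabet slot; non-canonical -> 'X'."""
    return _AA_INDEX.get(aa.upper(), _AA_INDEX["X"])


def sanitize_sequence(sequence: str, max_length: int = DEFAULT_MAX_LENGTH) -> str:
    """Uppercase, map non-canonical residues to X, truncate C-terminus."""
    seq = "".join(ALPHABET[canonical_residue_index(c)] for c in sequence.strip())
    if len(seq) > max_length:
        warnings.warn(
            f"sequence of length {len(seq)} truncated to {max_length} residues",
            stacklevel=2,
        )
        seq = seq[:max_length]
    return seq


@dataclass(frozen=True)
class DrugRecord:
    """A drug: identifier, SMILES, and its fingerprint bit vector."""

    drug_id: str
    smiles: str
    fingerprint: np.ndarray

    def __post_init__(self) -> None:
        fp = np.asarray(self.fingerprint, dtype=np.uint8)
        object.__setattr__(self, "fingerprint", fp)
        if fp.ndim != 1:
            raise DataError(f"fingerprint for {self.drug_id!r} must be 1-D")


@dataclass(frozen=True)
class TargetRecord:
    """A protein target: identifier, sequence, optional structure channel."""

    target_id: str
    sequence: str
    structure_tokens: Optional[str] = None
    coordinates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.structure_tokens is not None and len(self.structure_tokens) != len(
            self.sequence
        ):
            raise DataError(
                f"structure_tokens length {len(self.structure_tokens)} != "
                f"sequence length {len(self.sequence)} for {self.target_id!r}"
            )


@dataclass(frozen=True)
class ResidueEmbeddingMatrix:
    """Per-residue embedding matrix (L x E) for one target."""

    target_id: str
    values: np.ndarray
    provider_name: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2:
            raise DataError("embedding values must be a 2-D matrix")
        if not np.all(np.isfinite(vals)):
            raise DataError(f"non-finite embeddings for {self.target_id!r}")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def morgan_fingerprint(smiles: str, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Morgan (ECFP-like) fingerprint as a uint8 bit vector.

    Parameters mirror the conventional virtual-screening setup: 2048 bits,
    radius 2.  Chemically identical inputs (after canonicalization) map to
    identical fingerprints.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    if n_bits <= 0:
        raise ConfigError(f"n_bits must be positive, got {n_bits}")
    if radius < 0:
        raise ConfigError(f"radius must be non-negative, got {radius}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DataError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)


# ---------------------------------------------------------------------------
# Embedding provider registry
# ---------------------------------------------------------------------------

ProviderFn = Callable[[str, Optional[str]], np.ndarray]


@dataclass
class EmbeddingProvider:
    """A registered residue-embedding provider.

    ``fn(sequence, structure_tokens) -> (L, E) array``.  ``width`` is the
    provider's declared E; it is validated against the first matrix produced.
    """

    name: str
    fn: ProviderFn
    width: int
    _validated: bool = field(default=False, repr=False)


_REGISTRY: dict[str, EmbeddingProvider] = {}


def register_provider(name: str, fn: ProviderFn, width: int) -> EmbeddingProvider:
    """Register an embedding provider under a unique name."""
    if name in _REGISTRY:
        raise ConfigError(f"provider {name!r} is already registered")
    provider = EmbeddingProvider(name=name, fn=fn, width=width)
    _REGISTRY[name] = provider
    return provider


def get_provider(name: str) -> EmbeddingProvider:
    if name not in _REGISTRY:
        raise ConfigError(
            f"unknown provider {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


def unregister_provider(name: str) -> None:
    """Remove a provider (mainly for tests)."""
    _REGISTRY.pop(name, None)


def embed_residues(
    target: TargetRecord, provider: EmbeddingProvider | str
) -> ResidueEmbeddingMatrix:
    """Run a provider on one target, validating the L x E contract."""
    if isinstance(provider, str):
        provider = get_provider(provider)
    if len(target.sequence) == 0:
        raise DataError(f"empty sequence for target {target.target_id!r}")
    values = np.asarray(
        provider.fn(target.sequence, target.structure_tokens), dtype=np.float64
    )
    if values.ndim != 2 or values.shape[0] != len(target.sequence):
        raise DataError(
            f"provider {provider.name!r} returned shape {values.shape} for a "
            f"length-{len(target.sequence)} sequence"
        )
    if values.shape[1] != provider.width:
        raise DataError(
            f"provider {provider.name!r} declared width {provider.width} but "
            f"produced {values.shape[1]}"
        )
    provider._validated = True
    return ResidueEmbeddingMatrix(
        target_id=target.target_id, values=values, provider_name=provider.name
    )


# ---------------------------------------------------------------------------
# Built-in toy provider
# ---------------------------------------------------------------------------


class ToyEmbedder:
    """Deterministic stand-in for a protein language model.

    Each residue's embedding is the sum of a seeded random vector for its
    identity and one for its length-k context window (window centred on the
    residue, padded with X at the termini).  With k=1 the context collapses
    to the residue itself, making rows depend only on residue identity.
    Context tables are materialized from the seed so the same
    (seed, k, width, sequence) always yields bitwise-identical output.
    """

    def __init__(self, width: int = 64, k: int = 3, seed: int = 0):
        if width <= 0:
            raise ConfigError(f"width must be positive, got {width}")
        if k < 1 or k % 2 == 0:
            raise ConfigError(f"context size k must be a positive odd integer, got {k}")
        self.width = width
        self.k = k
        self.seed = seed
        n_letters = len(ALPHABET)
        rng = np.random.default_rng(np.random.SeedSequence([seed, width, k]))
        self._residue_table = rng.standard_normal((n_letters, width))
        # one row per possible k-mer over the closed alphabet (21**k)
        self._context_table = rng.standard_normal((n_letters**k, width))

    def __call__(self, sequence: str, structure_tokens: Optional[str] = None) -> np.ndarray:
        idx = np.array([canonical_residue_index(c) for c in sequence], dtype=np.int64)
        L = idx.shape[0]
        half = self.k // 2
        x_idx = _AA_INDEX["X"]
        padded = np.concatenate(
            [np.full(half, x_idx, dtype=np.int64), idx, np.full(half, x_idx, dtype=np.int64)]
        )
        # base-21 code of each window
        codes = np.zeros(L, dtype=np.int64)
        n_letters = len(ALPHABET)
        for j in range(self.k):
            codes = codes * n_letters + padded[j : j + L]
        return self._residue_table[idx] + self._context_table[codes]


def make_toy_provider(
    name: str = "toy", width: int = 64, k: int = 3, seed: int = 0
) -> EmbeddingProvider:
    """Register a fresh toy provider instance under ``name``."""
    return register_provider(name, ToyEmbedder(width=width, k=k, seed=seed), width)


def ensure_toy_provider(width: int = 64, k: int = 3, seed: int = 0) -> EmbeddingProvider:
    """Return the default ``toy`` provider, registering it on first use."""
    if "toy" not in _REGISTRY:
        return make_toy_provider("toy", width=width, k=k, seed=seed)
    return _REGISTRY["toy"]
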