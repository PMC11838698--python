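"""Residue-level attention interpretation.

Given a bound protein-ligand structure, identify binding residues by a
heavy-atom distance cutoff, compare each pooling head's mean attention on
binding vs non-binding residues, and export per-residue attention onto the
structure's temperature-factor column for viewer coloring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .model.core import AttentionMap

#: standard heavy-atom contact criterion, configurable everywhere it is used
DEFAULT_CONTACT_CUTOFF = 4.5

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class BoundStructure:
    """A single-chain protein with a bound ligand.

    ``residue_coords[i]`` holds the heavy-atom coordinates of 0-based
    residue ``i`` (None for residues unresolved in the structure);
    ``author_numbers`` maps those indices back to the file's numbering.
    """

    target_id: str
    sequence: str
    residue_coords: list[Optional[np.ndarray]]
    ligand_coords: np.ndarray
    chain_id: str = "A"
    author_numbers: list[Optional[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.residue_coords) != len(self.sequence):
            raise DataError(
                f"residue_coords length {len(self.residue_coords)} != sequence "
                f"length {len(self.sequence)}"
            )
        if not self.author_numbers:
            self.author_numbers = list(range(1, len(self.sequence) + 1))
        lig = np.asarray(self.ligand_coords, dtype=np.float64)
        if lig.ndim != 2 or lig.shape[1] != 3:
            raise DataError("ligand coordinates must be (n, 3)")
        if not np.all(np.isfinite(lig)):
            raise DataError("non-finite ligand coordinates")
        self.ligand_coords = lig

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def resolved_indices(self) -> set[int]:
        return {i for i, c in enumerate(self.residue_coords) if c is not None}


def binding_residues(
    structure: BoundStructure, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> set[int]:
    """0-based indices of residues with any heavy atom within ``cutoff``
    angstroms of any ligand heavy atom.  Monotone non-decreasing in cutoff."""
    if cutoff <= 0:
        raise ConfigError(f"cutoff must be positive, got {cutoff}")
    if structure.ligand_coords.shape[0] == 0:
        raise DataError("ligand has no heavy atoms")
    out: set[int] = set()
    lig = structure.ligand_coords
    for i, coords in enumerate(structure.residue_coords):
        if coords is None or coords.shape[0] == 0:
            continue
        diff = coords[:, None, :] - lig[None, :, :]
        if np.any(np.sum(diff * diff, axis=-1) <= cutoff * cutoff):
            out.add(i)
    return out


@dataclass
class EnrichmentReport:
    """Per-head mean attention on binding vs non-binding residues."""

    target_id: str
    binding_mean: np.ndarray  # (H,)
    nonbinding_mean: np.ndarray  # (H,)
    ratio: np.ndarray  # (H,), +inf where nonbinding mean is 0
    n_binding: int
    n_nonbinding: int

    def to_tsv(self) -> str:
        lines = ["head\tbinding_mean\tnonbinding_mean\tratio"]
        for h in range(len(self.binding_mean)):
            lines.append(
                f"{h}\t{self.binding_mean[h]:.8g}\t{self.nonbinding_mean[h]:.8g}\t"
                f"{self.ratio[h]:.8g}"
            )
        return "\n".join(lines) + "\n"

    @property
    def mean_ratio(self) -> float:
        finite = self.ratio[np.isfinite(self.ratio)]
        return float(np.mean(finite)) if finite.size else float("inf")


def attention_enrichment(
    attention: AttentionMap,
    binding: set[int],
    exclude: set[int] | frozenset[int] = frozenset(),
) -> EnrichmentReport:
    """Compare mean attention on binding vs non-binding residues per head.

    ``exclude`` removes residues (e.g. unresolved ones) from both sets; the
    remaining residues are partitioned by ``binding``.
    """
    L = attention.length
    for idx in binding | set(exclude):
        if not 0 <= idx < L:
            raise DataError(f"residue index {idx} outside [0, {L})")
    eligible = set(range(L)) - set(exclude)
    bind = sorted(binding & eligible)
    nonbind = sorted(eligible - binding)
    if not bind or not nonbind:
        raise DataError(
            f"binding set must be a non-empty proper subset of eligible residues "
            f"(got {len(bind)} binding, {len(nonbind)} non-binding)"
        )
    W = attention.weights
    b_mean = W[:, bind].mean(axis=1)
    n_mean = W[:, nonbind].mean(axis=1)
    with np.errstate(divide="ignore"):
        ratio = np.where(n_mean > 0, b_mean / np.where(n_mean > 0, n_mean, 1.0), np.inf)
    return EnrichmentReport(
        target_id=attention.target_id,
        binding_mean=b_mean,
        nonbinding_mean=n_mean,
        ratio=ratio,
        n_binding=len(bind),
        n_nonbinding=len(nonbind),
    )


def rescale_attention(weights: np.ndarray) -> np.ndarray:
    """Min-max rescale one head's weights to [0, 100] (flat input -> 0)."""
    lo, hi = float(np.min(weights)), float(np.max(weights))
    if hi == lo:
        return np.zeros_like(weights)
    return 100.0 * (weights - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# PDB plumbing (biotite-backed)
# ---------------------------------------------------------------------------


def read_bound_structure(
    path: str | Path, chain: str | None = None, target_id: str | None = None
) -> BoundStructure:
    """Read a single-chain protein + HETATM ligand (waters excluded).

    The ligand is the union of non-water hetero heavy atoms.  Residue
    indices are assigned in file order; author numbering is preserved.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio
    from biotite.sequence import ProteinSequence

    pdb = pdbio.PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    heavy = atoms[atoms.element != "H"]
    protein_mask = struc.filter_amino_acids(heavy) & ~heavy.hetero
    protein = heavy[protein_mask]
    if protein.array_length() == 0:
        raise DataError(f"{path}: no protein atoms found")
    if chain is None:
        chain = str(protein.chain_id[0])
    protein = protein[protein.chain_id == chain]
    if protein.array_length() == 0:
        raise DataError(f"{path}: no protein atoms in chain {chain!r}")

    ligand_mask = heavy.hetero & ~np.isin(heavy.res_name, list(_WATER_NAMES))
    ligand = heavy[ligand_mask]

    res_ids, res_names = struc.get_residues(protein)
    sequence = []
    coords: list[Optional[np.ndarray]] = []
    numbers: list[Optional[int]] = []
    for rid, rname in zip(res_ids, res_names):
        try:
            sequence.append(ProteinSequence.convert_letter_3to1(rname))
        except KeyError:
            sequence.append("X")
        coords.append(protein.coord[protein.res_id == rid])
        numbers.append(int(rid))
    return BoundStructure(
        target_id=target_id or Path(path).stem,
        sequence="".join(sequence),
        residue_coords=coords,
        ligand_coords=ligand.coord.astype(np.float64),
        chain_id=chain,
        author_numbers=numbers,
    )


def export_attention_structure(
    pdb_in: str | Path,
    attention: AttentionMap,
    head: int,
    pdb_out: str | Path,
    chain: str | None = None,
) -> None:
    """Write a copy of the structure with one head's min-max-rescaled
    attention (0-100) in the temperature-factor column of protein atoms."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    if not 0 <= head < attention.n_heads:
        raise ConfigError(
            f"head {head} out of range for {attention.n_heads}-head attention"
        )
    pdb = pdbio.PDBFile.read(str(pdb_in))
    atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])
    protein_mask = struc.filter_amino_acids(atoms) & ~atoms.hetero
    if chain is not None:
        protein_mask &= atoms.chain_id == chain
    res_ids = np.unique(atoms.res_id[protein_mask])
    res_ids.sort()
    if len(res_ids) != attention.length:
        raise DataError(
            f"structure has {len(res_ids)} residues but attention has "
            f"{attention.length}"
        )
    scaled = rescale_attention(attention.weights[head])
    value_of = dict(zip(res_ids.tolist(), scaled))
    b = atoms.b_factor.copy()
    for rid, val in value_of.items():
        b[protein_mask & (atoms.res_id == rid)] = val
    atoms.b_factor = np.round(b, 2)  # PDB format carries 2 decimals
    out = pdbio.PDBFile()
    out.set_structure(atoms)
    out.write(str(pdb_out))


def motif_attention_ratio(
    attention_maps: Sequence[AttentionMap],
    motif_windows: Sequence[tuple[int, int]],
) -> float:
    """Mean over maps and heads of (motif mean attention) / (background
    mean attention); the synthetic analogue of binding-site enrichment."""
    if len(attention_maps) != len(motif_windows):
        raise DataError("need one motif window per attention map")
    ratios = []
    for amap, (start, length) in zip(attention_maps, motif_windows):
        report = attention_enrichment(amap, set(range(start, start + length)))
        ratios.append(report.ratio)
    ratios = np.concatenate(ratios)
    finite = ratios[np.isfinite(ratios)]
    return float(np.mean(finite)) if finite.size else float("inf")
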