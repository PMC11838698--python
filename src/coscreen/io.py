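"""File format adapters: .smi / delimited SMILES tables, FASTA, TSV
interaction tables, and the named-array container used to persist embedding
matrices keyed by target id."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError
from .featurizers import DrugRecord, TargetRecord, morgan_fingerprint


def read_smiles(path: str | Path, n_bits: int = 2048, radius: int = 2) -> list[DrugRecord]:
    """Read drugs from a `.smi` file (SMILES [id] per line) or a delimited
    table with `smiles` and `drug_id` columns, computing fingerprints."""
    path = Path(path)
    rows: list[tuple[str, str]] = []  # (drug_id, smiles)
    if path.suffix == ".smi":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            drug_id = parts[1] if len(parts) > 1 else f"drug_{i}"
            rows.append((drug_id, smiles))
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        missing = {"smiles", "drug_id"} - set(df.columns)
        if missing:
            raise DataError(f"{path}: missing columns {sorted(missing)}")
        rows = list(zip(df["drug_id"].astype(str), df["smiles"].astype(str)))
    return [
        DrugRecord(drug_id=d, smiles=s, fingerprint=morgan_fingerprint(s, n_bits, radius))
        for d, s in rows
    ]


def read_fasta(path: str | Path) -> list[TargetRecord]:
    """Read targets from FASTA; the record id becomes the target_id."""
    from Bio import SeqIO

    records = [
        TargetRecord(target_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def write_fasta(targets: Iterable[TargetRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f">{t.target_id}\n")
            seq = t.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def save_arrays(path: str | Path, arrays: dict[str, np.ndarray]) -> None:
    """Persist named arrays (embedding matrices keyed by target_id)."""
    np.savez(path, **arrays)


def load_arrays(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def read_interactions(path: str | Path) -> pd.DataFrame:
    """Read a TSV interaction table: drug_id, target_id, label-or-pK."""
    df = pd.read_csv(path, sep="\t")
    required = {"drug_id", "target_id"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: need columns drug_id, target_id")
    if not ({"label", "pK"} & set(df.columns)):
        raise DataError(f"{path}: need a 'label' or 'pK' column")
    return df


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
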