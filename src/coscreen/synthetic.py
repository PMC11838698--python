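"""Synthetic datasets with planted interaction structure.

Drug latents live on the unit sphere; targets carry jittered archetype
latents and a sequence whose only label-relevant signal is the archetype's
signature motif inserted at a recorded position.  Labels follow the same
generative geometry the model assumes: Bernoulli(sigmoid(gen_alpha *
cosine)) for classification, dot product + Gaussian noise for affinity.
Everything is deterministic given the spec seed, with named substreams so
components can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError
from .featurizers import AMINO_ACIDS, DrugRecord, TargetRecord
from .training.data import InteractionRecord

_STREAMS = {"drugs": 1, "targets": 2, "labels": 3, "smiles": 4}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator; serialized alongside every dataset."""

    n_drugs: int = 500
    n_targets: int = 200
    n_pairs: int = 20000
    latent_dim: int = 4
    gen_alpha: float = 12.0
    n_archetypes: int = 8
    motif_length: int = 6
    seq_length: int = 48
    label_mode: str = "bernoulli"
    noise_sd: float = 0.1
    archetype_jitter: float = 0.05
    fp_bits: int = 512
    fp_noise_sd: float = 0.05
    #: signature motifs are drawn from this sub-alphabet, backgrounds from its
    #: complement, so the planted signal is compositionally localized the way
    #: binding sites are against their scaffold
    motif_alphabet: str = "HKWY"
    emit_smiles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_targets", "n_pairs", "latent_dim", "n_archetypes",
                     "motif_length", "seq_length", "fp_bits"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if self.motif_length >= self.seq_length:
            raise DataError("motif_length must be smaller than seq_length")
        if self.label_mode not in ("bernoulli", "affinity"):
            raise DataError(f"label_mode must be bernoulli|affinity, got {self.label_mode!r}")
        if not self.motif_alphabet or not set(self.motif_alphabet) <= set(AMINO_ACIDS):
            raise DataError("motif_alphabet must be a non-empty subset of the 20 residues")
        if len(set(self.motif_alphabet)) == len(AMINO_ACIDS):
            raise DataError("motif_alphabet must leave residues for the background")
        if self.n_archetypes > len(set(self.motif_alphabet)) ** self.motif_length:
            raise DataError(
                f"cannot draw {self.n_archetypes} distinct signature "
                f"{self.motif_length}-mers from a "
                f"{len(set(self.motif_alphabet)) ** self.motif_length}-mer space"
            )
        if self.n_pairs > self.n_drugs * self.n_targets:
            raise DataError("n_pairs exceeds the drug x target universe")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        known = set(cls.__dataclass_fields__)
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    drugs: list[DrugRecord]
    targets: list[TargetRecord]
    interactions: list[InteractionRecord]
    truth: dict = field(default_factory=dict)

    @property
    def drug_features(self) -> dict[str, np.ndarray]:
        return {d.drug_id: d.fingerprint for d in self.drugs}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[name]]))


def _unit_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def _simple_smiles(rng: np.random.Generator) -> str:
    """A small valid molecule: alkyl chain with an optional polar cap."""
    n = int(rng.integers(1, 9))
    cap = rng.choice(["", "O", "N", "C(=O)O"])
    return "C" * n + str(cap)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a full dataset plus ground-truth latents and motif positions."""
    d_rng = _stream(spec.seed, "drugs")
    t_rng = _stream(spec.seed, "targets")
    y_rng = _stream(spec.seed, "labels")

    # drugs: unit latents; observable = sign of a noisy fixed linear readout
    drug_latents = _unit_rows(d_rng.standard_normal((spec.n_drugs, spec.latent_dim)))
    readout = d_rng.standard_normal((spec.latent_dim, spec.fp_bits))
    logits = drug_latents @ readout + spec.fp_noise_sd * d_rng.standard_normal(
        (spec.n_drugs, spec.fp_bits)
    )
    fingerprints = (logits > 0).astype(np.uint8)

    smiles: list[str]
    if spec.emit_smiles:
        s_rng = _stream(spec.seed, "smiles")
        smiles = [_simple_smiles(s_rng) for _ in range(spec.n_drugs)]
    else:
        smiles = ["*"] * spec.n_drugs  # sentinel: synthetic, no chemistry
    drugs = [
        DrugRecord(drug_id=f"drug_{i:05d}", smiles=smiles[i], fingerprint=fingerprints[i])
        for i in range(spec.n_drugs)
    ]

    # archetypes: unit latents + distinct signature motifs
    archetypes = _unit_rows(
        t_rng.standard_normal((spec.n_archetypes, spec.latent_dim))
    )
    motif_letters = sorted(set(spec.motif_alphabet))
    background_letters = sorted(set(AMINO_ACIDS) - set(motif_letters))
    signatures: list[str] = []
    seen: set[str] = set()
    while len(signatures) < spec.n_archetypes:
        m = "".join(
            t_rng.choice(motif_letters, size=spec.motif_length, replace=True)
        )
        if m not in seen:
            seen.add(m)
            signatures.append(m)

    arch_of = t_rng.integers(0, spec.n_archetypes, size=spec.n_targets)
    target_latents = _unit_rows(
        archetypes[arch_of]
        + spec.archetype_jitter * t_rng.standard_normal((spec.n_targets, spec.latent_dim))
    )
    motif_pos = t_rng.integers(0, spec.seq_length - spec.motif_length + 1, size=spec.n_targets)
    targets: list[TargetRecord] = []
    for i in range(spec.n_targets):
        seq = list(t_rng.choice(background_letters, size=spec.seq_length, replace=True))
        p = int(motif_pos[i])
        seq[p : p + spec.motif_length] = signatures[int(arch_of[i])]
        targets.append(
            TargetRecord(target_id=f"target_{i:05d}", sequence="".join(seq))
        )

    # interactions: unique pairs sampled uniformly from the universe
    flat = y_rng.choice(
        spec.n_drugs * spec.n_targets, size=spec.n_pairs, replace=False
    )
    di = flat // spec.n_targets
    ti = flat % spec.n_targets
    cos = np.sum(drug_latents[di] * target_latents[ti], axis=1)
    interactions: list[InteractionRecord] = []
    if spec.label_mode == "bernoulli":
        p = 1.0 / (1.0 + np.exp(-spec.gen_alpha * cos))
        y = (y_rng.random(spec.n_pairs) < p).astype(int)
        for j in range(spec.n_pairs):
            interactions.append(
                InteractionRecord(
                    drug_id=drugs[di[j]].drug_id,
                    target_id=targets[ti[j]].target_id,
                    label=int(y[j]),
                )
            )
    else:
        pk = cos + spec.noise_sd * y_rng.standard_normal(spec.n_pairs)
        for j in range(spec.n_pairs):
            interactions.append(
                InteractionRecord(
                    drug_id=drugs[di[j]].drug_id,
                    target_id=targets[ti[j]].target_id,
                    pK=float(pk[j]),
                )
            )

    truth = {
        "drug_latents": drug_latents,
        "target_latents": target_latents,
        "archetype_latents": archetypes,
        "archetype_of_target": arch_of,
        "motif_positions": motif_pos,
        "signatures": signatures,
        "pair_cosines": cos,
        "pair_drug_index": di,
        "pair_target_index": ti,
    }
    return SyntheticDataset(
        spec=spec, drugs=drugs, targets=targets, interactions=interactions, truth=truth
    )


# ---------------------------------------------------------------------------
# Disk round trip (plain text formats only)
# ---------------------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, directory: str | Path, overwrite: bool = False) -> None:
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise DataError(f"{directory} is not empty; pass overwrite=True to replace")
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "drugs.smi", "w") as fh:
        for d in dataset.drugs:
            fh.write(f"{d.smiles}\t{d.drug_id}\n")
    with open(directory / "fingerprints.tsv", "w") as fh:
        fh.write("drug_id\tbits\n")
        for d in dataset.drugs:
            fh.write(f"{d.drug_id}\t{''.join(map(str, d.fingerprint))}\n")
    from .io import write_fasta

    write_fasta(dataset.targets, directory / "targets.fasta")
    mode = dataset.spec.label_mode
    with open(directory / "interactions.tsv", "w") as fh:
        col = "label" if mode == "bernoulli" else "pK"
        fh.write(f"drug_id\ttarget_id\t{col}\tsource\n")
        for r in dataset.interactions:
            value = r.label if mode == "bernoulli" else repr(r.pK)
            fh.write(f"{r.drug_id}\t{r.target_id}\t{value}\t{r.source}\n")
    truth_json = {
        "spec": dataset.spec.to_dict(),
        "signatures": list(dataset.truth["signatures"]),
    }
    for key in (
        "drug_latents",
        "target_latents",
        "archetype_latents",
        "archetype_of_target",
        "motif_positions",
        "pair_cosines",
        "pair_drug_index",
        "pair_target_index",
    ):
        truth_json[key] = np.asarray(dataset.truth[key]).tolist()
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh)
    with open(directory / "spec.cfg", "w") as fh:
        for k, v in dataset.spec.to_dict().items():
            fh.write(f"{k} = {v}\n")


def read_dataset(directory: str | Path) -> SyntheticDataset:
    directory = Path(directory)
    with open(directory / "ground_truth.json") as fh:
        truth_json = json.load(fh)
    spec = SyntheticSpec.from_dict(truth_json["spec"])

    fps: dict[str, np.ndarray] = {}
    with open(directory / "fingerprints.tsv") as fh:
        next(fh)
        for line in fh:
            drug_id, bits = line.strip().split("\t")
            fps[drug_id] = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    drugs = []
    with open(directory / "drugs.smi") as fh:
        for line in fh:
            smiles, drug_id = line.strip().split("\t")
            drugs.append(DrugRecord(drug_id=drug_id, smiles=smiles, fingerprint=fps[drug_id]))

    from .io import read_fasta

    targets = read_fasta(directory / "targets.fasta")

    interactions = []
    with open(directory / "interactions.tsv") as fh:
        header = next(fh).strip().split("\t")
        is_label = header[2] == "label"
        for line in fh:
            d, t, v, src = line.rstrip("\n").split("\t")
            interactions.append(
                InteractionRecord(
                    drug_id=d,
                    target_id=t,
                    label=int(v) if is_label else None,
                    pK=None if is_label else float(v),
                    source=src,
                )
            )

    truth = {"signatures": truth_json["signatures"]}
    for key in (
        "drug_latents",
        "target_latents",
        "archetype_latents",
        "pair_cosines",
    ):
        truth[key] = np.asarray(truth_json[key], dtype=np.float64)
    for key in ("archetype_of_target", "motif_positions", "pair_drug_index", "pair_target_index"):
        truth[key] = np.asarray(truth_json[key], dtype=np.int64)
    return SyntheticDataset(
        spec=spec, drugs=drugs, targets=targets, interactions=interactions, truth=truth
    )
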