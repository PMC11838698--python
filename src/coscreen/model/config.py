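"""Model configuration, recorded verbatim in every saved model file."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

from ..errors import ConfigError

_REQUIRED_KEYS = (
    "alpha",
    "n_heads",
    "d",
    "drug_depth",
    "target_depth",
    "n_bits",
    "embed_width",
    "seed",
)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the co-embedding model.

    ``alpha`` is the constant scaling factor applied to the cosine before
    the sigmoid (default 5, saturating the sigmoid over cosine's (-1, 1)
    range).  ``d`` is the shared co-embedding width.  ``head_merge``
    selects whether per-head pooled vectors are concatenated or averaged.
    """

    alpha: float = 5.0
    n_heads: int = 8
    d: int = 256
    drug_depth: int = 3
    target_depth: int = 3
    n_bits: int = 2048
    embed_width: int = 64
    key_width: int = 32
    value_width: int = 32
    head_merge: str = "concat"
    activation: str = "relu"
    dropout: float = 0.0
    seed: int = 0
    provider: str = "toy"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ConfigError(f"alpha must be positive, got {self.alpha}")
        if self.n_heads <= 0:
            raise ConfigError(f"n_heads must be positive, got {self.n_heads}")
        if self.drug_depth not in (1, 3) or self.target_depth not in (1, 3):
            raise ConfigError("projection depths must be 1 or 3")
        if self.head_merge not in ("concat", "mean"):
            raise ConfigError(f"head_merge must be concat|mean, got {self.head_merge!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")

    @property
    def pooled_width(self) -> int:
        if self.head_merge == "concat":
            return self.n_heads * self.value_width
        return self.value_width

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        missing = [k for k in _REQUIRED_KEYS if k not in data]
        if missing:
            raise ConfigError(
                f"model config is missing required fields {missing}; refusing "
                "to silently default"
            )
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})
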