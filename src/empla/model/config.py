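"""Model hyperparameter configuration and ablation switches."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class ModelConfig:
    hidden_dim: int = 128
    protein_dilations: tuple[int, ...] = (1, 2, 4, 8, 16)
    ligand_dilations: tuple[int, ...] = (1, 2, 4, 8)
    attention_heads: int = 2
    egnn_layers: int = 3
    hgt_layers: int = 3
    attentivefp_layers: int = 3
    attentivefp_timesteps: int = 2
    fusion_hidden: tuple[int, ...] = (128, 64)

    # ablation switches (module removal, not zeroing)
    use_protein: bool = True
    use_sequence_complex: bool = True
    use_covalent: bool = True
    use_noncovalent: bool = True
    use_environment_nodes: bool = True

    def __post_init__(self):
        if self.hidden_dim % self.attention_heads != 0:
            raise ValueError("hidden_dim must be divisible by attention_heads")
        for name in ("egnn_layers", "hgt_layers", "attentivefp_layers",
                     "attentivefp_timesteps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (self.use_protein or self.use_sequence_complex
                or self.use_covalent or self.use_noncovalent):
            raise ValueError("at least one branch must be enabled")

    @property
    def key_dim(self) -> int:
        return self.hidden_dim // self.attention_heads

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protein_dilations"] = list(self.protein_dilations)
        d["ligand_dilations"] = list(self.ligand_dilations)
        d["fusion_hidden"] = list(self.fusion_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        for k in ("protein_dilations", "ligand_dilations", "fusion_hidden"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)
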