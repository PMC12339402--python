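"""Run configuration: the thresholds and constants of the whole pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List


def _default_antibody_constants() -> Dict[str, float]:
    # Arbitrary scale-factor numerators per antibody; divided by the
    # properly-paired spike-in read count to place samples on one scale.
    return {
        "H3K9me2": 3000.0,
        "H3K9me3": 7000.0,
        "LAP2B": 8000.0,
        "LB1": 8000.0,
    }


@dataclass
class Config:
    """All tunable constants in one place.

    Attributes
    ----------
    bin_size : genomic bin width in bp.
    antibody_constants : scale-factor numerator per mark.
    gene_overlap_fraction : minimum gene-body coverage (>=) for domain
        membership.
    tpm_expressed : TPM threshold; a gene is "expressed" if TPM is strictly
        above this (``tpm_ge`` switches to >=).
    deg_fc, deg_alpha : fold-change and adjusted-p thresholds for calling
        differential genes (strict > on |FC|, strict < on p).
    copy_fc : fold-change threshold for TE unique-copy derepression calls.
    mirE_te_fc : fold-change threshold for knockdown TE derepression calls.
    te_z_threshold : modified-z cut (strict >) for TE-family enrichment.
    n_shells : radial shells per nucleus (shell 1 = center).
    tem_square_um, tem_n_squares : TEM quantification square side and count.
    hmm_states_to_try : candidate HMM state numbers for model selection.
    seed : default random seed.
    """

    bin_size: int = 10_000
    antibody_constants: Dict[str, float] = field(
        default_factory=_default_antibody_constants
    )
    gene_overlap_fraction: float = 0.90
    tpm_expressed: float = 5.0
    tpm_ge: bool = False
    deg_fc: float = 2.0
    deg_alpha: float = 0.05
    copy_fc: float = 10.0
    mirE_te_fc: float = 5.0
    te_z_threshold: float = 2.0
    n_shells: int = 25
    tem_square_um: float = 0.2
    tem_n_squares: int = 40
    hmm_states_to_try: List[int] = field(default_factory=lambda: [2, 3, 4, 5])
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "bin_size": self.bin_size,
            "tpm_expressed": self.tpm_expressed,
            "deg_fc": self.deg_fc,
            "deg_alpha": self.deg_alpha,
            "copy_fc": self.copy_fc,
            "mirE_te_fc": self.mirE_te_fc,
            "te_z_threshold": self.te_z_threshold,
            "n_shells": self.n_shells,
            "tem_square_um": self.tem_square_um,
            "tem_n_squares": self.tem_n_squares,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not (0 < self.gene_overlap_fraction <= 1):
            raise ValueError("gene_overlap_fraction must be in (0, 1]")
        for mark, c in self.antibody_constants.items():
            if c <= 0:
                raise ValueError(f"antibody constant for {mark} must be > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Config":
        data = json.loads(Path(path).read_text())
        return cls(**data)
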