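"""Pipeline configuration: every numeric threshold used by the stages.

All thresholds live in one object that is serialized next to the outputs,
so a run is fully described by (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """Global thresholds for all pipeline stages.

    Defaults are the study conditions: DUST complexity cutoff 7 over
    64-base windows, 500 bp minimum transcript length, TPM >= 1,
    isoform clustering at >= 100 shared bp and >= 97% identity,
    alignment-row filters at 1,500 residues and 40% gaps, a 50-gene
    synteny window requiring >= 2 shared families, and 4dTv histograms
    over [0.2, 1.4).
    """

    # transcript filters
    dust_threshold: float = 7.0
    dust_window: int = 64
    min_transcript_len: int = 500
    min_tpm: float = 1.0
    # isoform clustering
    isoform_min_overlap: int = 100
    isoform_min_identity: float = 0.97
    # family-alignment filters
    max_protein_len: int = 1500
    max_gap_frac: float = 0.40
    # 4dTv
    min_4d_sites: int = 10
    # synteny
    synteny_window: int = 50
    min_shared_families: int = 2
    # pooled (default) counts shared families over both sides of each
    # neighbourhood; per-side requires a single side-to-side match
    synteny_per_side: bool = False
    # histograms / density
    hist_min: float = 0.2
    hist_max: float = 1.4
    hist_width: float = 0.05
    mixture_k_candidates: tuple[int, ...] = (1, 2, 3, 4)
    mixture_n_init: int = 10
    density_grid_min: float = 0.01
    density_grid_max: float = 1.5
    density_grid_step: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "dust_threshold", "dust_window", "min_transcript_len",
            "isoform_min_overlap", "max_protein_len", "synteny_window",
            "min_shared_families", "min_4d_sites", "hist_width",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.isoform_min_identity <= 1:
            raise ValueError("isoform_min_identity must be in (0, 1]")
        if not 0 <= self.max_gap_frac <= 1:
            raise ValueError("max_gap_frac must be in [0, 1]")
        if not self.hist_min < self.hist_max:
            raise ValueError("hist_min must be < hist_max")
        if self.min_tpm < 0:
            raise ValueError("min_tpm must be >= 0")
        self.mixture_k_candidates = tuple(int(k) for k in self.mixture_k_candidates)
        if any(k < 1 for k in self.mixture_k_candidates):
            raise ValueError("mixture component counts must be >= 1")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                rendered = "[" + ", ".join(str(v) for v in value) + "]"
            elif isinstance(value, bool):
                rendered = "true" if value else "false"
            elif isinstance(value, str):
                rendered = f'"{value}"'
            else:
                rendered = repr(value)
            lines.append(f"{f.name} = {rendered}")
        Path(path).write_text("\n".join(lines) + "\n")

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mixture_k_candidates"] = list(d["mixture_k_candidates"])
        return d
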