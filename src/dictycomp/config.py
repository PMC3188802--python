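"""Run configuration and provenance.

A run is configured by a flat key-value document (YAML).  Unknown keys are
rejected so that typos never silently fall back to defaults, and every run
emits a provenance block (parameters, seed, input checksums) alongside its
outputs so stochastic stages are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Flat parameter set for every analysis stage."""

    seed: int = 0

    # ssr stage
    ssr_max_unit: int = 20
    ssr_fraction_mode: str = "union"  # or "summed"

    # homopolymer stage
    aa_alpha: float = 0.01
    align_open_gap: float = 11.0
    align_extend_gap: float = 1.0
    homology_min_overlap: int = 1

    # synteny stage
    synteny_w: int = 0
    synteny_w_max: int = 20
    synteny_n_perm: int = 100
    synteny_k_sd: float = 2.0
    synteny_strict_order: bool = False
    synteny_shuffle_mode: str = "within_scaffold"  # or "whole_genome"

    # ncrna stage
    ncrna_k: int = 8
    ncrna_duse_pattern: str = "WCCCAWAA"
    ncrna_duse_window: tuple[int, int] = (40, 90)
    ncrna_stem_len: int = 5
    ncrna_separation: tuple[int, int] = (40, 70)
    ncrna_stem5_offset: int = 15
    ncrna_bulge: str = "CCTTACAGCCAA"
    ncrna_respect_mask: bool = True

    # expression / social stage
    qc_min_total: int = 20
    qc_min_reproducibility: float = 0.8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ncrna_duse_window", "ncrna_separation"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("ncrna_duse_window", "ncrna_separation"):
            d[key] = list(d[key])
        return d


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance_block(config: RunConfig, inputs: dict[str, str | Path]) -> dict:
    """Parameters, seed and input checksums for a run's provenance record."""
    return {
        "parameters": config.to_dict(),
        "seed": config.seed,
        "inputs": {name: {"path": str(p), "sha256": sha256_file(p)}
                   for name, p in inputs.items() if p and Path(p).exists()},
    }


def write_provenance(config: RunConfig, inputs: dict[str, str | Path],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(provenance_block(config, inputs), fh, sort_keys=True)
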