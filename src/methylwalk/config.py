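"""Run configuration: a declarative YAML file plus CLI overrides.

Example::

    structure_files: [model.pdb]
    labelling_scheme: MILproSVproSAT
    peak_list: peaks.tsv
    theoretical_restraints: theo_pcs.tsv   # optional, per-methyl table
    restraint_weights: [1.0, 1.0, 1.0, 1.0]
    noe_weight: 1.0
    replica_ranges:                         # exactly three, increasing maxima
      - [3.0, 8.0, 0.2]
      - [3.0, 9.0, 0.2]
      - [3.0, 10.0, 0.2]
    min_score: 0.0
    min_common_edges: 1
    min_common_edges_seminal: 2
    safeguard: {enabled: true, k_sigma: 1.0}
    preassignments: fixed.tsv               # optional, resonance<TAB>methyl
    collapse_symmetry: true
    seed: 1
    output_dir: out/
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .labelling import LabellingScheme
from .scoring import Weights
from .structure import CutoffGrid
from .walker import WalkerConfig


@dataclass
class RunConfig:
    structure_files: list[Path]
    labelling_scheme: str
    peak_list: Path | None = None
    theoretical_restraints: Path | None = None
    restraint_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    noe_weight: float = 1.0
    replica_ranges: tuple[tuple[float, float, float], ...] = (
        (3.0, 8.0, 0.2),
        (3.0, 9.0, 0.2),
        (3.0, 10.0, 0.2),
    )
    min_score: float = 0.0
    min_common_edges: int = 1
    min_common_edges_seminal: int = 2
    top_k_seminal: int | None = None
    safeguard_enabled: bool = True
    safeguard_k_sigma: float = 1.0
    preassignments: Path | None = None
    score_dump: bool = False
    collapse_symmetry: bool = True
    ensemble_mode: str = "min"
    seed: int = 0
    output_dir: Path = field(default_factory=lambda: Path("methylwalk_out"))

    def __post_init__(self) -> None:
        self.structure_files = [Path(p) for p in self.structure_files]
        self.peak_list = Path(self.peak_list) if self.peak_list else None
        self.theoretical_restraints = (
            Path(self.theoretical_restraints) if self.theoretical_restraints else None
        )
        self.preassignments = Path(self.preassignments) if self.preassignments else None
        self.output_dir = Path(self.output_dir)
        self.replica_ranges = tuple(tuple(map(float, r)) for r in self.replica_ranges)

    # -- validation -------------------------------------------------------
    def validate(self, check_paths: bool = True) -> None:
        LabellingScheme.from_token(self.labelling_scheme)  # raises if malformed
        if len(self.replica_ranges) != 3:
            raise ValueError("exactly 3 replica cut-off ranges are required")
        maxima = [r[1] for r in self.replica_ranges]
        if not (maxima[0] < maxima[1] < maxima[2]):
            raise ValueError("replica cut-off maxima must be strictly increasing")
        for r in self.replica_ranges:
            CutoffGrid(*r)  # raises on min >= max or step <= 0
        if check_paths:
            for p in self.structure_files:
                if not p.exists():
                    raise FileNotFoundError(f"structure file not found: {p}")
            for p in (self.peak_list, self.theoretical_restraints, self.preassignments):
                if p is not None and not p.exists():
                    raise FileNotFoundError(f"input file not found: {p}")

    # -- derived objects --------------------------------------------------
    @property
    def scheme(self) -> LabellingScheme:
        return LabellingScheme.from_token(self.labelling_scheme)

    @property
    def weights(self) -> Weights:
        return Weights(self.noe_weight, tuple(self.restraint_weights))

    def walker_config(self, replica: int) -> WalkerConfig:
        return WalkerConfig(
            grid=CutoffGrid(*self.replica_ranges[replica]),
            weights=self.weights,
            min_score=self.min_score,
            min_common_edges=self.min_common_edges,
            min_common_edges_seminal=self.min_common_edges_seminal,
            top_k_seminal=self.top_k_seminal,
        )

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sg = raw.pop("safeguard", None)
        if sg is not None:
            raw["safeguard_enabled"] = bool(sg.get("enabled", True))
            raw["safeguard_k_sigma"] = float(sg.get("k_sigma", 1.0))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def effective_parameters(self) -> dict:
        """All parameters including defaults, for the run log."""
        out = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if isinstance(v, Path):
                v = str(v)
            elif isinstance(v, list):
                v = [str(x) for x in v]
            elif isinstance(v, tuple):
                v = [list(x) if isinstance(x, tuple) else x for x in v]
            out[name] = v
        return out
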