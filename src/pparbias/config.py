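"""Run configuration: defaults, YAML round-trip, and config echo."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Fully resolved configuration for the binding and transcriptome arms."""

    # input paths
    plate_csvs: list[str] = field(default_factory=list)
    de_table: str | None = None
    gmt: str | None = None
    fasta: str | None = None
    motif_matrix: str | None = None
    antidiabetic_genes: str | None = None
    adverse_genes: str | None = None

    # assay constants (nM)
    receptor_total: float = 800.0
    tracer_total: float = 50.0
    tracer_kd: float = 200.0

    # statistics
    sigma_convention: str = "log10_ratio"
    ki_convention: str = "nikolovska"
    rout_q: float = 0.01
    lfc_epsilon: float = 0.01
    alpha: float = 0.05

    # references
    reference_ligand: str = "rosiglitazone"
    reference_coregulator: str = "CBP_1-127"
    reference_pathway: str = "AMPK"

    # occupancy prediction
    cellular_receptor_nM: float = 50.0
    coregulator_concentrations_nM: tuple[float, ...] = (150.0, 1500.0)

    # motif scan
    motif_threshold: float = 7.350619126
    upstream_window: int = 10_000

    seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["coregulator_concentrations_nM"] = list(self.coregulator_concentrations_nM)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def validate_paths(self) -> None:
        for name in ("de_table", "gmt", "fasta", "motif_matrix",
                     "antidiabetic_genes", "adverse_genes"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value}")
        for p in self.plate_csvs:
            if not Path(p).exists():
                raise FileNotFoundError(f"plate_csvs entry: {p}")

    def echo(self, output_dir=None) -> Path:
        """Write the fully resolved config next to the outputs."""
        out = Path(output_dir or self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "run_config.yaml"
        self.to_yaml(path)
        return path
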