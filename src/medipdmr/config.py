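"""Pipeline configuration: one YAML file, every threshold a named key."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .dmr import DMRCallParams

__all__ = ["PipelineConfig", "load_config", "write_manifest"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, defaulting to the published thresholds.

    ``window_width`` 100 bp, DMR seed p 1e-7, extension p 0.1 within
    1000 bp, >=2 significant windows for the stringent set, gene
    association within 10 kb.
    """

    # paths (filled per run; None means the stage is skipped or synthetic)
    reference: str | None = None
    counts: str | None = None
    reads_dir: str | None = None
    annotation: str | None = None
    pathway_map: str | None = None
    phenotypes: str | None = None
    output_dir: str = "medipdmr_out"

    # windowing / testing
    window_width: int = 100
    normalization: str = "total-count"
    phi: float | None = None            # None -> estimate from replicates
    fixed_phi_pairwise: float = 0.1     # 1-vs-1 epiallele comparisons
    two_sided_rule: str = "min-likelihood"

    # DMR calling
    p_seed: float = 1e-7
    p_extend: float = 0.1
    max_gap: int = 1000
    min_significant_windows: int = 2
    sweep_thresholds: tuple[float, ...] = (1e-3, 1e-4, 1e-5, 1e-6, 1e-7)

    # clustering
    cluster_scan_width: int = 2_000_000
    cluster_min_members: int = 3
    cluster_alpha: float = 0.05

    # annotation
    gene_max_distance: int = 10_000

    # phenotypes
    control_lineage: str = "control"

    seed: int = 0

    def dmr_params(self) -> DMRCallParams:
        return DMRCallParams(
            p_seed=self.p_seed,
            p_extend=self.p_extend,
            max_gap=self.max_gap,
            min_significant_windows=self.min_significant_windows,
        )

    def validate(self) -> None:
        self.dmr_params()  # raises on inconsistent thresholds
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("cluster_alpha must be in (0, 1)")
        if self.gene_max_distance < 0:
            raise ValueError("gene_max_distance must be >= 0")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: PipelineConfig, outdir: Path, inputs: list[str | Path]) -> None:
    """Record everything needed to reproduce a run."""
    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "input_checksums": {str(p): _checksum(p) for p in inputs if p and Path(p).exists()},
    }
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
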