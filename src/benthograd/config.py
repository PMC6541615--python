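"""Pipeline configuration.

The defaults reproduce the survey's stated design: 0.5 m raster, disturbance
bands at 1/10/50 m, composite units of 14,000 cells (3500 m^2), replicate
counts A/B/C: 5 and D: 10, quasi-Poisson errors for counts and Gaussian for
diversity.  Every stochastic stage derives its own seed deterministically
from the master seed and the stage name, so editing one stage's settings
never silently changes another stage's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from .synthetic import CommunitySpec, default_community

__all__ = ["PipelineConfig", "default_config", "stage_seed"]


def _plain(obj):
    """Recursively coerce to YAML-safe builtins (lists, floats, ints, str)."""
    import numpy as np

    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class SceneConfig:
    extent_ha: float
    n_tracks: int
    track_width: float = 8.0
    track_spacing: object = 40.0  # scalar or cyclic gap pattern
    height: float = 100.0
    name: str = "scene"


@dataclass
class PipelineConfig:
    #: disturbed-area analogue: 20 tracks in paired clusters so each band
    #: A/B/C can supply five 14,000-cell composite units (see docs/methods.md)
    dea: SceneConfig = field(
        default_factory=lambda: SceneConfig(
            extent_ha=5.86, n_tracks=20, track_width=8.0,
            track_spacing=[10.0, 47.0], name="DEA",
        )
    )
    ref: SceneConfig = field(
        default_factory=lambda: SceneConfig(extent_ha=5.25, n_tracks=0, name="REF")
    )
    community: CommunitySpec = field(default_factory=default_community)
    cell_size: float = 0.5
    band_bounds: tuple = (1.0, 10.0, 50.0)
    cells_per_unit: int = 14_000
    replicates: dict = field(default_factory=lambda: {"A": 5, "B": 5, "C": 5, "D": 10})
    count_metrics_family: str = "quasipoisson"
    diversity_metrics_family: str = "gaussian"
    alpha: float = 0.05
    anosim_max_exact: int = 200_000
    anosim_n_perm: int = 9_999
    nmds_dims: int = 2
    nmds_starts: int = 20
    nmds_max_iter: int = 500
    nmds_tol: float = 1e-7
    heatmap_resolution: float = 1.0
    heatmap_radius: float = 20.0
    heatmap_groups: tuple = (
        "Anthozoa", "Porifera", "Holothuroidea",
        "Ophiuroidea", "Crustacea", "Actinopterygii",
    )
    seed: int = 0

    def to_dict(self) -> dict:
        d = _plain(dataclasses.asdict(self))
        d["community"] = {
            "intensity": dict(self.community.intensity),
            "group_mix": {k: dict(v) for k, v in self.community.group_mix.items()},
            "n_msp_per_group": dict(self.community.n_msp_per_group),
            "decay": self.community.decay,
            "size_log_mean": self.community.size_log_mean,
            "size_log_sd": self.community.size_log_sd,
        }
        return _plain(d)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(seed=seed)


def load_config(path) -> PipelineConfig:
    """Load a YAML config; absent keys keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    if "community" in data:
        base = cfg.to_dict()["community"]
        base.update(data.pop("community"))
        cfg.community = CommunitySpec(**base)
    for scene_key in ("dea", "ref"):
        if scene_key in data:
            setattr(cfg, scene_key, SceneConfig(**data.pop(scene_key)))
    for key, val in data.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key {key!r}")
        setattr(cfg, key, val)
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
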