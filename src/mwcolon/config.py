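"""Pipeline configuration: a single validated YAML document.

The config gathers everything an end-to-end run needs — the tissue table,
array geometry, imaging grid, noise level, validity thresholds, detector
parameters, and the top-level seed — and validates the cross-references
(every referenced tissue class must be defined; the angular grid must be
divisible by the element count so rotation symmetry is representable).
Unknown keys are an error: silent typos in threshold names are worse than
a hard failure.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from . import dielectrics as dx
from .array_forward import ArrayGeometry
from .detection import DetectorConfig
from .imaging import PolarGrid

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    tissues: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            name: {"eps_r": e, "sigma": s}
            for name, (e, s) in dx.DEFAULT_TISSUES.items()
        }
    )
    background_tissue: str = "mucosa"
    geometry: dict = field(
        default_factory=lambda: {
            "n_tx": 8, "n_rx": 8, "ring_radius": 10.0, "frequency": 7.5e9,
        }
    )
    grid: dict = field(
        default_factory=lambda: {"n_r": 20, "n_theta": 64, "r_max": 25.0}
    )
    noise_sigma: float = 1e-3
    detector: dict = field(
        default_factory=lambda: {
            "k_sigma": 5.0, "L_min": 10, "gap_bridge": 3, "calib_frames": 50,
            "tau_chan": 0.5, "m_min": 2,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, props in self.tissues.items():
            extra = set(props) - {"eps_r", "sigma"}
            if extra:
                raise ValueError(f"unknown tissue keys for {name!r}: {sorted(extra)}")
            dx.DielectricProps(props["eps_r"], props["sigma"])
        if self.background_tissue not in self.tissues:
            raise ValueError(
                f"background tissue {self.background_tissue!r} is not defined"
            )
        for ref in ("polyp", "stool"):
            if ref not in self.tissues:
                raise ValueError(f"missing tissue class {ref!r}")
        geo_keys = {"n_tx", "n_rx", "ring_radius", "frequency"}
        extra = set(self.geometry) - geo_keys
        if extra:
            raise ValueError(f"unknown geometry keys: {sorted(extra)}")
        grid_keys = {"n_r", "n_theta", "r_max"}
        extra = set(self.grid) - grid_keys
        if extra:
            raise ValueError(f"unknown grid keys: {sorted(extra)}")
        n_theta = self.grid.get("n_theta", 64)
        n_tx = self.geometry.get("n_tx", 8)
        if n_theta % n_tx != 0:
            raise ValueError(
                f"n_theta ({n_theta}) must be divisible by n_tx ({n_tx})"
            )
        det_keys = {f.name for f in fields(DetectorConfig)}
        extra = set(self.detector) - det_keys
        if extra:
            raise ValueError(f"unknown detector keys: {sorted(extra)}")
        # validate by construction
        self.make_geometry()
        self.make_grid()
        self.make_detector()

    def tissue_table(self) -> dict[str, tuple[float, float]]:
        return {n: (p["eps_r"], p["sigma"]) for n, p in self.tissues.items()}

    def make_geometry(self) -> ArrayGeometry:
        return ArrayGeometry(**self.geometry)

    def make_grid(self) -> PolarGrid:
        return PolarGrid(**self.grid)

    def make_detector(self) -> DetectorConfig:
        return DetectorConfig(**self.detector)


def write_config(config: PipelineConfig, path: str) -> None:
    doc = {"schema_version": SCHEMA_VERSION, **asdict(config)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return PipelineConfig()
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    version = doc.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"config schema version {version} != supported {SCHEMA_VERSION}"
        )
    known = {f.name for f in fields(PipelineConfig)}
    extra = set(doc) - known
    if extra:
        raise ValueError(f"unknown config keys: {sorted(extra)}")
    return PipelineConfig(**doc)
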