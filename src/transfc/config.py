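"""Configuration objects for the phantom simulation and the full pipeline.

Defaults encode the acquisition and analysis constants of the study design
this package models: TR 2.4 s, 0.01-0.1 Hz connectivity band, T>3.1
winner-take-all threshold, 1.3% / 0.3 mm spike-detection thresholds, 1.5 mm
FWHM smoothing, 2-SD seed-intensity exclusion, five subiculum segments and
three 60-degree CA1 sectors.  The phantom defaults are a desk-scale version
of the study (16 subjects, one 240-volume run on a 24x24x12 grid); the
full-scale values (32 subjects, two 332-volume runs) remain valid
configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Tuple

import yaml

from .exceptions import InvalidConfigError

#: Fixed order of cortical source regions; used for deterministic
#: tie-breaking in the winner-take-all parcellation.
SOURCE_ORDER: Tuple[str, ...] = ("RSC", "PHC", "A35", "A36")

#: Task conditions, in design-matrix column order.
CONDITIONS: Tuple[str, ...] = ("scene", "object", "baseline")


def _default_gradient_weights() -> dict:
    """Ground-truth (proximal, distal) connectivity weights per target.

    Encodes the qualitative pattern the pipeline must recover: in the
    subiculum the PHC-driven entorhinal signal strengthens towards the
    distal end while the A35- and RSC-driven signals strengthen towards
    the proximal end; in CA1 the RSC-driven signal strengthens distally
    with a weaker opposing A35 trend.
    """
    return {
        "SUB": {
            "RSC": (0.70, 0.30),
            "PHC": (0.20, 0.80),
            "A35": (0.70, 0.20),
            "A36": (0.45, 0.45),
        },
        "CA1": {
            "RSC": (0.30, 0.70),
            "PHC": (0.35, 0.35),
            "A35": (0.50, 0.30),
            "A36": (0.35, 0.35),
        },
    }


def _default_condition_amplitudes() -> dict:
    """(region, condition) -> BOLD amplitude in noise-SD units.

    The scene bias is confined to the PHC-driven entorhinal subregion and
    the distal subiculum; everywhere else scene and object evoke equal
    responses.  Proximal/distal endpoint amplitudes are interpolated
    linearly along the transversal coordinate.
    """
    amps = {}
    for region in ("EC_RSC", "EC_PHC", "EC_A35", "EC_A36",
                   "SUB_proximal", "SUB_distal", "CA1_proximal", "CA1_distal"):
        amps[(region, "scene")] = 0.5
        amps[(region, "object")] = 0.5
        amps[(region, "baseline")] = 0.2
    amps[("EC_PHC", "scene")] = 1.2
    amps[("SUB_distal", "scene")] = 1.2
    return amps


@dataclass
class PhantomConfig:
    """Parameters of the synthetic group dataset."""

    grid_dims: Tuple[int, int, int] = (24, 24, 12)
    n_subjects: int = 16
    n_volumes_per_run: int = 240
    n_runs: int = 1
    tr_seconds: float = 2.4
    band_hz: Tuple[float, float] = (0.01, 0.1)
    noise_sd: float = 1.0
    gradient_weights: Mapping = field(default_factory=_default_gradient_weights)
    condition_amplitudes: Mapping = field(default_factory=_default_condition_amplitudes)
    spike_rate: float = 0.02
    baseline_intensity: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        low, high = self.band_hz
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0 < low < high < nyquist):
            raise InvalidConfigError(
                f"band_hz {self.band_hz} must satisfy 0 < low < high < "
                f"Nyquist ({nyquist:.4f} Hz at TR {self.tr_seconds} s)")
        if self.n_volumes_per_run < 20:
            raise InvalidConfigError("n_volumes_per_run must be >= 20")
        if len(self.grid_dims) != 3 or any(d < 8 for d in self.grid_dims):
            raise InvalidConfigError("grid_dims must be a triple with each >= 8")
        if not (0.0 <= self.spike_rate <= 1.0):
            raise InvalidConfigError("spike_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if self.tr_seconds <= 0:
            raise InvalidConfigError("tr_seconds must be positive")
        if self.n_subjects < 1 or self.n_runs < 1:
            raise InvalidConfigError("n_subjects and n_runs must be >= 1")


@dataclass
class PipelineConfig:
    """All analysis constants plus the nested phantom configuration."""

    t_threshold: float = 3.1
    band_hz: Tuple[float, float] = (0.01, 0.1)
    n_sub_segments: int = 5
    n_ca1_segments: int = 3
    ca1_angle_deg: float = 60.0
    intensity_k_sd: float = 2.0
    art_intensity_pct: float = 1.3
    art_motion_mm: float = 0.3
    fwhm_mm: float = 1.5
    voxel_size_mm: float = 1.0
    fdr_q: float = 0.05
    #: average segments weighting slices by voxel count instead of equally
    voxel_weighted_slices: bool = False
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("t_threshold", "intensity_k_sd", "art_intensity_pct",
                     "art_motion_mm", "fdr_q", "ca1_angle_deg", "voxel_size_mm"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.fwhm_mm < 0:
            raise InvalidConfigError("fwhm_mm must be non-negative")
        if self.n_sub_segments < 2 or self.n_ca1_segments < 2:
            raise InvalidConfigError("segment counts must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        phantom_raw = raw.pop("phantom", {})
        if phantom_raw and not isinstance(phantom_raw, PhantomConfig):
            phantom_raw = dict(phantom_raw)
            for key in ("grid_dims", "band_hz"):
                if key in phantom_raw:
                    phantom_raw[key] = tuple(phantom_raw[key])
            # YAML mappings cannot carry tuple keys; accept "REGION/condition"
            if "condition_amplitudes" in phantom_raw:
                amps = {}
                for key, val in phantom_raw["condition_amplitudes"].items():
                    if isinstance(key, str) and "/" in key:
                        region, cond = key.split("/", 1)
                        amps[(region, cond)] = float(val)
                    else:
                        amps[key] = float(val)
                phantom_raw["condition_amplitudes"] = amps
            if "gradient_weights" in phantom_raw:
                gw = {}
                for target, srcs in phantom_raw["gradient_weights"].items():
                    gw[target] = {s: tuple(w) for s, w in srcs.items()}
                phantom_raw["gradient_weights"] = gw
            phantom = PhantomConfig(**phantom_raw)
        else:
            phantom = phantom_raw or PhantomConfig()
        known = {f.name for f in dataclasses.fields(cls)} - {"phantom"}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        if "band_hz" in raw:
            raw["band_hz"] = tuple(raw["band_hz"])
        return cls(phantom=phantom, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        ph = out["phantom"]
        ph["condition_amplitudes"] = {
            f"{r}/{c}": v for (r, c), v in ph["condition_amplitudes"].items()}
        return out
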