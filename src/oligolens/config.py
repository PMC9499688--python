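"""Analysis configuration: defaults, validation, provenance echoing."""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["AnalysisConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Aggregated configuration errors; one line per offending key."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class AnalysisConfig:
    """Pipeline parameters. Distances nm, angles degrees, temperature K.

    Defaults are the analysis conventions of the study this package
    models: heavy-atom contact cutoff 0.54 nm; H-bond criterion 0.35 nm
    with a D–H–A angle above 150°; Daura Cα-RMSD cutoff 0.45 nm; SASA
    water-probe radius 0.14 nm; ensemble temperature 310 K.
    """

    contact_cutoff: float = 0.54
    hbond_distance_cutoff: float = 0.35
    hbond_angle_cutoff: float = 150.0
    cluster_cutoff: float = 0.45
    stacking_parallel_max: float = 30.0
    stacking_herringbone_min: float = 50.0
    temperature: float = 310.0
    sasa_probe: float = 0.14
    sasa_points: int = 960
    pmf_bins: tuple[int, int] = (50, 50)
    top_k_clusters: int = 10
    convergence_threshold: float = 0.05
    window_a: tuple[int, int] | None = None    # [start, stop) frame ranges
    window_b: tuple[int, int] | None = None
    seed: int = 0

    def provenance_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_RANGES = {
    "contact_cutoff": (0.0, 5.0),
    "hbond_distance_cutoff": (0.0, 2.0),
    "hbond_angle_cutoff": (0.0, 180.0),
    "cluster_cutoff": (0.0, 10.0),
    "stacking_parallel_max": (0.0, 90.0),
    "stacking_herringbone_min": (0.0, 90.0),
    "temperature": (0.0, 10000.0),
    "sasa_probe": (0.0, 1.0),
    "convergence_threshold": (0.0, 1.0),
}


def validate_config(source) -> AnalysisConfig:
    """Build an AnalysisConfig from a YAML file path, YAML text, or dict.

    Absent keys take the package defaults; unknown keys are rejected with a
    spelling suggestion; out-of-range values are aggregated into a single
    error listing every offending key."""
    if isinstance(source, dict):
        data = dict(source)
    else:
        text = None
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = str(source)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(["config must be a key: value mapping"])

    known = set(AnalysisConfig.__dataclass_fields__)
    errors: list[str] = []
    clean: dict = {}
    for key, value in data.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown key {key!r}{suffix}")
            continue
        if key in _RANGES:
            lo, hi = _RANGES[key]
            try:
                value = float(value)
            except (TypeError, ValueError):
                errors.append(f"{key}: not a number ({value!r})")
                continue
            if not (lo < value <= hi):
                errors.append(f"{key}: {value} outside ({lo}, {hi}]")
                continue
        if key in ("pmf_bins", "window_a", "window_b") and value is not None:
            try:
                value = tuple(int(v) for v in value)
                assert len(value) == 2
            except Exception:
                errors.append(f"{key}: expected a pair of integers")
                continue
        if key in ("sasa_points", "top_k_clusters", "seed"):
            try:
                value = int(value)
            except (TypeError, ValueError):
                errors.append(f"{key}: not an integer ({value!r})")
                continue
            if key == "sasa_points" and value < 92:
                errors.append("sasa_points: must be >= 92")
                continue
        clean[key] = value
    if errors:
        raise ConfigError(errors)
    return AnalysisConfig(**clean)
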