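"""Run configuration: a single structured YAML file covering every stage.

Defaults equal the workflow's standard settings: SNR > 5, peak-picking half
window 20, binning tolerance 0.002 (relative), R² ≥ 0.9, three biological
replicates, 3 ppm annotation cutoff, m/z 200–2,000. CLI flags override
config keys one-to-one; concentrations may be given in µM (``doses_um``)
and are stored molar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigError
from .preprocess import PreprocessConfig
from .response import ResponseConfig
from .simulate import AnalytePeak, SimConfig


@dataclass
class AnnotateConfig:
    """Accurate-mass search settings."""

    max_ppm: float = 3.0
    adducts: tuple = ("[M+H]+", "[M+Na]+", "[M+K]+", "[M]+.")
    compound_table: str | None = None
    exclude_odd_acyl: bool = True
    #: window (Da) for listing candidate identities of low-resolution
    #: TOF features in run reports; exact ppm matching needs FTICR masses.
    tof_window_da: float = 0.3

    def validate(self) -> None:
        if self.max_ppm <= 0:
            raise ConfigError("max_ppm must be positive")
        if not self.adducts:
            raise ConfigError("at least one adduct required")


def _build(dc_type, data: dict, name: str):
    fields = {f for f in dc_type.__dataclass_fields__}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown {name} config keys: {sorted(unknown)}")
    try:
        return dc_type(**data)
    except TypeError as exc:
        raise ConfigError(f"bad {name} config: {exc}") from None


def sim_config_from_dict(data: dict, seed: int | None = None) -> SimConfig:
    data = dict(data)
    if "doses_um" in data:
        if "doses" in data:
            raise ConfigError("give doses (molar) or doses_um, not both")
        data["doses"] = tuple(float(d) * 1e-6 for d in data.pop("doses_um"))
    if "doses" in data:
        data["doses"] = tuple(float(d) for d in data["doses"])
    if "mz_range" in data:
        data["mz_range"] = tuple(float(v) for v in data["mz_range"])
    if "analytes" in data:
        data["analytes"] = [
            a if isinstance(a, AnalytePeak) else _build(AnalytePeak, dict(a), "analyte")
            for a in data["analytes"]
        ]
    if "matrix_ions" in data:
        data["matrix_ions"] = [tuple(map(float, ion)) for ion in data["matrix_ions"]]
    if seed is not None:
        data["seed"] = seed
    if "seed" not in data:
        raise ConfigError("simulate config requires a seed")
    cfg = _build(SimConfig, data, "simulate")
    cfg.validate()
    return cfg


@dataclass
class RunConfig:
    """All stage parameters plus the seed, resolvable from one YAML file."""

    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    response: ResponseConfig = field(default_factory=ResponseConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {"seed", "preprocess", "response", "annotate", "simulate"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        cfg = cls(seed=int(data.get("seed", 0)))
        if "preprocess" in data:
            cfg.preprocess = _build(PreprocessConfig, dict(data["preprocess"]), "preprocess")
        if "response" in data:
            r = dict(data["response"])
            if "exclude_mz" in r:
                r["exclude_mz"] = tuple(float(m) for m in r["exclude_mz"])
            cfg.response = _build(ResponseConfig, r, "response")
        if "annotate" in data:
            a = dict(data["annotate"])
            if "adducts" in a:
                a["adducts"] = tuple(a["adducts"])
            cfg.annotate = _build(AnnotateConfig, a, "annotate")
        cfg.simulate = dict(data.get("simulate", {}))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def validate(self) -> None:
        self.preprocess.validate()
        self.response.validate()
        self.annotate.validate()

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "preprocess": asdict(self.preprocess),
            "response": asdict(self.response),
            "annotate": asdict(self.annotate),
            "simulate": self.simulate,
        }
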