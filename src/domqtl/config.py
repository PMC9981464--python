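"""Run configuration: schema, validation, YAML loading.

A :class:`RunConfig` collects every knob of the pipeline — cohort
simulation (or input paths), transform and kinship choices, thresholds,
permutation and mediation settings, integration windows and the root
seed. Validation raises :class:`~domqtl.errors.ConfigError` with explicit
messages; the resolved configuration is written next to the outputs of
every run and hashed into the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError


@dataclass
class SimulateConfig:
    n_mice: int = 200
    n_chr: int = 20
    markers_per_chr: int = 100
    chr_length_mbp: float = 100.0
    n_generations: int = 20
    softness: float = 0.02
    n_waves: int = 5
    n_microbe_traits: int = 40
    n_lipid_traits: int = 20
    n_qtl_traits: int = 8
    qtl_var_frac: float = 0.2
    h2_polygenic: float = 0.3
    zero_inflation: float = 0.1
    mediation_chrom: str = "1"
    mediation_pos_mbp: float = 92.9
    mediation_alpha: float = 1.0
    mediation_qtl_var_frac: float = 0.35
    lipid_residual_sd: float = 0.5
    mediation_mode: str = "mediated"


@dataclass
class InputConfig:
    probs: str = ""
    microbe_traits: str = ""
    lipid_traits: str = ""
    covariates: str = ""


@dataclass
class AnalysisConfig:
    transform: str = "rankz"          # rankz | none
    kinship: str = "loco"             # loco | overall | none
    n_perm: int = 0
    alphas: tuple = (0.05, 0.2)
    suggestive_lod: float = 6.0
    threshold_traits: str = "first"   # first | all
    refit_h2_in_perm: bool = True


@dataclass
class PrevalenceConfig:
    enabled: bool = True
    min_value: float = 0.01
    min_fraction: float = 0.2


@dataclass
class MediationSection:
    z_threshold: float = -6.0
    direction: str = "both"           # a2b | b2a | both
    min_overlap: int = 50
    null_set: str = "all"
    min_group_size: int = 5
    # median/MAD null by default: with the pipeline's small candidate sets a
    # strong mediator would inflate a mean/sd null and cap |z| near sqrt(k-1)
    robust: bool = True


@dataclass
class IntegrationConfig:
    window_mbp: float = 4.0
    bin_mbp: float = 1.0
    min_hotspot_traits: int = 5
    hotspot_lod_floor: float = 6.0
    fc_min: float = 10.0


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "domqtl_run"
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    inputs: InputConfig | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    prevalence: PrevalenceConfig = field(default_factory=PrevalenceConfig)
    mediation: MediationSection = field(default_factory=MediationSection)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ConfigError("config needs either a 'simulate' or an 'inputs' section")
        a = self.analysis
        if a.transform not in ("rankz", "none"):
            raise ConfigError(f"analysis.transform must be 'rankz' or 'none', got {a.transform!r}")
        if a.kinship not in ("loco", "overall", "none"):
            raise ConfigError(f"analysis.kinship must be loco/overall/none, got {a.kinship!r}")
        if a.n_perm < 0:
            raise ConfigError(f"analysis.n_perm must be >= 0, got {a.n_perm}")
        for alpha in a.alphas:
            if not 0 < alpha < 1:
                raise ConfigError(f"alpha levels must be in (0,1), got {alpha}")
        if a.threshold_traits not in ("first", "all"):
            raise ConfigError(f"analysis.threshold_traits must be 'first' or 'all'")
        if self.mediation.direction not in ("a2b", "b2a", "both"):
            raise ConfigError(
                f"mediation.direction must be a2b/b2a/both, got {self.mediation.direction!r}"
            )
        if self.simulate is not None:
            s = self.simulate
            if s.n_mice < 8:
                raise ConfigError(f"simulate.n_mice must be >= 8, got {s.n_mice}")
            if s.mediation_mode not in ("mediated", "independent", "none"):
                raise ConfigError(f"simulate.mediation_mode must be mediated/independent/none")

    def resolved(self) -> dict:
        d = asdict(self)
        d["analysis"]["alphas"] = list(self.analysis.alphas)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {
            "simulate": SimulateConfig,
            "inputs": InputConfig,
            "analysis": AnalysisConfig,
            "prevalence": PrevalenceConfig,
            "mediation": MediationSection,
            "integration": IntegrationConfig,
        }
        kwargs: dict = {}
        for key, val in d.items():
            if key in ("seed", "out_dir"):
                kwargs[key] = val
            elif key in known:
                if val is None:
                    kwargs[key] = None
                    continue
                section_cls = known[key]
                valid = {f for f in section_cls.__dataclass_fields__}
                unknown = set(val) - valid
                if unknown:
                    raise ConfigError(
                        f"unknown option(s) {sorted(unknown)} in config section {key!r}; "
                        f"valid options: {sorted(valid)}"
                    )
                if "alphas" in val:
                    val = dict(val, alphas=tuple(val["alphas"]))
                kwargs[key] = section_cls(**val)
            else:
                raise ConfigError(f"unknown top-level config key {key!r}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as f:
                d = yaml.safe_load(f)
        except (OSError, yaml.YAMLError) as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        if not isinstance(d, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.resolved(), f, sort_keys=True)
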