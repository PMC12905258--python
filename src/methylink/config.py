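"""Pipeline configuration: thresholds, model specs, simulation settings.

Every analysis threshold carries the published default (FDR alpha 0.05,
I2 ceiling 90 with strict ">" removal, colocalisation PP.H4 > 0.9,
+/-100 kb cis window, minimum 50 participants per probe, 3 x IQR
outlier rule, colocalisation priors 1e-4 / 1e-4 / 5e-6).  The whole
configuration round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .synthetic import SimulationConfig

__all__ = ["Thresholds", "BaconSettings", "PipelineConfig"]


@dataclass
class Thresholds:
    fdr_alpha: float = 0.05
    i2_max: float = 90.0
    i2_strict: bool = True       # remove I2 > max (Results wording);
                                 # False removes I2 >= max (Methods wording)
    pp4: float = 0.9
    window: int = 100_000
    min_n: int = 50
    iqr_k: float = 3.0
    coloc_priors: tuple = (1e-4, 1e-4, 5e-6)
    r2_max: float = 0.001
    palindromic_eaf: tuple = (0.42, 0.58)


@dataclass
class BaconSettings:
    n_iter: int = 5000
    burn_in: int = 2000
    prior_alpha: float = 1.28
    prior_beta: float = 0.36
    method: str = "gibbs"


@dataclass
class PipelineConfig:
    seed: int = 0
    lod_mode: str = "remove"
    thresholds: Thresholds = field(default_factory=Thresholds)
    bacon: BaconSettings = field(default_factory=BaconSettings)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def demo(cls, seed: int = 0) -> "PipelineConfig":
        """A small configuration for the end-to-end demonstration run.

        Scaled down from the full study conditions (fewer CpGs, smaller
        cohorts, a shorter warm-started chain for the bias/inflation
        fit) so the complete pipeline finishes in about a minute.
        """
        sim = SimulationConfig(
            n_per_cohort=(250, 220, 400), n_cpgs=600,
            n_causal_forward=40, n_causal_reverse=8,
            effect_sd=0.012, heterogeneity_sd=0.004, n_heterogeneous=3,
            confounding_strength=0.6, n_confounded=25,
            n_mediating=8, seed=seed)
        return cls(seed=seed, simulation=sim,
                   bacon=BaconSettings(n_iter=1200, burn_in=400))

    def to_yaml(self, path=None) -> str:
        doc = asdict(self)
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    doc = yaml.safe_load(fh)
            except (OSError, ValueError):
                doc = yaml.safe_load(source)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: dict) -> "PipelineConfig":
        def build(klass, d):
            names = {f.name for f in fields(klass)}
            kw = {}
            for k, v in d.items():
                if k not in names:
                    raise ValueError(f"unknown config key {k!r} for "
                                     f"{klass.__name__}")
                kw[k] = tuple(v) if isinstance(v, list) else v
            return klass(**kw)

        return cls(
            seed=doc.get("seed", 0),
            lod_mode=doc.get("lod_mode", "remove"),
            thresholds=build(Thresholds, doc.get("thresholds", {})),
            bacon=build(BaconSettings, doc.get("bacon", {})),
            simulation=build(SimulationConfig, doc.get("simulation", {})),
        )
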