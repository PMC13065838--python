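"""Run configuration: every pipeline threshold with its default.

Defaults are the published analysis settings (genome-wide significance
5e-8, clumping r^2 0.001 within 10 Mbp, F >= 10, cis window 1 Mbp, MHC
chr6:28.5-33.5 Mb, PAV proxy r^2 0.6, coloc priors 1e-4/1e-4/1e-5 with a
100 kb window and >= 50 variants, PP_H4 support 0.8), so a bare demo run
reproduces the headline filtering rules. The config round-trips through
YAML; dotted-path overrides support command-line ``-O key=value`` flags.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError


@dataclass
class SimulateSection:
    n_genes: int = 5
    n_diseases: int = 3
    n_region_variants: int = 120
    exposure_z: float = 14.0
    outcome_z: float = 10.0
    n_exposure: int = 35_000
    n_outcome: int = 150_000
    causal_pairs: list = field(default_factory=lambda: [[0, 0]])


@dataclass
class InstrumentsSection:
    p_thresh: float = 5e-8
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    f_min: float = 10.0
    cis_window_bp: int = 1_000_000
    mhc_chrom: str = "6"
    mhc_lo: int = 28_500_000
    mhc_hi: int = 33_500_000
    pav_proxy_r2: float = 0.6
    palindrome_window: float = 0.08


@dataclass
class MRSection:
    random_effects: bool = True
    presso_n_sim: int = 1000
    n_boot: int = 1000
    outlier_alpha: float = 0.05


@dataclass
class ColocSection:
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quant: float = 0.2
    prior_sd_binary: float = 0.15
    window_bp: int = 100_000
    min_variants: int = 50


@dataclass
class IntegrateSection:
    nominal_alpha: float = 0.05
    pp_h4_support: float = 0.8


@dataclass
class RunConfig:
    """Full pipeline configuration (paths, thresholds, seed)."""

    data_dir: str = "data"
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    genome_build: str = "GRCh38"  # carried as a label, never inferred
    simulate: SimulateSection = field(default_factory=SimulateSection)
    instruments: InstrumentsSection = field(default_factory=InstrumentsSection)
    mr: MRSection = field(default_factory=MRSection)
    coloc: ColocSection = field(default_factory=ColocSection)
    integrate: IntegrateSection = field(default_factory=IntegrateSection)

    def validate(self) -> None:
        checks = [
            ("instruments.p_thresh", 0 < self.instruments.p_thresh < 1),
            ("instruments.clump_r2", 0 < self.instruments.clump_r2 <= 1),
            ("instruments.clump_window_bp", self.instruments.clump_window_bp > 0),
            ("instruments.f_min", self.instruments.f_min >= 0),
            ("instruments.cis_window_bp", self.instruments.cis_window_bp > 0),
            ("instruments.palindrome_window",
             0 <= self.instruments.palindrome_window < 0.5),
            ("mr.presso_n_sim", self.mr.presso_n_sim >= 1),
            ("mr.n_boot", self.mr.n_boot >= 1),
            ("coloc.p12",
             0 < self.coloc.p12 <= min(self.coloc.p1, self.coloc.p2) < 1),
            ("coloc.window_bp", self.coloc.window_bp > 0),
            ("coloc.min_variants", self.coloc.min_variants >= 1),
            ("integrate.nominal_alpha", 0 < self.integrate.nominal_alpha < 1),
            ("integrate.pp_h4_support", 0 < self.integrate.pp_h4_support <= 1),
            ("simulate.n_genes", self.simulate.n_genes >= 1),
            ("simulate.n_diseases", self.simulate.n_diseases >= 1),
            ("seed", isinstance(self.seed, int)),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"invalid config value: {name}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        sections = {
            "simulate": SimulateSection,
            "instruments": InstrumentsSection,
            "mr": MRSection,
            "coloc": ColocSection,
            "integrate": IntegrateSection,
        }
        for key, value in data.items():
            if key in sections:
                known = {f.name for f in dataclasses.fields(sections[key])}
                bad = set(value) - known
                if bad:
                    raise ConfigError(
                        f"unknown config field: {key}.{sorted(bad)[0]}"
                    )
                kwargs[key] = sections[key](**value)
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown config field: {key}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls.from_dict(data or {})
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def apply_override(self, dotted: str, raw: str) -> None:
        """Apply one ``section.field=value`` command-line override."""
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            if not hasattr(obj, part):
                raise ConfigError(f"unknown config field: {dotted}")
            obj = getattr(obj, part)
        leaf = parts[-1]
        if not hasattr(obj, leaf):
            raise ConfigError(f"unknown config field: {dotted}")
        current = getattr(obj, leaf)
        value = yaml.safe_load(raw)
        if current is not None and not isinstance(value, type(current)):
            try:
                value = type(current)(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(
                    f"invalid value for {dotted}: {raw!r}"
                ) from exc
        setattr(obj, leaf, value)
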