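"""Declarative run configuration (YAML) with the stock defaults.

All physical defaults follow the reference protocol: 20 fs time step,
tau_t = 0.1 ps, 300 K, 1.1 nm non-bonded cutoff, hysteresis cutoffs
r_b = 0.6 nm / r_u = 0.9 nm, 0.3 ns sampling, 15 ns transition lag,
0.7 nm LENS cutoff, and the chain-stopper series 0/40/120/200/300/400
(2000-monomer systems) or 10/30/50/75/100 (500-monomer systems).
"""

from __future__ import annotations

from pydantic import BaseModel, Field, field_validator, model_validator

C_SERIES_N2000 = (0, 40, 120, 200, 300, 400)
C_SERIES_N500 = (0, 10, 30, 50, 75, 100)


class SystemConfig(BaseModel):
    counts: dict[str, int]
    box_edge: float = Field(gt=0)
    temperature: float = Field(default=300.0, gt=0)
    seed: int = 0
    placement_min_distance: float = Field(default=0.8, gt=0)


class IntegratorConfig(BaseModel):
    #: None selects the species default (20 fs; 10 fs for dipolar systems)
    dt_fs: float | None = Field(default=None, gt=0)
    tau_t_ps: float = Field(default=0.1, gt=0)
    seed: int = 0


class RunSection(BaseModel):
    duration_ns: float = Field(gt=0)
    sample_every_ns: float = Field(default=0.3, gt=0)
    minimise: bool = True


class AnalysisConfig(BaseModel):
    r_b: float = Field(default=0.6, gt=0)
    r_u: float = Field(default=0.9, gt=0)
    dtau_ns: float = Field(default=15.0, gt=0)
    lens_cutoff: float = Field(default=0.7, gt=0)
    min_row_count: int = Field(default=500, ge=0)

    @model_validator(mode="after")
    def _check(self):
        if self.r_b >= self.r_u:
            raise ValueError("r_b must be below r_u")
        return self


class PerturbationConfig(BaseModel):
    c_series: tuple[int, ...] = C_SERIES_N2000
    seed: int = 0

    @field_validator("c_series")
    @classmethod
    def _nonneg(cls, v):
        if any(c < 0 for c in v):
            raise ValueError("chain-stopper amounts must be >= 0")
        return v


class RunConfig(BaseModel):
    system: SystemConfig
    integrator: IntegratorConfig = IntegratorConfig()
    run: RunSection
    analysis: AnalysisConfig = AnalysisConfig()
    perturbation: PerturbationConfig = PerturbationConfig()
    output_dir: str = "out"

    @model_validator(mode="after")
    def _check(self):
        ratio = self.analysis.dtau_ns / self.run.sample_every_ns
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("the transition lag dtau must be an integer "
                             "multiple of the sampling period")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))
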