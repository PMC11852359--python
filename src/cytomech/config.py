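"""Run configuration: one plain-text YAML file covering scene, materials,
solver and output options.

Units are strict SI — Pa, m, m**2, N — and are spelled out in the field
names.  Unknown keys are rejected; omitted fields fall back to the built-in
defaults (the literature material table, 6.0 Pa pressure, 2+6 increments).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .materials import (
    DEFAULT_TENDON_PRESTRESS,
    ECM_NU,
    ECM_SOFT_E,
    ECM_STIFF_E,
    MaterialSpec,
    MembraneMaterial,
    SolidMaterial,
    TrussMaterial,
)
from .solver import SolverConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config", "config_hash"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


def _positive(name):
    def check(cls, v):
        if v is not None and not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
        return v

    return check


class SolidMaterialConfig(_Strict):
    young_modulus_pa: float
    poisson_ratio: float

    @field_validator("young_modulus_pa")
    @classmethod
    def _e(cls, v):
        if not v > 0:
            raise ValueError(f"young_modulus_pa must be positive, got {v}")
        return v

    @field_validator("poisson_ratio")
    @classmethod
    def _nu(cls, v):
        if not (0.0 <= v < 0.5):
            raise ValueError(f"poisson_ratio must satisfy 0 <= nu < 0.5, got {v}")
        return v


class MembraneMaterialConfig(SolidMaterialConfig):
    thickness_m: float

    @field_validator("thickness_m")
    @classmethod
    def _t(cls, v):
        if not v > 0:
            raise ValueError(f"thickness_m must be positive, got {v}")
        return v


class TrussMaterialConfig(_Strict):
    young_modulus_pa: float
    cross_section_area_m2: float
    prestress_force_n: float = 0.0

    @field_validator("young_modulus_pa", "cross_section_area_m2")
    @classmethod
    def _pos(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v


class MaterialsConfig(_Strict):
    """Literature elastic constants for each component; ECM modulus chosen by the scenario's
    ``ecm_variant``."""

    ecm_young_modulus_stiff_pa: float = ECM_STIFF_E
    ecm_young_modulus_soft_pa: float = ECM_SOFT_E
    ecm_poisson_ratio: float = ECM_NU
    cytoplasm: SolidMaterialConfig = SolidMaterialConfig(
        young_modulus_pa=100.0, poisson_ratio=0.37
    )
    nucleus: SolidMaterialConfig = SolidMaterialConfig(
        young_modulus_pa=400.0, poisson_ratio=0.37
    )
    cortex: MembraneMaterialConfig = MembraneMaterialConfig(
        young_modulus_pa=1000.0, poisson_ratio=0.3, thickness_m=6.0e-9
    )
    nuclear_membrane: MembraneMaterialConfig = MembraneMaterialConfig(
        young_modulus_pa=1000.0, poisson_ratio=0.3, thickness_m=6.0e-9
    )
    microtubules: TrussMaterialConfig = TrussMaterialConfig(
        young_modulus_pa=1.2e9, cross_section_area_m2=190.0e-18
    )
    actin: TrussMaterialConfig = TrussMaterialConfig(
        young_modulus_pa=2.6e9,
        cross_section_area_m2=18.0e-18,
        prestress_force_n=DEFAULT_TENDON_PRESTRESS,
    )

    @field_validator("ecm_young_modulus_stiff_pa", "ecm_young_modulus_soft_pa")
    @classmethod
    def _e(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    @field_validator("ecm_poisson_ratio")
    @classmethod
    def _nu(cls, v):
        if not (0.0 <= v < 0.5):
            raise ValueError(f"ecm_poisson_ratio must satisfy 0 <= nu < 0.5, got {v}")
        return v

    def to_material_spec(self, ecm_variant: str) -> MaterialSpec:
        if ecm_variant == "stiff":
            ecm_e = self.ecm_young_modulus_stiff_pa
        elif ecm_variant == "soft":
            ecm_e = self.ecm_young_modulus_soft_pa
        else:
            raise ConfigError(f"unknown ecm_variant '{ecm_variant}'")
        return MaterialSpec(
            ecm=SolidMaterial(ecm_e, self.ecm_poisson_ratio),
            cytoplasm=SolidMaterial(
                self.cytoplasm.young_modulus_pa, self.cytoplasm.poisson_ratio
            ),
            nucleus=SolidMaterial(
                self.nucleus.young_modulus_pa, self.nucleus.poisson_ratio
            ),
            cortex=MembraneMaterial(
                self.cortex.young_modulus_pa,
                self.cortex.poisson_ratio,
                self.cortex.thickness_m,
            ),
            nuclear_membrane=MembraneMaterial(
                self.nuclear_membrane.young_modulus_pa,
                self.nuclear_membrane.poisson_ratio,
                self.nuclear_membrane.thickness_m,
            ),
            microtubule_bar=TrussMaterial(
                self.microtubules.young_modulus_pa,
                self.microtubules.cross_section_area_m2,
                self.microtubules.prestress_force_n,
            ),
            actin_tendon=TrussMaterial(
                self.actin.young_modulus_pa,
                self.actin.cross_section_area_m2,
                self.actin.prestress_force_n,
            ),
        )


class SceneConfig(_Strict):
    cell_radius_m: float = 10e-6
    nucleus_radius_m: float = 5e-6
    mesh_resolution_m: float = 2.5e-6
    pressure_pa: float = 6.0
    single_box_side_m: float = 40e-6
    group_spacing_m: float = 25e-6
    group_nx: int = 3
    group_ny: int = 3
    group_nz: int = 2
    attachment: Literal["cortex", "nuclear_membrane"] = "cortex"
    oblate_squash: Optional[float] = None  # optional shape transform (z scale)
    # Desk-scale discretization (surface grid per cube-face edge and radial
    # layer counts).  ``None`` derives a value from mesh_resolution_m.  The
    # defaults give the single-cell and group scenes *identical* per-cell
    # discretization -- same surface grid and the same ECM layer thickness
    # next to the cortex -- so that per-component maxima are comparable
    # across layouts.
    single_n_surface: Optional[int] = 4
    single_n_ecm_layers: Optional[int] = 8
    group_n_surface: Optional[int] = 4
    group_n_nucleus_layers: Optional[int] = 2
    group_n_cytoplasm_layers: Optional[int] = 2
    group_n_ecm_layers: Optional[int] = 2

    @field_validator(
        "cell_radius_m",
        "nucleus_radius_m",
        "mesh_resolution_m",
        "single_box_side_m",
        "group_spacing_m",
    )
    @classmethod
    def _pos(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    @field_validator("group_nx", "group_ny", "group_nz")
    @classmethod
    def _n(cls, v, info):
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1, got {v}")
        return v


class SolverSection(_Strict):
    n_prestress_increments: int = 2
    n_load_increments: int = 6
    residual_tolerance: float = 1e-8
    absolute_tolerance_n: float = 1e-18
    max_newton_iterations: int = 20
    geometric_nonlinearity: bool = True

    def to_solver_config(self) -> SolverConfig:
        return SolverConfig(
            n_prestress_increments=self.n_prestress_increments,
            n_load_increments=self.n_load_increments,
            residual_tolerance=self.residual_tolerance,
            absolute_tolerance=self.absolute_tolerance_n,
            max_newton_iterations=self.max_newton_iterations,
            geometric_nonlinearity=self.geometric_nonlinearity,
        )


class OutputConfig(_Strict):
    directory: str = "results"
    write_vtu: bool = True
    log10_hmh_floor_pa: float = 1e-12  # clamp for decimal-log stress channels

    @field_validator("log10_hmh_floor_pa")
    @classmethod
    def _floor(cls, v):
        if not v > 0:
            raise ValueError(f"log10_hmh_floor_pa must be positive, got {v}")
        return v


class RunConfig(_Strict):
    scene: SceneConfig = Field(default_factory=SceneConfig)
    materials: MaterialsConfig = Field(default_factory=MaterialsConfig)
    solver: SolverSection = Field(default_factory=SolverSection)
    output: OutputConfig = Field(default_factory=OutputConfig)
    seed: int = 0


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` naming the offending key on any schema
    violation or non-physical value; an empty file yields the full defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries the key path
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc


def dump_config(config: RunConfig) -> str:
    """Fully resolved configuration as YAML (round-trips through load)."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:16]
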