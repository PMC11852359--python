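"""Per-component elastic constants.

Defaults are literature values for this cell–matrix system: linear
elastic solids for cytoplasm, nucleus and ECM; thin linear-elastic membranes
for the cortex and nuclear membrane; stiff elastic fibres for the
cytoskeleton, with the actin tendons carrying a force-controlled prestress.
All quantities are SI (Pa, m, m**2, N).
"""

from __future__ import annotations

from dataclasses import dataclass, replace


class MaterialError(ValueError):
    pass


def _check_elastic(E: float, nu: float, what: str):
    if not E > 0:
        raise MaterialError(f"{what}: Young's modulus must be positive, got {E}")
    if not (0.0 <= nu < 0.5):
        raise MaterialError(f"{what}: Poisson ratio must satisfy 0 <= nu < 0.5, got {nu}")


@dataclass(frozen=True)
class SolidMaterial:
    young_modulus: float  # Pa
    poisson_ratio: float

    def __post_init__(self):
        _check_elastic(self.young_modulus, self.poisson_ratio, "solid")

    @property
    def lame(self):
        E, nu = self.young_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu


@dataclass(frozen=True)
class MembraneMaterial:
    young_modulus: float  # Pa
    poisson_ratio: float
    thickness: float  # m

    def __post_init__(self):
        _check_elastic(self.young_modulus, self.poisson_ratio, "membrane")
        if not self.thickness > 0:
            raise MaterialError("membrane thickness must be positive")

    @property
    def plane_stress_lame(self):
        """Lamé-like constants of the plane-stress constitutive matrix."""
        E, nu = self.young_modulus, self.poisson_ratio
        lam_bar = E * nu / (1 - nu**2)
        mu = E / (2 * (1 + nu))
        return lam_bar, mu


@dataclass(frozen=True)
class TrussMaterial:
    young_modulus: float  # Pa
    cross_section_area: float  # m**2
    prestress_force: float = 0.0  # N, tension positive

    def __post_init__(self):
        if not self.young_modulus > 0:
            raise MaterialError("truss Young's modulus must be positive")
        if not self.cross_section_area > 0:
            raise MaterialError("truss cross-section area must be positive")


#: Default tendon prestress force (N).  Cytoskeletal prestress has no
#: agreed literature value; this one puts the tendon uniaxial stress after
#: the prestress step at ~1.1e5 Pa, the order expected for prestressed
#: actin networks.  The stiff/soft orderings are insensitive to it over at
#: least a 10x range (verified in the acceptance suite).
DEFAULT_TENDON_PRESTRESS = 2.0e-12

ECM_STIFF_E = 56_200.0  # Pa, alginate-like gel
ECM_SOFT_E = 30.0  # Pa, medium-like gel
ECM_NU = 0.4777


@dataclass(frozen=True)
class MaterialSpec:
    """The full per-component material table for one scenario."""

    ecm: SolidMaterial
    cytoplasm: SolidMaterial
    nucleus: SolidMaterial
    cortex: MembraneMaterial
    nuclear_membrane: MembraneMaterial
    microtubule_bar: TrussMaterial
    actin_tendon: TrussMaterial

    @staticmethod
    def defaults(
        ecm_variant: str = "stiff",
        tendon_prestress: float = DEFAULT_TENDON_PRESTRESS,
        ecm_young_modulus: float | None = None,
    ) -> "MaterialSpec":
        if ecm_young_modulus is None:
            if ecm_variant == "stiff":
                ecm_young_modulus = ECM_STIFF_E
            elif ecm_variant == "soft":
                ecm_young_modulus = ECM_SOFT_E
            else:
                raise MaterialError("ecm_variant must be 'stiff' or 'soft'")
        return MaterialSpec(
            ecm=SolidMaterial(ecm_young_modulus, ECM_NU),
            cytoplasm=SolidMaterial(100.0, 0.37),
            nucleus=SolidMaterial(400.0, 0.37),
            cortex=MembraneMaterial(1000.0, 0.3, 6.0e-9),
            nuclear_membrane=MembraneMaterial(1000.0, 0.3, 6.0e-9),
            microtubule_bar=TrussMaterial(1.2e9, 190.0e-18, 0.0),
            actin_tendon=TrussMaterial(2.6e9, 18.0e-18, tendon_prestress),
        )

    def with_prestress(self, force: float) -> "MaterialSpec":
        return replace(self, actin_tendon=replace(self.actin_tendon, prestress_force=force))
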