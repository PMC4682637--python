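"""Model configuration: schema, validation, unit conversion, serialization.

Configs are written in human units (mmol l^-1, nm, um) and converted to SI
internally (note mmol l^-1 == mol m^-3 numerically).  The packaged default
(``data/default.yaml``) carries the physicochemical parameter set of the
rabbit-heart model: compartment volume fractions and membrane surface
densities from ultrastructural morphometry, albumin/FABP binding constants,
and the boundary-zone reaction-rate length d_Cp.

The albumin binding-site concentration is n_Alb * [Alb] (three high-affinity
sites per albumin with the average equilibrium constant); the interstitial
albumin concentration is a fixed fraction (86%) of the capillary one.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from fatrans.boundary_physics import CompartmentSpec, MembraneSpec
from fatrans.capillary_geometry import CapillaryBedSpec

__all__ = ["ModelConfig", "load_config", "default_config", "default_config_path"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GeneralConfig(_Strict):
    C_lipid: float = Field(8e5, gt=0, description="lipid/water partition coefficient of Fa")
    D_Fa: float = Field(4.8e-10, gt=0, description="free-Fa diffusion coefficient [m2/s]")
    D_mem: float = Field(4e-12, gt=0, description="intramembrane Fa diffusion [m2/s]")
    h_mem_nm: float = Field(5.0, gt=0, description="bilayer thickness [nm]")
    n_Alb: int = Field(3, gt=0, description="Fa binding sites per albumin")
    d_Cp_nm: float = Field(5.0, ge=0, description="membrane reaction rate length [nm]")
    M_Fa: float = Field(256.0, gt=0, description="Fa molar mass [g/mol] (metadata)")
    M_Cp_alb: float = Field(67000.0, gt=0, description="albumin molar mass (metadata)")
    M_Cp_fabp: float = Field(15000.0, gt=0, description="FABP molar mass (metadata)")


class CompartmentConfig(_Strict):
    volume_fraction: float = Field(gt=0, lt=1)
    D_Cp: float = Field(gt=0, description="carrier diffusion coefficient [m2/s]")
    K_CpFa: float = Field(9e-6, gt=0, description="binding constant [mmol/l == mol/m3]")
    tau_CpFa: float = Field(0.01, gt=0, description="dissociation time constant [s]")
    Cp_total: float | None = Field(None, gt=0, description="[mmol/l]; None => from albumin")
    Cp_ratio_to_cap: float | None = Field(None, gt=0, le=1)
    h_diff_nm: float | None = Field(None, gt=0, description="diffusion thickness [nm]")


class MembraneConfig(_Strict):
    S_per_Vall: float = Field(gt=0, description="surface density [m2 per m3 tissue]")
    d_Cp_left_nm: float | None = Field(None, ge=0)
    d_Cp_right_nm: float | None = Field(None, ge=0)


class AuxVolumes(_Strict):
    """Volume bookkeeping of compartments that are not dynamic states."""

    is2: float = Field(0.060, gt=0, lt=1)
    ttub: float = Field(0.010, ge=0, lt=1)
    lv: float = Field(0.059, ge=0, lt=1)
    isc: float = Field(0.010, ge=0, lt=1)
    is2_mid_S_per_Vall: float = Field(94000.0, gt=0)
    is2_Cp_ratio_to_cap: float = Field(0.86, gt=0, le=1)


class BedConfig(_Strict):
    z0_um: float = Field(800.0, gt=0, description="mean capillary length [um]")
    sigma_cap: float = Field(0.5, gt=0, description="relative length dispersion")
    d_cap_um: float = Field(5.2, gt=0, description="capillary diameter [um]")


class ExperimentConfig(_Strict):
    inlet_Alb: float = Field(gt=0, description="perfusate albumin [mmol/l]")
    inlet_Fa_total: float = Field(gt=0, description="perfusate total Fa [mmol/l]")
    q_tot: float = Field(gt=0, description="flow per tissue volume [s^-1]")
    target_extraction: float | None = Field(None, ge=0, le=0.95)
    R_met: float | None = Field(None, ge=0, description="metabolic rate constant [s^-1]")

    @model_validator(mode="after")
    def _one_of(self) -> "ExperimentConfig":
        if (self.target_extraction is None) == (self.R_met is None):
            raise ValueError("specify exactly one of target_extraction or R_met")
        return self


class NumericsConfig(_Strict):
    n_z: int = Field(120, ge=16, description="z cells")
    area_cutoff: float = Field(1e-4, gt=0, lt=1)
    dt: float = Field(0.02, gt=0, description="tracer time step [s]")
    t_max: float = Field(150.0, gt=0, description="tracer horizon [s]")
    steady_tol: float = Field(1e-8, gt=0, description="outer fixed-point tolerance")
    max_outer: int = Field(200, gt=0)
    damping: float = Field(0.5, gt=0, le=1, description="free-Cp update damping")
    deconv_dt: float = Field(0.1, gt=0)
    deconv_smoothing: float = Field(1e-4, ge=0)
    deconv_max_time: float = Field(60.0, gt=0)
    seed: int = Field(0, ge=0)


class ModelConfig(_Strict):
    general: GeneralConfig = GeneralConfig()
    compartments: dict[Literal["cap", "ec", "is1", "myo"], CompartmentConfig]
    membranes: dict[Literal["cap_ec", "ec_is1", "is1_myo"], MembraneConfig]
    aux_volumes: AuxVolumes = AuxVolumes()
    bed: BedConfig = BedConfig()
    experiment: ExperimentConfig
    numerics: NumericsConfig = NumericsConfig()

    @model_validator(mode="after")
    def _complete(self) -> "ModelConfig":
        missing = {"cap", "ec", "is1", "myo"} - set(self.compartments)
        if missing:
            raise ValueError(f"missing compartments: {sorted(missing)}")
        missing = {"cap_ec", "ec_is1", "is1_myo"} - set(self.membranes)
        if missing:
            raise ValueError(f"missing membranes: {sorted(missing)}")
        for name in ("ec", "is1"):
            if self.compartments[name].h_diff_nm is None:
                raise ValueError(f"compartment {name} requires h_diff_nm")
        return self

    # ---- derived SI-unit builders -------------------------------------

    def cp_total(self, name: str) -> float:
        """Total binding-site concentration [mol m^-3] of a compartment."""
        cc = self.compartments[name]
        if cc.Cp_total is not None:
            return cc.Cp_total
        cap_sites = self.general.n_Alb * self.experiment.inlet_Alb
        if name == "cap":
            return cap_sites
        if cc.Cp_ratio_to_cap is not None:
            return cc.Cp_ratio_to_cap * cap_sites
        raise ValueError(f"compartment {name} has neither Cp_total nor Cp_ratio_to_cap")

    def compartment_spec(self, name: str) -> CompartmentSpec:
        cc = self.compartments[name]
        return CompartmentSpec(
            name=name,
            D_Fa=self.general.D_Fa,
            D_Cp=cc.D_Cp,
            K_CpFa=cc.K_CpFa,
            tau_CpFa=cc.tau_CpFa,
            Cp_total=self.cp_total(name),
            volume_fraction=cc.volume_fraction,
            h_diff=None if cc.h_diff_nm is None else cc.h_diff_nm * 1e-9,
        )

    def membrane_spec(self, name: str) -> MembraneSpec:
        mc = self.membranes[name]
        d_default = self.general.d_Cp_nm
        left = mc.d_Cp_left_nm if mc.d_Cp_left_nm is not None else d_default
        right = mc.d_Cp_right_nm if mc.d_Cp_right_nm is not None else d_default
        return MembraneSpec(
            name=name,
            S_per_Vall=mc.S_per_Vall,
            h_mem=self.general.h_mem_nm * 1e-9,
            C_lipid=self.general.C_lipid,
            D_mem=self.general.D_mem,
            d_Cp_left=left * 1e-9,
            d_Cp_right=right * 1e-9,
        )

    def bed_spec(self) -> CapillaryBedSpec:
        return CapillaryBedSpec(
            z0=self.bed.z0_um * 1e-6,
            sigma_cap=self.bed.sigma_cap,
            V_cap=self.compartments["cap"].volume_fraction,
            S_cap_total=self.membranes["cap_ec"].S_per_Vall,
            q_tot=self.experiment.q_tot,
            d_cap=self.bed.d_cap_um * 1e-6,
        )

    def boundary_layer_thickness(self, name: str) -> float:
        """Aqueous thickness h [m] entering the full P_b prefactor.

        ec/is1 use their morphometric diffusion thickness; cap uses the
        cylinder volume-to-surface length d_cap/4; myo uses its volume over
        its bounding membrane area (sarcolemma plus both is2 faces).
        """
        if name in ("ec", "is1"):
            return self.compartments[name].h_diff_nm * 1e-9
        if name == "cap":
            return self.bed.d_cap_um * 1e-6 / 4.0
        if name == "myo":
            s = self.membranes["is1_myo"].S_per_Vall + 2.0 * self.aux_volumes.is2_mid_S_per_Vall
            return self.compartments["myo"].volume_fraction / s
        raise KeyError(name)

    def replace_value(self, path: str, value) -> "ModelConfig":
        """Return a copy with the dotted-path scalar replaced (for sensitivity)."""
        data = self.model_dump()
        node = data
        keys = path.split(".")
        for k in keys[:-1]:
            node = node[k]
        if keys[-1] not in node:
            raise KeyError(f"config has no entry {path!r}")
        node[keys[-1]] = value
        return ModelConfig.model_validate(data)

    def get_value(self, path: str):
        node = self.model_dump()
        for k in path.split("."):
            node = node[k]
        return node


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML/JSON model configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return ModelConfig.model_validate(data)


def default_config_path() -> Path:
    return Path(str(importlib.resources.files("fatrans") / "data" / "default.yaml"))


def default_config(**experiment_overrides) -> ModelConfig:
    """The packaged default parameter set, optionally with experiment overrides."""
    cfg = load_config(default_config_path())
    if experiment_overrides:
        data = cfg.model_dump()
        data["experiment"].update(experiment_overrides)
        if "target_extraction" in experiment_overrides:
            data["experiment"]["R_met"] = None
        if "R_met" in experiment_overrides:
            data["experiment"]["target_extraction"] = None
        cfg = ModelConfig.model_validate(data)
    return cfg
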