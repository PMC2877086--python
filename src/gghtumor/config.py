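"""Simulation configuration.

:class:`SimulationConfig` carries every model parameter of the tumor-growth
simulation in lattice units (lengths in voxels, time in Monte Carlo Steps,
energies in units of the contact-energy scale).  The default profile is the
full-scale study conditions: a 100^3 voxel domain (voxel = 60 um, so 6 mm per side),
tumor-TM contact energy 8, cell motility 60, doubling volume 54 voxels,
inverse compressibility 20 and inverse membrane elasticity 0.4, with 400 MCS
corresponding to one day.

The diffusion-limitation parameter G and the per-cell substrate consumption
rate k are two parameterizations of the same knob, related by
``G = k L^2 / D_c`` (times an adjustable mapping constant); exactly one of
them may be specified and the other is derived.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from typing import Optional

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    # --- lattice & time ---
    lattice_size: int = 100          # voxels per side
    voxel_size: float = 60.0         # um
    mcs_per_day: int = 400

    # --- contact energies & Metropolis dynamics ---
    J_tumor_tumor: float = 4.0       # varied 4..16 <-> surface tension 6..0
    J_tumor_tm: float = 8.0
    T_m: float = 60.0                # cell motility (Metropolis temperature)
    lambda_V: float = 20.0           # inverse compressibility
    lambda_S: float = 0.4            # inverse membrane elasticity
    neighbor_order: int = 4          # 32 neighbors per voxel

    # --- tumor biology ---
    V_doubling: float = 54.0         # voxels; divide when volume doubles
    shape_constant: float = 6.0      # S_t = shape_constant * V_t^(2/3)
    g: float = 0.25                  # target-volume growth, voxels/MCS per unit c
    division_trigger: str = "actual"  # "actual" volume or "target" volume
    quiescence_enabled: bool = False
    necrosis_enabled: bool = False
    c_threshold: float = 0.05
    g_necrotic: float = -0.125

    # --- fields ---
    D_c: float = 0.5                 # substrate diffusion, voxel^2/MCS
    D_m: float = 0.01                # MDE diffusion, voxel^2/MCS
    delta: float = 0.5               # TM degradation rate per unit MDE, 1/MCS
    mu: float = 1.0                  # MDE production per cell, conc/MCS
    S_prod: float = 0.1              # substrate production per unit TM, conc/MCS
    k: Optional[float] = None        # substrate consumption per cell, conc/MCS
    G: Optional[float] = None        # diffusion-limitation parameter
    G_mapping_constant: float = 0.05  # G = const * k * L^2 / D_c

    # --- bookkeeping ---
    seed: int = 0
    snapshot_interval: int = 400
    max_mcs: int = 40000
    surface_estimator: str = "mesh"  # "mesh", "mesh_aa" or "face"

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.lattice_size < 8:
            raise ConfigError("lattice_size must be at least 8")
        if self.J_tumor_tumor <= 0 or self.J_tumor_tm <= 0:
            raise ConfigError("all contact energies must be positive")
        if self.T_m <= 0:
            raise ConfigError("T_m must be positive")
        if not 0.0 <= self.c_threshold <= 1.0:
            raise ConfigError("c_threshold must lie in [0, 1]")
        if (self.k is None) == (self.G is None):
            raise ConfigError("exactly one of k and G must be given")
        if self.quiescence_enabled and self.necrosis_enabled:
            raise ConfigError(
                "quiescence and necrosis are alternative rules; enable only one")
        if self.division_trigger not in ("actual", "target"):
            raise ConfigError("division_trigger must be 'actual' or 'target'")
        if self.neighbor_order not in (1, 2, 3, 4):
            raise ConfigError("neighbor_order must be 1..4")
        if self.surface_estimator not in ("mesh", "mesh_aa", "face"):
            raise ConfigError(
                "surface_estimator must be 'mesh', 'mesh_aa' or 'face'")

    # ------------------------------------------------------------------
    @property
    def gamma(self) -> float:
        """Tumor-TM surface tension: gamma = J(t,TM) - J(t,t)/2."""
        return self.J_tumor_tm - self.J_tumor_tumor / 2.0

    @property
    def k_value(self) -> float:
        from .tumor_biology import k_from_G
        if self.k is not None:
            return self.k
        return k_from_G(self.G, self.lattice_size, self.D_c,
                        self.G_mapping_constant)

    @property
    def G_value(self) -> float:
        from .tumor_biology import G_from_k
        if self.G is not None:
            return self.G
        return G_from_k(self.k, self.lattice_size, self.D_c,
                        self.G_mapping_constant)

    # ------------------------------------------------------------------
    @classmethod
    def full_profile(cls, **overrides) -> "SimulationConfig":
        """Full-scale study conditions: L=100; G = 50..200 corresponds to
        per-cell consumption rates k = 0.05..0.2."""
        kw = dict(lattice_size=100, G=50.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def reduced_profile(cls, **overrides) -> "SimulationConfig":
        """Desk-scale profile: L=50 with D_c scaled so the G grid and the
        per-cell consumption rates k in [0.05, 0.2] are both unchanged."""
        kw = dict(lattice_size=50, D_c=0.125, G=50.0, snapshot_interval=100)
        kw.update(overrides)
        return cls(**kw)

    def with_gamma(self, gamma: float) -> "SimulationConfig":
        """Copy with J(t,t) chosen so the tumor-TM surface tension is gamma."""
        J_tt = 2.0 * (self.J_tumor_tm - gamma)
        if J_tt <= 0:
            raise ConfigError(f"gamma={gamma} would need non-positive J(t,t)")
        return dataclasses.replace(self, J_tumor_tumor=J_tt)

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    def digest(self) -> str:
        """Stable hash of the full parameter set, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @property
    def n_sites(self) -> int:
        return self.lattice_size ** 3

    def mcs_to_days(self, mcs: float) -> float:
        return mcs / self.mcs_per_day
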