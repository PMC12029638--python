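"""Physical <-> lattice unit conversion, parameter tables and run configuration.

The solver works internally in lattice units with dx = dt = 1 and a lattice
density of 1 (so the physical density maps to 1).  A :class:`UnitSystem`
carries the physical scales and provides the conversion rules; configuration
files carry physical SI values only, and every lattice quantity is derived
from them through a single :class:`UnitSystem` instance.

Lattice sound speed is cs^2 = 1/3, so the BGK relaxation time follows the
standard relation nu_lat = (tau - 1/2)/3.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml


class ConfigError(ValueError):
    """Raised for invalid or inconsistent run configuration."""


#: speed of sound squared on the D3Q19 lattice (lattice units)
CS2 = 1.0 / 3.0


@dataclass(frozen=True)
class UnitSystem:
    """Physical scales of one lattice cell and one time step.

    Parameters
    ----------
    dx : float
        Lattice spacing in metres.
    dt : float
        Time step in seconds.
    rho_phys : float
        Fluid density in kg/m^3 (maps to lattice density 1).
    mu_phys : float
        Dynamic viscosity in Pa s.
    """

    dx: float = 1.0e-6
    dt: float = 1.8e-8
    rho_phys: float = 1050.0
    mu_phys: float = 1.2e-3

    def __post_init__(self) -> None:
        for name in ("dx", "dt", "rho_phys", "mu_phys"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"UnitSystem.{name} must be positive")
        if self.tau <= 0.5:
            raise ConfigError(
                f"unit system yields tau = {self.tau:.4f} <= 0.5 (unstable); "
                "decrease dt or increase viscosity"
            )

    # ---- derived scales -------------------------------------------------
    @property
    def nu_phys(self) -> float:
        """Kinematic viscosity in m^2/s."""
        return self.mu_phys / self.rho_phys

    @property
    def nu_lat(self) -> float:
        """Dimensionless lattice kinematic viscosity."""
        return self.nu_phys * self.dt / self.dx**2

    @property
    def tau(self) -> float:
        return 3.0 * self.nu_lat + 0.5

    @property
    def omega(self) -> float:
        """Relaxation frequency 1/tau."""
        return 1.0 / self.tau

    @property
    def mass_unit(self) -> float:
        """Mass of one lattice cell of fluid, kg (makes rho_lat = 1)."""
        return self.rho_phys * self.dx**3

    # ---- conversions ----------------------------------------------------
    def to_physical_velocity(self, u_lat: float) -> float:
        """Lattice velocity -> m/s."""
        return u_lat * self.dx / self.dt

    def to_lattice_velocity(self, u_phys: float) -> float:
        """Velocity in m/s -> lattice units."""
        return u_phys * self.dt / self.dx

    def to_lattice_time(self, t_phys: float) -> float:
        return t_phys / self.dt

    def to_physical_time(self, n_steps: float) -> float:
        return n_steps * self.dt

    def to_lattice_length(self, x_phys: float) -> float:
        return x_phys / self.dx

    def to_lattice_acceleration(self, a_phys: float) -> float:
        return a_phys * self.dt**2 / self.dx

    def to_lattice_shear_modulus(self, ks_phys: float) -> float:
        """Membrane modulus in N/m (kg/s^2) -> lattice units."""
        return ks_phys * self.dt**2 / self.mass_unit

    def to_lattice_bending_modulus(self, kb_phys: float) -> float:
        """Bending modulus in N m (kg m^2/s^2) -> lattice units."""
        return kb_phys * self.dt**2 / (self.mass_unit * self.dx**2)

    def to_lattice_volume_modulus(self, kv_phys: float) -> float:
        """Volume modulus in N/m^2 (kg/(m s^2)) -> lattice units."""
        return kv_phys * self.dt**2 * self.dx / self.mass_unit


def lattice_viscosity(us: UnitSystem) -> float:
    """Dimensionless lattice kinematic viscosity of a unit system."""
    return us.nu_lat


def relaxation_from_viscosity(nu_lat: float) -> tuple[float, float]:
    """BGK relaxation time and frequency for a lattice viscosity.

    Inverts nu = (tau - 1/2) cs^2 with cs^2 = 1/3; returns ``(tau, omega)``
    with omega = 1/tau in (0, 2).
    """
    if nu_lat <= 0:
        raise ConfigError(f"lattice viscosity must be positive, got {nu_lat}")
    tau = 3.0 * nu_lat + 0.5
    return tau, 1.0 / tau


def viscosity_from_relaxation(tau: float) -> float:
    """Lattice kinematic viscosity (tau - 1/2) cs^2 of a relaxation time."""
    if tau <= 0.5:
        raise ConfigError(f"tau must exceed 0.5, got {tau}")
    return (tau - 0.5) * CS2


def to_physical_velocity(u_lat: float, us: UnitSystem) -> float:
    """Lattice velocity -> m/s (function form of the method)."""
    return us.to_physical_velocity(u_lat)


def poiseuille_acceleration(Re: float, nu: float, D: float) -> float:
    """Body acceleration driving pipe Poiseuille flow at a target Reynolds number.

    a = 32 nu^2 Re / D^3, valid in any consistent unit system (physical SI or
    lattice units).  Follows from Um = a D^2 / (32 nu) and Re = Um D / nu.
    """
    if nu <= 0 or D <= 0 or Re < 0:
        raise ConfigError("poiseuille_acceleration needs nu > 0, D > 0, Re >= 0")
    return 32.0 * nu**2 * Re / D**3


def mean_velocity_from_acceleration(ax: float, D: float, nu: float) -> float:
    """Mean Poiseuille velocity Um = a D^2 / (32 nu) (consistent units)."""
    return ax * D**2 / (32.0 * nu)


def reynolds_number(Um: float, D: float, nu: float) -> float:
    """Re = Um D / nu (consistent units)."""
    return Um * D / nu


@dataclass(frozen=True)
class FlowParams:
    """Channel flow parameters in lattice units.

    ``Um`` and ``Re`` are derived from the body acceleration ``ax`` via
    Um = ax D^2/(32 nu) (the pressure-drop equivalence dp = rho ax L) and
    Re = Um D / nu.
    """

    L: float
    D: float
    ax: float
    nu: float

    @property
    def Um(self) -> float:
        return mean_velocity_from_acceleration(self.ax, self.D, self.nu)

    @property
    def Re(self) -> float:
        return reynolds_number(self.Um, self.D, self.nu)

    @classmethod
    def from_reynolds(cls, L: float, D: float, Re: float, nu: float) -> "FlowParams":
        return cls(L=L, D=D, ax=poiseuille_acceleration(Re, nu, D), nu=nu)


# ---------------------------------------------------------------------------
# Particle parameter tables (physical SI values; the authoritative column)
# ---------------------------------------------------------------------------

#: Red blood cell membrane parameters.
RBC_PARAMS = {
    "radius": 3.5e-6,       # m
    "ks": 5.0e-6,           # elastic shear modulus, N/m
    "kalpha": 2.5e-6,       # area dilation modulus, N/m
    "kB": 2.0e-19,          # bending modulus, N m
    "kA": 0.5,              # total-surface modulus, N/m
    "kV": 1.0e6,            # volume modulus, N/m^2
}

#: Micrometric drug-carrier parameters (radius spans 1.3-2.0 um).
DC_PARAMS = {
    "radius": 1.5e-6,       # m (within the 1.3-2.0 um design range)
    "ks": 1.0,              # N/m
    "kalpha": 0.1,          # N/m
    "kB": 1.0e-13,          # N m
    "kA": 1.0,              # N/m
    "kV": 1.0e6,            # N/m^2
}

#: Drug-carrier stiffness sweep, soft (case 1) to rigid (case 5).
DC_STIFFNESS_CASES = {
    1: {"ks": 1.0e-5, "kalpha": 1.0e-6, "kB": 1.0e-18, "kA": 1.0e-5, "kV": 1.0e1},
    2: {"ks": 1.0e-3, "kalpha": 1.0e-4, "kB": 1.0e-16, "kA": 1.0e-3, "kV": 1.0e3},
    3: {"ks": 1.0, "kalpha": 1.0e-1, "kB": 1.0e-13, "kA": 1.0, "kV": 1.0e6},
    4: {"ks": 1.0e1, "kalpha": 1.0, "kB": 1.0e-12, "kA": 1.0e1, "kV": 1.0e7},
    5: {"ks": 1.0e2, "kalpha": 1.0e1, "kB": 1.0e-11, "kA": 1.0e2, "kV": 1.0e8},
}


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "fluid": {
        "dx": 1.0e-6,
        "dt": 1.8e-8,
        "rho": 1050.0,
        "mu": 1.2e-3,
    },
    "geometry": {
        "type": "straight",     # straight | curved
        "L": 60,                # lattice units
        "D": 28,
        "amplitude": 0.0,       # curved-centerline amplitude, lattice units
        "ny": 30,
        "nz": 30,
    },
    "particles": {
        "n_rbc": 2,
        "n_dc": 2,
        "rbc_radius": 5.0,      # lattice units (scaled-down default)
        "dc_radius": 2.0,
        "rbc_faces": 480,
        "dc_faces": 120,
    },
    "run": {
        "Re": 1.465,
        "steps": 120000,
        "record_every": 200,
        "bending_model": "tan_half",   # tan_half | quadratic
        "membrane_substeps": 1,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Load a run configuration, merged over the defaults.

    The ``seed`` key is required (all stochastic placement derives from it);
    it may come from the file, from ``overrides``, or from the CLI.
    """
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path!r} is not a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def validate_config(cfg: dict) -> dict:
    if "seed" not in cfg:
        raise ConfigError("config requires an explicit integer 'seed'")
    fluid = cfg["fluid"]
    UnitSystem(dx=fluid["dx"], dt=fluid["dt"],
               rho_phys=fluid["rho"], mu_phys=fluid["mu"])
    geo = cfg["geometry"]
    if geo["type"] not in ("straight", "curved"):
        raise ConfigError(f"unknown geometry type {geo['type']!r}")
    if geo["D"] > min(geo["ny"], geo["nz"]) - 1:
        raise ConfigError("vessel diameter does not fit the grid cross-section")
    return cfg


def unit_system_from_config(cfg: dict) -> UnitSystem:
    fluid = cfg["fluid"]
    return UnitSystem(dx=fluid["dx"], dt=fluid["dt"],
                      rho_phys=fluid["rho"], mu_phys=fluid["mu"])
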