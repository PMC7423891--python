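"""Model parameters for the coarse-grained wedge tubulin model.

All quantities are expressed in reduced Lennard-Jones units: ``sigma`` (bead
diameter) is the unit of length, ``epsilon`` the unit of energy, ``m`` the bead
mass, and ``tau = sigma*sqrt(m/epsilon)`` the unit of time.  The mapping to
physical units uses two calibrations: ``nm_per_row`` (axial length of one dimer
row) and ``tau_per_second`` (obtained by matching the simulated depolymerization
rate of a fully compressed microtubule to the experimental 0.240 um/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


@dataclass
class ModelParameters:
    """Physical and numerical parameters of the wedge model.

    Attributes
    ----------
    epsilon, sigma, mass : float
        Reduced LJ units (energy, length, bead mass).
    temperature : float
        Thermostat temperature in units of ``epsilon/k_b``.
    boltzmann : float
        Boltzmann constant (kept at 1 in reduced units).
    timestep : float
        Integration time step in tau.
    damping : float
        Langevin friction in 1/tau (applied to both translational and
        rotational degrees of freedom).
    A_lateral, A_vertical, A_intra : float
        Strengths (in k_b*T) of the attractive binding-site wells: lateral
        protofilament-protofilament contacts, vertical inter-dimer contacts,
        and the intra-dimer alpha-beta bond.
    site_cutoff : float
        Range ``r_c`` of the cosine attraction well, in sigma.
    spring_K : float
        Harmonic constant (k_b*T/sigma^2) used by the stiff-spring
        compatibility mode; the default integrator treats subunits as rigid.
    theta : float
        Compression angle of the hydrolyzed alpha-subunit, degrees.
    n_protofilaments : int
        Number of protofilaments closing the lattice ring.
    tau_per_second : float
        Time-unit conversion (simulated tau per experimental second).
    nm_per_row : float
        Axial length of one dimer row in nanometres.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    mass: float = 1.0
    temperature: float = 1.0
    boltzmann: float = 1.0
    timestep: float = 0.005
    damping: float = 1.0
    A_lateral: float = 1.4
    A_vertical: float = 4.8
    A_intra: float = 8.0
    site_cutoff: float = 0.75
    spring_K: float = 500.0
    theta: float = 15.0
    n_protofilaments: int = 13
    tau_per_second: float = 3.0e6
    nm_per_row: float = 9.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("epsilon", "sigma", "mass", "temperature", "boltzmann",
                     "damping", "A_lateral", "A_vertical", "A_intra",
                     "spring_K", "tau_per_second", "nm_per_row"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.theta < 90.0):
            raise ValueError("theta must lie in [0, 90) degrees")
        if not (0.0 < self.site_cutoff < 2.0 ** (1.0 / 6.0)):
            raise ValueError("site_cutoff must be positive and below 2^(1/6)")
        if self.n_protofilaments < 3:
            raise ValueError("n_protofilaments must be at least 3")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")

    @property
    def kT(self) -> float:
        return self.boltzmann * self.temperature

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta)

    def replace(self, **kwargs) -> "ModelParameters":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(kwargs)
        return ModelParameters(**values)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})
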