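"""Physical and numerical constants of the spine model.

Units throughout the package: lengths um, forces pN, energies pN*um, time s.
"""
from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the spine membrane model.

    Defaults are the reference parameter set for a mushroom-type spine:
    Laplace-scale pressure and tension of the spine head, Helfrich bending
    modulus of a lipid bilayer, and the geometry (sphere radius, neck ring,
    PSD disc) matched to measured spine/PSD dimensions.
    """

    P: float = 75.0            # pressure difference, pN um^-2
    sigma: float = 15.0        # surface tension, pN um^-1
    kappa: float = 0.18        # bending modulus, pN um
    alpha: float = 3.8         # strength of F-actin influence, pN
    zeta: float = 0.004        # strength of force update, um^2 s^-1 pN^-1
    n_fil: int = 70            # F-actin filaments in the spine head
    delta_s: float = 0.03      # remeshing target edge length, um
    dt: float = 0.125          # time step, s
    r_s: float = 0.4           # initial sphere radius, um
    r_neck: float = 0.0796     # neck radius, um
    r_psd0: float = 0.1744     # initial PSD radius, um
    h_neck: float = -0.3920    # neck fixing height, um
    h_psd: float = 0.36        # PSD fixing height, um
    delta_psd: float = 0.03 / 60.0   # PSD radius growth rate, um s^-1

    # numerical knobs (do not change the model, only its integration)
    n_substeps: int = 6        # internal RK4 substeps per reported dt
    remesh_iterations: int = 3
    d_min_frac: float = 0.5    # actin 1/d clamp at d_min = d_min_frac*delta_s
    psd_capture_tol: float = 0.001  # |z - h_psd| capture tolerance, um

    def __post_init__(self):
        for name in ("P", "sigma", "kappa", "alpha", "zeta", "delta_s", "dt",
                     "r_s", "r_neck", "r_psd0", "h_psd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.h_neck >= 0:
            raise ValueError("h_neck must be negative (neck is at the bottom)")
        if self.n_fil <= 0 or self.n_substeps <= 0:
            raise ValueError("counts must be positive")
        if self.delta_psd < 0:
            raise ValueError("delta_psd must be non-negative")

    @property
    def d_min(self) -> float:
        return self.d_min_frac * self.delta_s

    def with_(self, **kwargs) -> "ModelParams":
        """Copy with overrides (frozen dataclass convenience)."""
        return replace(self, **kwargs)
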