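"""Desk-scale underdamped Langevin dynamics on analytic toy potentials.

The solvated-protein dynamics the metadynamics machinery was built for are
out of desk scale; the engine here propagates one or a few collective-variable
-like coordinates on analytic potentials (symmetric/asymmetric double wells,
harmonic wells) with a BAOAB splitting, which is what the enhanced-sampling
layers are exercised and validated on.

Unit conventions: energies kcal/mol, temperatures K, lengths in the CV's
native unit; mass and friction define the (arbitrary) toy time unit.  The
Boltzmann constant is kcal/(mol K), so k_B*T ~ 0.6 kcal/mol at 300 K.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import KB_KCAL_MOL_K
from .errors import IntegrationError, ValidationError

__all__ = ["PotentialSpec", "ToySystem", "double_well", "harmonic",
           "langevin_trajectory"]


@dataclass(frozen=True)
class PotentialSpec:
    """One-dimensional analytic potential: ``double_well`` with
    U(s) = a*(s^2 - s0^2)^2 + tilt*s, or ``harmonic`` with
    U(s) = 0.5*kappa*(s - center)^2."""

    kind: str
    params: tuple[tuple[str, float], ...]

    def as_dict(self) -> dict[str, float]:
        return dict(self.params)

    def functions(self) -> tuple[Callable[[float], float], Callable[[float], float]]:
        """(U, dU/ds) as plain-float callables (fast in tight loops)."""
        p = self.as_dict()
        if self.kind == "double_well":
            a, s0, tilt = p["a"], p["s0"], p.get("tilt", 0.0)
            s0sq = s0 * s0

            def u(s: float) -> float:
                d = s * s - s0sq
                return a * d * d + tilt * s

            def du(s: float) -> float:
                return 4.0 * a * s * (s * s - s0sq) + tilt

            return u, du
        if self.kind == "harmonic":
            kappa, center = p["kappa"], p.get("center", 0.0)

            def u(s: float) -> float:
                d = s - center
                return 0.5 * kappa * d * d

            def du(s: float) -> float:
                return kappa * (s - center)

            return u, du
        raise ValidationError(f"unknown potential kind {self.kind!r}")

    def curvature_scale(self) -> float:
        """Representative |U''| used for the timestep-stability heuristic."""
        p = self.as_dict()
        if self.kind == "double_well":
            return 8.0 * p["a"] * p["s0"] ** 2
        if self.kind == "harmonic":
            return p["kappa"]
        raise ValidationError(f"unknown potential kind {self.kind!r}")


def double_well(a: float = 5.0, s0: float = 1.0, tilt: float = 0.0) -> PotentialSpec:
    """Symmetric double well with barrier height ``a*s0**4`` (kcal/mol) at
    s=0 and minima at ±s0; a linear ``tilt`` makes it asymmetric."""
    if a <= 0:
        raise ValidationError("double-well stiffness a must be positive")
    return PotentialSpec("double_well", (("a", a), ("s0", s0), ("tilt", tilt)))


def harmonic(kappa: float = 10.0, center: float = 0.0) -> PotentialSpec:
    if kappa <= 0:
        raise ValidationError("harmonic kappa must be positive")
    return PotentialSpec("harmonic", (("kappa", kappa), ("center", center)))


@dataclass
class ToySystem:
    """Separable toy system: one :class:`PotentialSpec` per coordinate.

    ``friction`` is in inverse toy-time units, ``timestep`` in toy-time
    units, ``mass`` is shared across coordinates.
    """

    potentials: list[PotentialSpec] = field(default_factory=lambda: [double_well()])
    temperature: float = 300.0
    friction: float = 1.0
    timestep: float = 0.005
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            if self.temperature < 0:
                raise ValidationError("temperature must be >= 0")
        if self.friction <= 0:
            raise ValidationError("friction must be positive")
        if self.timestep <= 0 or self.mass <= 0:
            raise ValidationError("timestep and mass must be positive")
        for spec in self.potentials:
            omega_dt = math.sqrt(spec.curvature_scale() / self.mass) * self.timestep
            if omega_dt > 1.0:
                raise ValidationError(
                    f"unstable timestep: omega*dt = {omega_dt:.2f} > 1"
                )
            if omega_dt > 0.3:
                warnings.warn(
                    f"marginal timestep: omega*dt = {omega_dt:.2f}", stacklevel=2
                )

    @property
    def ndim(self) -> int:
        return len(self.potentials)

    @property
    def kbt(self) -> float:
        return KB_KCAL_MOL_K * self.temperature

    def minima(self) -> list[float]:
        """A reference minimum per coordinate (start point default)."""
        out = []
        for spec in self.potentials:
            p = spec.as_dict()
            out.append(-p["s0"] if spec.kind == "double_well" else p.get("center", 0.0))
        return out


def langevin_trajectory(
    system: ToySystem,
    n_steps: int,
    seed: int,
    bias: Callable[[float], tuple[float, float]] | None = None,
    s_init: Sequence[float] | float | None = None,
    sample_stride: int = 1,
    bound: float = 1e3,
) -> np.ndarray:
    """Integrate underdamped Langevin dynamics (BAOAB splitting).

    ``bias``, if given, is a callable ``s -> (V, dV/ds)`` applied to the
    first coordinate (the 1-D engine path used by the enhanced-sampling
    tests).  Returns sampled coordinates, shape (n_samples, ndim).

    The long-run histogram of an unbiased run converges to
    exp(-U/k_B T); at T=0 a system started in a minimum stays there.
    """
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    dt, m, gamma = system.timestep, system.mass, system.friction
    kbt = system.kbt
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kbt / m * (1.0 - c1 * c1))
    funcs = [spec.functions() for spec in system.potentials]
    if s_init is None:
        s = list(map(float, system.minima()))
    elif np.isscalar(s_init):
        s = [float(s_init)] * system.ndim
    else:
        s = [float(v) for v in s_init]
    v = [0.0] * system.ndim
    nd = system.ndim
    n_samples = n_steps // sample_stride
    out = np.empty((n_samples, nd))
    noise = rng.standard_normal((n_steps, nd))
    k = 0
    for step in range(n_steps):
        for d in range(nd):
            _, du = funcs[d]
            f = -du(s[d])
            if bias is not None and d == 0:
                f -= bias(s[d])[1]
            v[d] += 0.5 * dt * f / m
            s[d] += 0.5 * dt * v[d]
            v[d] = c1 * v[d] + c2 * noise[step, d]
            s[d] += 0.5 * dt * v[d]
            f = -du(s[d])
            if bias is not None and d == 0:
                f -= bias(s[d])[1]
            v[d] += 0.5 * dt * f / m
            if not (-bound < s[d] < bound):
                raise IntegrationError(
                    f"coordinate {d} diverged (|s| >= {bound}) at step {step}"
                )
        if (step + 1) % sample_stride == 0:
            out[k] = s
            k += 1
    return out[:k]
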