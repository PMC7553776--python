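"""Two-receptor / one-ligand competition equilibrium.

A single ligand (the stress-sensor lipoprotein RcsF) partitions between two
receptors that cannot bind it simultaneously: the abundant, low-affinity
periplasmic domain of OmpA and the scarce, high-affinity periplasmic domain
of IgaA.  At equilibrium the free-ligand concentration R satisfies

    f(R) = R + A_tot * R / (Kd_A + R) + I_tot * R / (Kd_I + R) - R_tot = 0

which is strictly increasing in R on [0, R_tot], so the physical root is
unique.  Because OmpA vastly outnumbers the ligand, the OmpA-bound pool
grows linearly with free ligand while the IgaA-bound pool saturates along a
hyperbola -- OmpA acts as a buffer that blunts the loading of IgaA.

All concentrations in this module are micromolar (µM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "BindingSystem",
    "SpeciesState",
    "BufferCurve",
    "solve_competition",
    "linearized_complexes",
    "kd_ratio",
    "buffer_curve",
]


def _require_finite_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return value


def _require_finite_pos(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")
    return value


@dataclass(frozen=True)
class BindingSystem:
    """Total concentrations and dissociation constants, all in µM.

    Attributes
    ----------
    r_total : total ligand (RcsF).
    a_total : total buffering receptor (OmpA C-terminal domain).
    i_total : total high-affinity receptor (IgaA periplasmic domain).
    kd_a    : receptor-A / ligand dissociation constant (OmpA-RcsF).
    kd_i    : receptor-I / ligand dissociation constant (IgaA-RcsF).
    """

    r_total: float
    a_total: float
    i_total: float
    kd_a: float
    kd_i: float

    def __post_init__(self) -> None:
        _require_finite_nonneg("r_total", self.r_total)
        _require_finite_nonneg("a_total", self.a_total)
        _require_finite_nonneg("i_total", self.i_total)
        _require_finite_pos("kd_a", self.kd_a)
        _require_finite_pos("kd_i", self.kd_i)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations of all five species, µM."""

    free_r: float
    free_a: float
    free_i: float
    complex_ar: float
    complex_ir: float


@dataclass(frozen=True)
class BufferCurve:
    """Complex concentrations along a grid of ligand concentrations.

    ``axis`` records whether the grid is free or total ligand; ``mode``
    whether complexes come from the exact solver or the constant-OmpA
    linearization.
    """

    r_grid: np.ndarray
    complex_ar: np.ndarray
    complex_ir: np.ndarray
    mode: Literal["exact", "linearized"]
    axis: Literal["free", "total"]


def _mass_balance(free_r: float, system: BindingSystem) -> float:
    return (
        free_r
        + system.a_total * free_r / (system.kd_a + free_r)
        + system.i_total * free_r / (system.kd_i + free_r)
        - system.r_total
    )


def _mass_balance_deriv(free_r: float, system: BindingSystem) -> float:
    return (
        1.0
        + system.a_total * system.kd_a / (system.kd_a + free_r) ** 2
        + system.i_total * system.kd_i / (system.kd_i + free_r) ** 2
    )


def solve_competition(system: BindingSystem) -> SpeciesState:
    """Solve the competition equilibrium exactly.

    Bracketed bisection on [0, r_total] (f is strictly increasing there)
    followed by Newton polishing to 1e-12 relative on the free-ligand
    concentration.  Returns the unique physical :class:`SpeciesState`.
    """
    if system.r_total == 0.0:
        return SpeciesState(0.0, system.a_total, system.i_total, 0.0, 0.0)

    lo, hi = 0.0, system.r_total
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _mass_balance(mid, system) < 0.0:
            lo = mid
        else:
            hi = mid
    r = 0.5 * (lo + hi)
    # Newton polish; f' >= 1 everywhere so the iteration is well conditioned
    for _ in range(8):
        step = _mass_balance(r, system) / _mass_balance_deriv(r, system)
        r_new = min(max(r - step, 0.0), system.r_total)
        if abs(r_new - r) <= 1e-12 * max(r_new, 1e-300):
            r = r_new
            break
        r = r_new

    # free receptor via Kd/(Kd+R) rather than subtraction: near saturation the
    # difference total - complex cancels catastrophically
    return SpeciesState(
        free_r=r,
        free_a=system.a_total * system.kd_a / (system.kd_a + r),
        free_i=system.i_total * system.kd_i / (system.kd_i + r),
        complex_ar=system.a_total * r / (system.kd_a + r),
        complex_ir=system.i_total * r / (system.kd_i + r),
    )


def linearized_complexes(free_r: float, system: BindingSystem) -> tuple[float, float]:
    """Complex concentrations under the constant-OmpA approximation.

    With the buffering receptor far in excess of the ligand its free
    concentration is effectively its total, so the A-bound pool is linear in
    free ligand, ``a_total * R / kd_a``, while the I-bound pool keeps its
    exact hyperbolic form ``i_total * R / (kd_i + R)`` for the conserved
    IgaA pool.
    """
    free_r = float(free_r)
    if not math.isfinite(free_r) or free_r < 0.0:
        raise ValueError(f"free_r must be finite and >= 0, got {free_r!r}")
    complex_ar = system.a_total * free_r / system.kd_a
    complex_ir = system.i_total * free_r / (system.kd_i + free_r)
    return complex_ar, complex_ir


def kd_ratio(kd_a: float, kd_i: float) -> float:
    """Fold difference in affinity, Kd_A / Kd_I (dimensionless).

    For the measured constants (125 µM vs 1.6 nM) this is ~8e4: the scarce
    receptor binds the ligand about eighty-thousand-fold more tightly.
    """
    _require_finite_pos("kd_a", kd_a)
    _require_finite_pos("kd_i", kd_i)
    return float(kd_a) / float(kd_i)


def buffer_curve(
    system: BindingSystem,
    grid: Sequence[float],
    mode: Literal["exact", "linearized"] = "exact",
    axis: Literal["free", "total"] = "free",
) -> BufferCurve:
    """Complex-formation curves along a ligand-concentration grid.

    ``axis='free'`` treats the grid as free-ligand concentrations and
    evaluates the complexes directly; ``axis='total'`` treats each grid
    point as a total-ligand concentration and obtains the free value with
    :func:`solve_competition` first.
    """
    if mode not in ("exact", "linearized"):
        raise ValueError(f"mode must be 'exact' or 'linearized', got {mode!r}")
    if axis not in ("free", "total"):
        raise ValueError(f"axis must be 'free' or 'total', got {axis!r}")
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size == 0:
        raise ValueError("grid must not be empty")
    if not np.all(np.isfinite(grid_arr)) or np.any(grid_arr < 0.0):
        raise ValueError("grid values must be finite and >= 0")
    if np.any(np.diff(grid_arr) < 0.0):
        raise ValueError("grid must be nondecreasing")

    ar = np.empty_like(grid_arr)
    ir = np.empty_like(grid_arr)
    for k, value in enumerate(grid_arr):
        if axis == "total":
            state = solve_competition(
                BindingSystem(value, system.a_total, system.i_total, system.kd_a, system.kd_i)
            )
            free_r = state.free_r
        else:
            free_r = value
        if mode == "exact":
            ar[k] = system.a_total * free_r / (system.kd_a + free_r)
            ir[k] = system.i_total * free_r / (system.kd_i + free_r)
        else:
            ar[k], ir[k] = linearized_complexes(free_r, system)
    return BufferCurve(r_grid=grid_arr, complex_ar=ar, complex_ir=ir, mode=mode, axis=axis)
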