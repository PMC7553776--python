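"""1:1 Langmuir kinetics for biolayer-interferometry sensorgrams.

A biosensor tip carrying immobilized ligand (RcsF) is dipped into analyte
(the IgaA periplasmic domain) at a series of concentrations; the optical
thickness response R(t) follows the single-site scheme

    dR/dt = kon * C * (Rmax - R) - koff * R

whose closed form is a saturating exponential during association,
R(t) = Req (1 - exp(-(kon C + koff) t)) with Req = Rmax C / (C + KD),
and a pure exponential decay during dissociation.  A global fit of kon and
koff across all concentrations of an injection series yields KD = koff/kon;
averaging KD over replicate series gives the reported 1.6 ± 0.3 nM for
IgaA–RcsF.

Concentrations are nanomolar at the interface and converted to molar inside
the rate terms; kon is per-molar per-second, koff per-second.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lmfit import Parameters, minimize as lmfit_minimize

__all__ = [
    "Sensorgram",
    "SensorgramSet",
    "KineticFit",
    "model_1to1",
    "fit_1to1_global",
    "average_kd",
]

_NM_TO_M = 1e-9


@dataclass
class Sensorgram:
    """One association+dissociation trace at a single analyte concentration."""

    analyte_conc_nM: float
    time_s: np.ndarray
    response_nm: np.ndarray
    t_assoc_end_s: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response_nm = np.asarray(self.response_nm, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.size < 2:
            raise ValueError("time grid must be a 1-D array with >= 2 points")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.response_nm.shape != self.time_s.shape:
            raise ValueError("response and time arrays must have the same shape")
        if not (self.time_s[0] <= self.t_assoc_end_s <= self.time_s[-1]):
            raise ValueError("t_assoc_end_s must lie within the time span")
        if self.analyte_conc_nM <= 0:
            raise ValueError("analyte_conc_nM must be > 0")


@dataclass
class SensorgramSet:
    """Replicate injection series: one trace per analyte concentration."""

    series_id: str
    sensorgrams: list[Sensorgram]
    blank_subtracted: bool = True

    def __post_init__(self) -> None:
        if not self.sensorgrams:
            raise ValueError("sensorgram set is empty")

    @property
    def concentrations_nM(self) -> list[float]:
        return [s.analyte_conc_nM for s in self.sensorgrams]


@dataclass(frozen=True)
class KineticFit:
    """Globally fitted 1:1 rate constants and derived affinity."""

    kon_M1s1: float
    koff_s1: float
    rmax_nm: float
    rms_nm: float
    residuals: tuple[np.ndarray, ...]

    @property
    def kd_nM(self) -> float:
        """KD = koff / kon, expressed in nM (held exactly by construction)."""
        return self.koff_s1 / self.kon_M1s1 * 1e9


def model_1to1(
    kon: float,
    koff: float,
    rmax: float,
    conc_nM: float,
    t_grid: np.ndarray | Sequence[float],
    t_assoc_end: float,
) -> np.ndarray:
    """Closed-form 1:1 response trace over ``t_grid`` (seconds).

    Association up to ``t_assoc_end``, then exponential dissociation
    continuous at the phase boundary.
    """
    if not (kon > 0 and koff > 0 and rmax > 0 and conc_nM > 0):
        raise ValueError("kon, koff, rmax and conc_nM must all be > 0")
    t = np.asarray(t_grid, dtype=float)
    c_M = conc_nM * _NM_TO_M
    kobs = kon * c_M + koff
    req = rmax * kon * c_M / kobs  # == rmax * C / (C + KD)
    r_end = req * -np.expm1(-kobs * t_assoc_end)
    assoc = req * -np.expm1(-kobs * np.minimum(t, t_assoc_end))
    dissoc = r_end * np.exp(-koff * np.maximum(t - t_assoc_end, 0.0))
    return np.where(t <= t_assoc_end, assoc, dissoc)


def _init_koff(sg: Sensorgram) -> float:
    """koff from a log-linear fit of the dissociation tail."""
    mask = sg.time_s > sg.t_assoc_end_s
    t, r = sg.time_s[mask], sg.response_nm[mask]
    keep = r > 1e-4 * max(np.max(np.abs(sg.response_nm)), 1e-12)
    if keep.sum() < 3:
        return 1e-3
    slope = np.polyfit(t[keep], np.log(r[keep]), 1)[0]
    return float(np.clip(-slope, 1e-7, 10.0))


def _init_kobs(sg: Sensorgram) -> float:
    """kobs from the time to reach 1 - 1/e of the association plateau."""
    mask = sg.time_s <= sg.t_assoc_end_s
    t, r = sg.time_s[mask], sg.response_nm[mask]
    req = float(np.mean(r[-max(3, t.size // 20) :]))
    if req <= 0:
        return 1e-3
    above = np.nonzero(r >= (1.0 - math.exp(-1.0)) * req)[0]
    if above.size == 0 or t[above[0]] <= 0:
        return 1e-3
    return 1.0 / float(t[above[0]])


def _initial_guess(sgset: SensorgramSet) -> tuple[float, float, float]:
    koff0 = float(np.median([_init_koff(s) for s in sgset.sensorgrams]))
    kobs = np.array([_init_kobs(s) for s in sgset.sensorgrams])
    conc_M = np.array(sgset.concentrations_nM) * _NM_TO_M
    if len(conc_M) >= 2 and np.ptp(conc_M) > 0:
        slope = np.polyfit(conc_M, kobs, 1)[0]
        kon0 = float(np.clip(slope, 1e3, 1e9))
    else:
        kon0 = float(np.clip((kobs[0] - koff0) / conc_M[0], 1e3, 1e9))
    kd_M = koff0 / kon0
    rmax_ests = []
    for s, c in zip(sgset.sensorgrams, conc_M):
        mask = s.time_s <= s.t_assoc_end_s
        req = float(np.mean(s.response_nm[mask][-max(3, mask.sum() // 20) :]))
        rmax_ests.append(req * (c + kd_M) / c)
    rmax0 = float(np.clip(np.median(rmax_ests), 1e-4, None))
    return kon0, koff0, rmax0


def fit_1to1_global(sgset: SensorgramSet, shared_rmax: bool = True) -> KineticFit:
    """Global nonlinear least-squares fit of one injection series.

    kon and koff are shared across all analyte concentrations; Rmax is
    shared by default (same sensor and ligand load within a series) with a
    per-curve option for sensors whose capacity drifts between cycles.
    Initial values come from the dissociation-tail slope and the kobs-vs-C
    regression, then both phases of every trace are refined jointly.
    """
    n_conc = len(set(sgset.concentrations_nM))
    if shared_rmax and n_conc < 2:
        warnings.warn(
            "shared-Rmax global fit needs >= 2 analyte concentrations; "
            "falling back to a per-curve fit",
            stacklevel=2,
        )
        shared_rmax = False

    kon0, koff0, rmax0 = _initial_guess(sgset)
    params = Parameters()
    params.add("log10_kon", value=math.log10(kon0), min=1.0, max=10.0)
    params.add("log10_koff", value=math.log10(koff0), min=-8.0, max=1.0)
    if shared_rmax:
        params.add("rmax", value=rmax0, min=1e-6)
    else:
        for j in range(len(sgset.sensorgrams)):
            params.add(f"rmax_{j}", value=rmax0, min=1e-6)

    def residual(p):
        kon = 10.0 ** p["log10_kon"].value
        koff = 10.0 ** p["log10_koff"].value
        out = []
        for j, sg in enumerate(sgset.sensorgrams):
            rmax = p["rmax"].value if shared_rmax else p[f"rmax_{j}"].value
            model = model_1to1(kon, koff, rmax, sg.analyte_conc_nM, sg.time_s, sg.t_assoc_end_s)
            out.append(sg.response_nm - model)
        return np.concatenate(out)

    result = lmfit_minimize(residual, params, method="leastsq", xtol=1e-15, ftol=1e-15)
    if not result.success:
        raise RuntimeError(f"global 1:1 fit did not converge: {result.message}")
    p = result.params
    kon = 10.0 ** p["log10_kon"].value
    koff = 10.0 ** p["log10_koff"].value
    if shared_rmax:
        rmax = float(p["rmax"].value)
    else:
        rmax = float(np.mean([p[f"rmax_{j}"].value for j in range(len(sgset.sensorgrams))]))

    per_curve = []
    for j, sg in enumerate(sgset.sensorgrams):
        rm = p["rmax"].value if shared_rmax else p[f"rmax_{j}"].value
        model = model_1to1(kon, koff, rm, sg.analyte_conc_nM, sg.time_s, sg.t_assoc_end_s)
        per_curve.append(sg.response_nm - model)
    rms = float(np.sqrt(np.mean(np.concatenate(per_curve) ** 2)))
    return KineticFit(
        kon_M1s1=float(kon),
        koff_s1=float(koff),
        rmax_nm=rmax,
        rms_nm=rms,
        residuals=tuple(per_curve),
    )


def average_kd(fits: Sequence[KineticFit]) -> tuple[float, float]:
    """Mean and sample SD (nM) of KD over replicate injection series."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to average KD")
    kds = np.array([f.kd_nM for f in fits])
    return float(kds.mean()), float(kds.std(ddof=1))
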