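"""Seeded generators for synthetic titrations, sensorgrams and blots.

Each generator emulates the statistical structure its downstream analysis
assumes, emits the exact in-memory containers (and, via :mod:`rcsbuffer.io`,
the exact CSV dialects) that the analysis consumes, and returns a
ground-truth sidecar so recovery errors are computable end to end.

Defaults mirror the source study's designs: an HSQC titration of a 50 µM
protein at ligand:protein ratios 0/2/10 with true Kd 125 µM; BLI injection
series at 5.9–30 nM analyte with 1000 s association and 1000 s dissociation
and true KD 1.6 nM; and a blot panel whose probe antibody is 25-fold more
sensitive than the reference antibody.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bli import Sensorgram, SensorgramSet, model_1to1
from .census import BlotPanel
from .csp import DEFAULT_WEIGHT_ALPHA, TitrationSeries, fraction_bound

__all__ = [
    "TitrationSimConfig",
    "BliSimConfig",
    "BlotSimConfig",
    "simulate_titration",
    "simulate_bli",
    "simulate_blot",
]

# one-letter codes minus proline, whose backbone amide is invisible in HSQC
_AMIDE_VISIBLE = "ACDEFGHIKLMNQRSTVWY"


@dataclass(frozen=True)
class TitrationSimConfig:
    """Design of a synthetic CSP titration.

    Binding residues move along fixed per-residue directions in the
    (ΔδH, α·ΔδN) plane with magnitude csp_max * fraction_bound; every
    residue additionally receives Gaussian shift noise at each point.
    csp_max for binding residues is drawn uniformly from ``cspmax_range_ppm``
    (defaults span the strongly perturbed interface residues; weak shifters
    are represented by the non-binding background).
    """

    true_kd_uM: float = 125.0
    p0_uM: float = 50.0
    ratios: tuple[float, ...] = (0.0, 2.0, 10.0)
    n_residues: int = 120
    n_binding_residues: int = 9
    cspmax_range_ppm: tuple[float, float] = (0.2, 0.5)
    noise_h_ppm: float = 0.004
    noise_n_ppm: float = 0.02
    weight_alpha: float = DEFAULT_WEIGHT_ALPHA
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.ratios:
            raise ValueError("ratios must include the reference point 0")
        if any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be >= 0")
        if not 0 <= self.n_binding_residues <= self.n_residues:
            raise ValueError("need 0 <= n_binding_residues <= n_residues")
        if self.noise_h_ppm < 0 or self.noise_n_ppm < 0:
            raise ValueError("noise levels must be >= 0")
        if not (self.true_kd_uM > 0 and self.p0_uM > 0):
            raise ValueError("true_kd_uM and p0_uM must be > 0")
        lo, hi = self.cspmax_range_ppm
        if not 0 < lo <= hi:
            raise ValueError("cspmax_range_ppm must satisfy 0 < lo <= hi")


def simulate_titration(cfg: TitrationSimConfig) -> tuple[TitrationSeries, dict]:
    """Generate a titration series plus its ground-truth sidecar."""
    rng = np.random.default_rng(cfg.seed)
    ids = np.arange(1, cfg.n_residues + 1)
    names = rng.choice(list(_AMIDE_VISIBLE), size=cfg.n_residues)
    base_h = rng.uniform(7.0, 9.5, size=cfg.n_residues)
    base_n = rng.uniform(103.0, 130.0, size=cfg.n_residues)

    binding = np.sort(rng.choice(ids, size=cfg.n_binding_residues, replace=False))
    csp_max = rng.uniform(*cfg.cspmax_range_ppm, size=cfg.n_binding_residues)
    theta = rng.uniform(0.0, 2.0 * math.pi, size=cfg.n_binding_residues)
    # unit direction in the weighted plane: |(dH, alpha*dN)| == 1
    dir_h = np.cos(theta)
    dir_n = np.sin(theta) / cfg.weight_alpha

    is_binding = np.isin(ids, binding)
    amp = np.zeros(cfg.n_residues)
    amp[is_binding] = csp_max
    dh = np.zeros(cfg.n_residues)
    dn = np.zeros(cfg.n_residues)
    dh[is_binding] = dir_h
    dn[is_binding] = dir_n

    points: dict[float, pd.DataFrame] = {}
    for r in sorted(cfg.ratios):
        fb = fraction_bound(r * cfg.p0_uM, cfg.p0_uM, cfg.true_kd_uM) if r > 0 else 0.0
        shift_h = base_h + amp * fb * dh + rng.normal(0.0, cfg.noise_h_ppm, cfg.n_residues)
        shift_n = base_n + amp * fb * dn + rng.normal(0.0, cfg.noise_n_ppm, cfg.n_residues)
        points[float(r)] = pd.DataFrame(
            {
                "residue_id": ids,
                "residue_name": names,
                "shift_h_ppm": shift_h,
                "shift_n_ppm": shift_n,
            }
        )
    series = TitrationSeries(protein_conc_uM=cfg.p0_uM, points=points)
    truth = {
        "true_kd_uM": cfg.true_kd_uM,
        "p0_uM": cfg.p0_uM,
        "binding_residues": [int(i) for i in binding],
        "csp_max_ppm": {int(i): float(a) for i, a in zip(binding, csp_max)},
        "seed": cfg.seed,
    }
    return series, truth


@dataclass(frozen=True)
class BliSimConfig:
    """Design of synthetic BLI injection series (1:1 kinetics plus noise)."""

    kon_M1s1: float = 1e6
    koff_s1: float = 1.6e-3
    rmax_nm: float = 1.0
    concentrations_nM: tuple[float, ...] = (5.9, 8.9, 13.3, 20.0, 30.0)
    t_assoc_s: float = 1000.0
    t_dissoc_s: float = 1000.0
    dt_s: float = 1.0
    noise_sd_nm: float = 0.005
    n_series: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.kon_M1s1 > 0 and self.koff_s1 > 0 and self.rmax_nm > 0):
            raise ValueError("rate constants and rmax must be > 0")
        if len(self.concentrations_nM) < 2:
            raise ValueError("need >= 2 analyte concentrations")
        if any(c <= 0 for c in self.concentrations_nM):
            raise ValueError("concentrations must be > 0")
        if not (self.t_assoc_s > 0 and self.t_dissoc_s > 0 and self.dt_s > 0):
            raise ValueError("phase lengths and dt must be > 0")
        if self.noise_sd_nm < 0 or self.n_series < 1:
            raise ValueError("noise_sd_nm >= 0 and n_series >= 1 required")

    @property
    def true_kd_nM(self) -> float:
        return self.koff_s1 / self.kon_M1s1 * 1e9


def simulate_bli(cfg: BliSimConfig) -> tuple[list[SensorgramSet], dict]:
    """Generate ``n_series`` replicate injection series plus ground truth."""
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.t_assoc_s + cfg.t_dissoc_s + cfg.dt_s / 2, cfg.dt_s)
    sets = []
    for s in range(cfg.n_series):
        traces = []
        for conc in cfg.concentrations_nM:
            clean = model_1to1(cfg.kon_M1s1, cfg.koff_s1, cfg.rmax_nm, conc, t, cfg.t_assoc_s)
            noisy = clean + rng.normal(0.0, cfg.noise_sd_nm, t.size)
            traces.append(
                Sensorgram(
                    analyte_conc_nM=conc,
                    time_s=t.copy(),
                    response_nm=noisy,
                    t_assoc_end_s=cfg.t_assoc_s,
                )
            )
        sets.append(SensorgramSet(series_id=f"series_{s + 1}", sensorgrams=traces))
    truth = {
        "kon_M1s1": cfg.kon_M1s1,
        "koff_s1": cfg.koff_s1,
        "true_kd_nM": cfg.true_kd_nM,
        "rmax_nm": cfg.rmax_nm,
        "seed": cfg.seed,
    }
    return sets, truth


@dataclass(frozen=True)
class BlotSimConfig:
    """Design of a synthetic calibration blot.

    Lane 1 carries the dual-detected tagged protein (both antibodies, role
    'calibration'); lane 2 the reference protein probed with the reference
    antibody; lane 3 the target probed with the probe antibody.  Every lane
    also gets a background band and a nonspecific loading band.  Band
    intensity = antibody sensitivity x concentration x lognormal noise,
    plus the lane background.
    """

    reference_conc_M: float = 1e-3
    target_conc_M: float = 40e-6
    calibration_conc_M: float = 1e-4
    sensitivity_factor: float = 25.0
    base_sensitivity_per_M: float = 1e6
    background_au: float = 5.0
    nonspecific_au: float = 50.0
    noise_cv: float = 0.10
    seed: int = 0
    probe_antibody: str = "anti-Flag"
    reference_antibody: str = "anti-OmpA"

    def __post_init__(self) -> None:
        positive = (
            self.reference_conc_M,
            self.target_conc_M,
            self.calibration_conc_M,
            self.sensitivity_factor,
            self.base_sensitivity_per_M,
            self.nonspecific_au,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("concentrations, factor and sensitivities must be > 0")
        if self.noise_cv < 0 or self.background_au < 0:
            raise ValueError("noise_cv and background_au must be >= 0")


def simulate_blot(cfg: BlotSimConfig) -> tuple[BlotPanel, dict]:
    """Generate a raw (uncorrected) blot panel plus ground truth."""
    rng = np.random.default_rng(cfg.seed)
    sigma = math.sqrt(math.log1p(cfg.noise_cv**2))  # lognormal with unit mean

    def noisy(mean: float) -> float:
        if cfg.noise_cv == 0:
            return mean
        return float(mean * rng.lognormal(-0.5 * sigma**2, sigma))

    s_ref = cfg.base_sensitivity_per_M
    s_probe = cfg.sensitivity_factor * s_ref
    rows = []
    specs = [
        (1, cfg.reference_antibody, s_ref * cfg.calibration_conc_M, "calibration"),
        (1, cfg.probe_antibody, s_probe * cfg.calibration_conc_M, "calibration"),
        (2, cfg.reference_antibody, s_ref * cfg.reference_conc_M, "reference"),
        (3, cfg.probe_antibody, s_probe * cfg.target_conc_M, "target"),
    ]
    for lane, antibody, mean, role in specs:
        rows.append((lane, antibody, noisy(mean) + cfg.background_au, role))
    for lane in (1, 2, 3):
        rows.append((lane, cfg.reference_antibody, noisy(cfg.nonspecific_au) + cfg.background_au, "nonspecific"))
        rows.append((lane, cfg.reference_antibody, cfg.background_au, "background"))
    panel = BlotPanel(
        table=pd.DataFrame(rows, columns=["lane", "antibody", "intensity", "role"]),
        background_corrected=False,
    )
    truth = {
        "reference_conc_M": cfg.reference_conc_M,
        "target_conc_M": cfg.target_conc_M,
        "sensitivity_factor": cfg.sensitivity_factor,
        "seed": cfg.seed,
    }
    return panel, truth
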