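"""Copy-number census and quantitative-immunoblot calibration.

Converts per-cell protein copy numbers into compartment concentrations
(copies / (N_A * V_cell * f_compartment)) and calibrates immunoblot band
intensities into concentrations via a dual-detected tagged protein that
fixes the relative sensitivity of two antibodies.

Defaults follow the E. coli envelope geometry used in the source study:
cell volume 1e-15 L (a 1 µm cube) with the periplasm taken as 30% of it.
With 200,000 OmpA copies per cell this puts the OmpA C-terminal domain at
~1 mM in the periplasm, RcsF (~3,000 copies) at ~17 µM and IgaA
(~200 copies) at ~1 µM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AVOGADRO",
    "CellCensus",
    "BlotPanel",
    "compartment_concentration",
    "round_to_sig",
    "reported_concentration",
    "background_correct",
    "normalize_to_nonspecific",
    "blot_sensitivity_factor",
    "relative_abundance_to_concentration",
    "fold_over_baseline",
]

AVOGADRO = 6.02214076e23  # CODATA, per mol

BLOT_COLUMNS = ["lane", "antibody", "intensity", "role"]
BLOT_ROLES = {"target", "reference", "nonspecific", "background", "calibration"}


@dataclass(frozen=True)
class CellCensus:
    """Copy number plus cell geometry for one protein."""

    copies_per_cell: float
    cell_volume_L: float = 1e-15
    compartment_fraction: float = 0.30
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if not math.isfinite(self.copies_per_cell) or self.copies_per_cell < 0:
            raise ValueError("copies_per_cell must be finite and >= 0")
        if not self.cell_volume_L > 0:
            raise ValueError("cell_volume_L must be > 0")
        if not 0 < self.compartment_fraction <= 1:
            raise ValueError("compartment_fraction must be in (0, 1]")
        if not self.avogadro > 0:
            raise ValueError("avogadro must be > 0")


def compartment_concentration(census: CellCensus) -> float:
    """Concentration (molar) of the protein within its compartment."""
    return census.copies_per_cell / (
        census.avogadro * census.cell_volume_L * census.compartment_fraction
    )


def round_to_sig(value: float, n_digits: int = 1) -> float:
    """Round to ``n_digits`` significant figures (0 stays 0)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, -exponent + n_digits - 1)


def reported_concentration(conc_M: float) -> str:
    """Paper-style '~1 mM' rendering: one significant figure, natural unit."""
    if conc_M == 0:
        return "0 M"
    for unit, scale in (("M", 1.0), ("mM", 1e-3), ("µM", 1e-6), ("nM", 1e-9)):
        if abs(conc_M) >= scale:
            mantissa = round_to_sig(conc_M / scale, 1)
            if mantissa == int(mantissa):
                mantissa = int(mantissa)
            return f"~{mantissa} {unit}"
    return f"~{round_to_sig(conc_M / 1e-9, 1)} nM"


@dataclass
class BlotPanel:
    """Immunoblot band intensities keyed by (lane, antibody).

    ``table`` columns: lane (int), antibody (str), intensity (arbitrary
    densitometry units), role (target | reference | nonspecific |
    background | calibration).  The calibration role marks the
    dual-detected tagged-protein band used to compare antibody
    sensitivities.
    """

    table: pd.DataFrame
    background_corrected: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in BLOT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"blot table lacks columns {missing}")
        bad = set(self.table["role"]) - BLOT_ROLES
        if bad:
            raise ValueError(f"unknown blot roles {sorted(bad)}")
        if self.background_corrected and (self.table["intensity"] < 0).any():
            raise ValueError("background-corrected intensities must be >= 0")

    def intensity(self, lane: int, antibody: str, role: str | None = None) -> float:
        sel = (self.table["lane"] == lane) & (self.table["antibody"] == antibody)
        if role is not None:
            sel &= self.table["role"] == role
        rows = self.table[sel]
        if rows.empty:
            raise KeyError(f"no band for lane={lane}, antibody={antibody!r}, role={role!r}")
        return float(rows["intensity"].sum())


def background_correct(panel: BlotPanel) -> BlotPanel:
    """Subtract each lane's background band from its other bands.

    The background row plays the part of the user-designated empty region
    of the lane; corrected intensities are clipped at zero.
    """
    df = panel.table.copy()
    bg = df[df["role"] == "background"].groupby("lane")["intensity"].mean()
    out = df[df["role"] != "background"].copy()
    out["intensity"] = (
        out["intensity"] - out["lane"].map(bg).fillna(0.0)
    ).clip(lower=0.0)
    return BlotPanel(table=out.reset_index(drop=True), background_corrected=True)


def normalize_to_nonspecific(panel: BlotPanel) -> BlotPanel:
    """Divide each lane's bands by that lane's nonspecific loading band."""
    df = panel.table.copy()
    ns = df[df["role"] == "nonspecific"].groupby("lane")["intensity"].mean()
    if (ns <= 0).any():
        raise ValueError("nonspecific band intensity must be > 0 in every lane")
    out = df[df["role"] != "nonspecific"].copy()
    out["intensity"] = out["intensity"] / out["lane"].map(ns)
    if out["intensity"].isna().any():
        raise ValueError("a lane lacks a nonspecific band for normalization")
    return BlotPanel(table=out.reset_index(drop=True), background_corrected=panel.background_corrected)


def blot_sensitivity_factor(
    panel: BlotPanel,
    tagged_protein_lane: int,
    probe_antibody: str = "anti-Flag",
    reference_antibody: str = "anti-OmpA",
) -> float:
    """Relative antibody sensitivity from a dual-detected tagged protein.

    The same band (e.g. Flag-tagged OmpA) is detected once with each
    antibody; the intensity ratio probe/reference is the factor by which
    the probe antibody over-reports abundance (~25 in the source blots).
    """
    i_probe = panel.intensity(tagged_protein_lane, probe_antibody, role="calibration")
    i_ref = panel.intensity(tagged_protein_lane, reference_antibody, role="calibration")
    if i_ref == 0:
        raise ValueError("reference-antibody intensity is zero; factor undefined")
    return i_probe / i_ref


def relative_abundance_to_concentration(
    i_probe_target: float,
    i_reference: float,
    factor: float,
    reference_conc_M: float,
) -> float:
    """Target concentration from cross-antibody band comparison.

    The probe-antibody intensity of the target is first deflated by the
    sensitivity factor, then scaled by the reference protein's known
    concentration:  conc = reference_conc * (I_target / factor) / I_ref.
    """
    if not (i_probe_target > 0 and i_reference > 0 and factor > 0 and reference_conc_M > 0):
        raise ValueError("all inputs must be > 0")
    return reference_conc_M * (i_probe_target / factor) / i_reference


def fold_over_baseline(conc_M: float, baseline_M: float = 1e-6) -> float:
    """Fold change of a concentration over a baseline (default 1 µM)."""
    if not (conc_M >= 0 and baseline_M > 0):
        raise ValueError("conc_M must be >= 0 and baseline_M > 0")
    return conc_M / baseline_M
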