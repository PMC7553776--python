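"""Readers and writers for the pipeline's plain-text formats.

Peak lists: one CSV per titration point (residue_id, residue_name,
shift_h_ppm, shift_n_ppm) plus a manifest CSV mapping file to molar_ratio
and protein_conc_uM.  Sensorgrams: one long-format CSV (series_id,
analyte_conc_nM, time_s, response_nm, phase).  Blots: one CSV (lane,
antibody, intensity, role).  All files are UTF-8 with '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .bli import Sensorgram, SensorgramSet
from .census import BlotPanel
from .csp import PEAK_COLUMNS, CSPProfile, TitrationSeries

__all__ = [
    "write_titration",
    "read_titration",
    "write_sensorgrams",
    "read_sensorgrams",
    "write_blot",
    "read_blot",
    "write_csp_table",
    "write_json",
    "read_json",
]


def write_titration(series: TitrationSeries, out_dir: str | Path) -> Path:
    """Write per-point peak-list CSVs plus a manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for k, ratio in enumerate(series.ratios):
        fname = f"peaks_point{k:02d}.csv"
        series.points[ratio][PEAK_COLUMNS].to_csv(out / fname, index=False)
        records.append({"file": fname, "molar_ratio": ratio, "protein_conc_uM": series.protein_conc_uM})
    manifest = out / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


def read_titration(manifest_path: str | Path) -> TitrationSeries:
    """Load a titration series from its manifest CSV."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"file", "molar_ratio", "protein_conc_uM"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    p0 = manifest["protein_conc_uM"].unique()
    if p0.size != 1:
        raise ValueError("manifest lists more than one protein concentration")
    points = {
        float(row.molar_ratio): pd.read_csv(manifest_path.parent / row.file)
        for row in manifest.itertuples()
    }
    return TitrationSeries(protein_conc_uM=float(p0[0]), points=points)


def write_sensorgrams(sets: list[SensorgramSet], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for sgset in sets:
        for sg in sgset.sensorgrams:
            frames.append(
                pd.DataFrame(
                    {
                        "series_id": sgset.series_id,
                        "analyte_conc_nM": sg.analyte_conc_nM,
                        "time_s": sg.time_s,
                        "response_nm": sg.response_nm,
                        "phase": np.where(sg.time_s <= sg.t_assoc_end_s, "assoc", "dissoc"),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")
    return path


def read_sensorgrams(path: str | Path) -> list[SensorgramSet]:
    df = pd.read_csv(path)
    required = {"series_id", "analyte_conc_nM", "time_s", "response_nm", "phase"}
    if not required <= set(df.columns):
        raise ValueError(f"sensorgram CSV must have columns {sorted(required)}")
    sets = []
    for series_id, group in df.groupby("series_id", sort=False):
        traces = []
        for conc, g in group.groupby("analyte_conc_nM", sort=True):
            g = g.sort_values("time_s")
            assoc_times = g.loc[g["phase"] == "assoc", "time_s"]
            if assoc_times.empty:
                raise ValueError(f"series {series_id} conc {conc} has no association phase")
            traces.append(
                Sensorgram(
                    analyte_conc_nM=float(conc),
                    time_s=g["time_s"].to_numpy(),
                    response_nm=g["response_nm"].to_numpy(),
                    t_assoc_end_s=float(assoc_times.max()),
                )
            )
        sets.append(SensorgramSet(series_id=str(series_id), sensorgrams=traces))
    return sets


def write_blot(panel: BlotPanel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    panel.table.to_csv(path, index=False)
    return path


def read_blot(path: str | Path, background_corrected: bool = False) -> BlotPanel:
    return BlotPanel(table=pd.read_csv(path), background_corrected=background_corrected)


def write_csp_table(profile: CSPProfile, path: str | Path) -> Path:
    """TSV of per-residue CSPs with significance calls (if thresholded)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = profile.table.copy()
    if profile.significant is not None:
        table["significant"] = table["residue_id"].isin(profile.significant)
    table.to_csv(path, sep="\t", index=False)
    return path


def write_json(obj: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
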