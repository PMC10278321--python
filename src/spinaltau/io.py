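"""Readers and writers for the package's CSV dialects and catalog files.

Rise data travel as ``needle,replicate,height_cm,time_s`` CSV (one row
per graduation crossing); regression input as
``needle,R_cm_s_per_ml,tau_s``. Lab sources sometimes use a decimal
comma — readers accept it behind an explicit flag rather than guessing.
Needle catalogs are YAML with dimensions in mm, converted once at parse
time to the canonical cm system.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .hydraulics import FluidProperties, ManometerSpec, NeedleSpec
from .estimation import FitResult, RiseDataset
from .simulator import SimulatedTrace
from .units import mm_to_cm, viscosity_cmh2o_s

__all__ = [
    "read_rise_csv",
    "write_rise_csv",
    "read_tau_resistance_csv",
    "write_tau_resistance_csv",
    "write_fit_results_csv",
    "write_trace_csv",
    "load_needle_catalog",
]

_RISE_COLUMNS = ["needle", "replicate", "height_cm", "time_s"]


def _read_csv(path, decimal_comma: bool) -> pd.DataFrame:
    return pd.read_csv(path, decimal="," if decimal_comma else ".")


def read_rise_csv(path, decimal_comma: bool = False) -> List[RiseDataset]:
    """Read rise observations, one :class:`RiseDataset` per needle/replicate."""
    df = _read_csv(path, decimal_comma)
    missing = [c for c in _RISE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"rise CSV {path} lacks columns: {', '.join(missing)}")
    datasets = []
    for (needle, rep), grp in df.groupby(["needle", "replicate"], sort=False):
        if grp["time_s"].duplicated().any():
            raise ConfigurationError(
                f"duplicated observation times in {needle}/{rep}; refusing to average"
            )
        grp = grp.sort_values("time_s")
        datasets.append(
            RiseDataset.from_arrays(needle, rep, grp["time_s"].values, grp["height_cm"].values)
        )
    return datasets


def write_rise_csv(path, datasets: List[RiseDataset]) -> None:
    records = [
        {
            "needle": ds.needle_label,
            "replicate": ds.replicate_label,
            "height_cm": o.height,
            "time_s": o.time,
        }
        for ds in datasets
        for o in ds.observations
    ]
    pd.DataFrame.from_records(records, columns=_RISE_COLUMNS).to_csv(path, index=False)


def read_tau_resistance_csv(path, decimal_comma: bool = False) -> List[Tuple[str, float, float]]:
    df = _read_csv(path, decimal_comma)
    for col in ("needle", "R_cm_s_per_ml", "tau_s"):
        if col not in df.columns:
            raise ConfigurationError(f"regression CSV {path} lacks column {col!r}")
    return [
        (rec.needle, float(rec.R_cm_s_per_ml), float(rec.tau_s))
        for rec in df.itertuples(index=False)
    ]


def write_tau_resistance_csv(path, pairs: List[Tuple[str, float, float]]) -> None:
    pd.DataFrame(pairs, columns=["needle", "R_cm_s_per_ml", "tau_s"]).to_csv(path, index=False)


def write_fit_results_csv(path, labelled_fits: List[Tuple[str, str, FitResult]]) -> None:
    records = [
        {
            "needle": needle,
            "replicate": rep,
            "p_inf_cmH2O": fit.p_inf,
            "tau_s": fit.tau,
            "r_squared": fit.r_squared,
            "rmse_cm": fit.rmse,
            "mode": fit.mode,
        }
        for needle, rep, fit in labelled_fits
    ]
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def write_trace_csv(path, trace: SimulatedTrace, metadata_path=None, seed=None, time_step=None) -> None:
    """Write a simulated trace; provenance goes to a YAML sidecar."""
    pd.DataFrame({"time_s": trace.times, "height_cm": trace.heights}).to_csv(path, index=False)
    if metadata_path is not None:
        meta = {
            "assembly": trace.assembly_description,
            "forcing": {
                "mean_pressure_cmH2O": trace.forcing.mean_pressure,
                "cardiac_amplitude_cm": trace.forcing.cardiac_amplitude,
                "cardiac_frequency_hz": trace.forcing.cardiac_frequency,
                "respiratory_amplitude_cm": trace.forcing.respiratory_amplitude,
                "respiratory_frequency_hz": trace.forcing.respiratory_frequency,
            },
            "time_step_s": time_step,
            "rng_seed": seed,
        }
        Path(metadata_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def load_needle_catalog(path) -> Tuple[List[NeedleSpec], Optional[ManometerSpec], FluidProperties]:
    """Parse a YAML needle catalog; all mm quantities become cm here, once.

    Expected layout::

        needles:
          - name: 22G Pajunk Sprotte
            gauge: 22G
            length_mm: 90
            outer_diameter_mm: 0.72
            inner_diameter_mm: 0.41    # optional
            resistance_cm_s_per_ml: 667.9  # optional
        manometer:
          bore_diameter_mm: 3.7
        fluid:
          density_g_per_ml: 1.0006
          viscosity_mPa_s: 1.002
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "needles" not in doc:
        raise ConfigurationError(f"catalog {path} must contain a 'needles' section")
    needles = []
    for entry in doc["needles"]:
        try:
            needles.append(
                NeedleSpec(
                    name=entry["name"],
                    gauge=entry.get("gauge", "?"),
                    length=mm_to_cm(entry["length_mm"]),
                    inner_diameter=(
                        mm_to_cm(entry["inner_diameter_mm"])
                        if "inner_diameter_mm" in entry
                        else None
                    ),
                    outer_diameter=(
                        mm_to_cm(entry["outer_diameter_mm"])
                        if "outer_diameter_mm" in entry
                        else None
                    ),
                    resistance=entry.get("resistance_cm_s_per_ml"),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(f"catalog entry missing key {exc}") from exc
    manometer = None
    if "manometer" in doc:
        manometer = ManometerSpec(bore_diameter=mm_to_cm(doc["manometer"]["bore_diameter_mm"]))
    fluid_cfg = doc.get("fluid", {})
    fluid = FluidProperties(
        density=fluid_cfg.get("density_g_per_ml", 1.0006),
        dynamic_viscosity=viscosity_cmh2o_s(fluid_cfg.get("viscosity_mPa_s", 1.002)),
    )
    return needles, manometer, fluid
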