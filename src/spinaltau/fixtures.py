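"""Bundled bench-measurement fixtures.

Three small CSV tables ship with the package:

* ``table1`` — drop-weight flow measurements for three 22G spinal
  needles (3 replicates each) with the flow rates and resistances as
  originally reported alongside.
* ``table2`` — manometer rise readings (1 cm graduations up to 13 cm,
  3 needles x 3 replicates) under a 13 cmH2O constant head.
* ``table3`` — five published (resistance, time constant) pairs for
  needles measured with a ~3 mm bore manometer.

The rise-time table was transcribed from a decimal-comma source; the
normalized CSV is authoritative and the raw transcription is kept next
to it (``table2_raw.txt``) for audit. Loaders verify a SHA-256 checksum
so silent corruption of the bundled data fails loudly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import List, Tuple

import pandas as pd

from .exceptions import FixtureError
from .hydraulics import DropMeasurement
from .estimation import RiseDataset

__all__ = ["Table1Row", "load_fixture", "FIXTURE_NAMES"]

#: Driving head stated for the drop-weight protocol, cmH2O.
STATED_DELTA_P = 13.0

_CHECKSUMS = {
    "table1.csv": "82beab380c49a7702d134dab544e0b35d04390f442928031ba31d19fcd4fadc6",
    "table2.csv": "2ecaae83cdbe432b3ce6043caa11461a552e9f0bbc5b956c8c9b3fe83dee6d0e",
    "table3.csv": "68af582f8139edb4c50366be397575ad63f24b64e09539b0da20c6f8c3dc5e06",
}

FIXTURE_NAMES = ("table1", "table2", "table3")


@dataclass(frozen=True)
class Table1Row:
    """One drop-weight measurement with the originally reported values."""

    needle: str
    replicate: str
    drops: DropMeasurement
    flow_rate_printed: float  # ml/s
    resistance_printed: float  # cmH2O.s/ml


def _read_checked(filename: str) -> pd.DataFrame:
    ref = resources.files("spinaltau").joinpath("data", filename)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:
        raise FixtureError(f"bundled fixture {filename!r} is missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise FixtureError(
            f"bundled fixture {filename!r} failed its integrity check "
            f"(sha256 {digest} != {_CHECKSUMS[filename]})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def _load_table1() -> List[Table1Row]:
    df = _read_checked("table1.csv")
    rows = []
    for rec in df.itertuples(index=False):
        drops = DropMeasurement(
            n_drops=int(rec.n_drops),
            total_mass=rec.total_mass_mg / 1000.0,  # mg -> g
            duration=float(rec.duration_s),
            applied_pressure=STATED_DELTA_P,
        )
        rows.append(
            Table1Row(
                needle=rec.needle,
                replicate=rec.measurement,
                drops=drops,
                flow_rate_printed=float(rec.flow_rate_printed_ml_per_s),
                resistance_printed=float(rec.resistance_printed_cm_s_per_ml),
            )
        )
    if len(rows) != 9:
        raise FixtureError(f"table1 must contain 9 measurements, found {len(rows)}")
    return rows


def _load_table2() -> List[RiseDataset]:
    df = _read_checked("table2.csv")
    datasets = []
    for (needle, rep), grp in df.groupby(["needle", "replicate"], sort=False):
        grp = grp.sort_values("height_cm")
        datasets.append(
            RiseDataset.from_arrays(needle, rep, grp["time_s"].values, grp["height_cm"].values)
        )
    if len(datasets) != 9 or any(len(ds) != 13 for ds in datasets):
        raise FixtureError("table2 must contain 9 replicates of 13 observations")
    return datasets


def _load_table3() -> List[Tuple[str, float, float]]:
    df = _read_checked("table3.csv")
    pairs = [
        (rec.needle, float(rec.R_cm_s_per_ml), float(rec.tau_s))
        for rec in df.itertuples(index=False)
    ]
    if len(pairs) != 5:
        raise FixtureError(f"table3 must contain 5 pairs, found {len(pairs)}")
    return pairs


def load_fixture(name: str):
    """Load a bundled fixture by name ('table1', 'table2' or 'table3')."""
    loaders = {"table1": _load_table1, "table2": _load_table2, "table3": _load_table3}
    try:
        loader = loaders[name]
    except KeyError:
        raise FixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return loader()
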