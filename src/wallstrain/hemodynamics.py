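"""Pressure-trace synthesis and analysis for the pulsatile flow circuit.

Provides synthetic lumen/sac pressure waveforms, automatic cardiac-cycle
delimitation at end-diastole (local pressure minima), per-cycle pulse
pressure, and summaries of benchtop pulse-pressure tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "PressureTrace",
    "CycleWindow",
    "synth_waveform",
    "detect_cycles",
    "pulse_pressure",
    "table_summary",
    "load_packaged_table",
    "read_pressure_csv",
    "write_pressure_csv",
]

#: Conversion factor, 1 mm Hg in kPa.
MMHG_TO_KPA = 0.133322

_SITES = ("lumen", "sac")


@dataclass(frozen=True)
class PressureTrace:
    """Uniformly sampled pressure recording at one catheter site.

    ``time`` in seconds (monotone, uniform), ``pressure`` in mm Hg.
    """

    time: np.ndarray
    pressure: np.ndarray
    site: str = "lumen"

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        pressure = np.asarray(self.pressure, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "pressure", pressure)
        if self.site not in _SITES:
            raise ValueError(f"site must be one of {_SITES}")
        if time.ndim != 1 or time.size < 2 or pressure.shape != time.shape:
            raise ValueError("time and pressure must be 1-D with >= 2 samples")
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.ptp(dt) > 1e-6:
            raise ValueError("sampling must be uniform within 1e-6 s")
        if not (np.all(np.isfinite(time)) and np.all(np.isfinite(pressure))):
            raise ValueError("samples must be finite")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class CycleWindow:
    """Index window delimiting one cardiac cycle, end-diastole to end-diastole."""

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")
        if self.start_index < 0:
            raise ValueError("indices must be non-negative")


def synth_waveform(
    heart_rate: float,
    p_sys: float,
    p_dia: float,
    n_cycles: int = 1,
    samples_per_cycle: int = 100,
    shape: str = "skewed",
    site: str = "lumen",
) -> PressureTrace:
    """Synthesize a periodic pressure waveform starting at end-diastole.

    Parameters
    ----------
    heart_rate : beats per minute.
    p_sys, p_dia : systolic and diastolic pressures, mm Hg.
    shape : ``"sine"`` for a symmetric raised cosine; ``"skewed"`` for a
        physiological asymmetry — raised-cosine upstroke over the first third
        of the cycle, slower cosine decay over the remaining two thirds.

    The first sample lies exactly at the diastolic minimum, so frame 0 of a
    cine driven by this waveform is the end-diastolic reference.
    """
    if heart_rate <= 0:
        raise ValueError("heart rate must be positive")
    if p_sys <= p_dia:
        raise ValueError("systolic pressure must exceed diastolic pressure")
    if n_cycles < 1 or samples_per_cycle < 2:
        raise ValueError("need at least one cycle of >= 2 samples")
    period = 60.0 / heart_rate
    n = n_cycles * samples_per_cycle
    time = np.arange(n) * period / samples_per_cycle
    phase = np.mod(time / period, 1.0)
    pp = p_sys - p_dia
    if shape == "sine":
        frac = (1.0 - np.cos(2.0 * np.pi * phase)) / 2.0
    elif shape == "skewed":
        up = phase < 1.0 / 3.0
        frac = np.empty_like(phase)
        frac[up] = (1.0 - np.cos(3.0 * np.pi * phase[up])) / 2.0
        frac[~up] = (1.0 + np.cos(np.pi * (phase[~up] - 1.0 / 3.0) / (2.0 / 3.0))) / 2.0
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return PressureTrace(time=time, pressure=p_dia + pp * frac, site=site)


def detect_cycles(trace: PressureTrace, prominence_frac: float = 0.1) -> list[CycleWindow]:
    """Delimit cardiac cycles at successive end-diastolic pressure minima.

    Minima are found with a prominence guard of ``prominence_frac`` of the
    global pressure excursion.  The first and last samples also qualify as
    cycle boundaries when they sit at the diastolic level (within 5% of the
    excursion above the global minimum), since a recording deliberately
    started at end-diastole has no interior minimum at its edges.
    """
    p = trace.pressure
    excursion = float(np.max(p) - np.min(p))
    if excursion <= 0:
        raise ValueError("no cycle detected: trace is constant")
    minima, _ = find_peaks(-p, prominence=prominence_frac * excursion)
    boundaries = list(minima)
    edge_tol = 0.05 * excursion
    if p[0] <= np.min(p) + edge_tol and (not boundaries or boundaries[0] != 0):
        boundaries.insert(0, 0)
    last = len(p) - 1
    if p[last] <= np.min(p) + edge_tol and boundaries[-1] != last:
        boundaries.append(last)
    if len(boundaries) < 2:
        raise ValueError("no cycle detected: fewer than two end-diastolic minima")
    return [
        CycleWindow(start_index=int(a), end_index=int(b))
        for a, b in zip(boundaries[:-1], boundaries[1:])
    ]


def pulse_pressure(trace: PressureTrace, window: CycleWindow | None = None) -> float:
    """Pulse pressure (mm Hg) within one cycle window: max − min pressure.

    With ``window=None`` the whole trace is used.
    """
    if window is None:
        seg = trace.pressure
    else:
        if window.end_index >= len(trace):
            raise ValueError("window exceeds trace bounds")
        seg = trace.pressure[window.start_index : window.end_index + 1]
    if seg.size == 0:
        raise ValueError("empty window")
    return float(np.max(seg) - np.min(seg))


def load_packaged_table() -> pd.DataFrame:
    """Benchtop pulse-pressure table shipped with the package.

    24 lumen and 24 sac pulse pressures (mm Hg): two deployment conditions ×
    four packing volumes × three time points.
    """
    with resources.files("wallstrain.data").joinpath("pulse_pressure_table.csv").open() as fh:
        return pd.read_csv(fh)


def table_summary(table: pd.DataFrame | None = None) -> dict[str, float]:
    """Per-site mean pulse pressure (mm Hg, 1 dp) over a benchtop table.

    Pools all rows (both deployment conditions, all packing volumes and time
    points).  Defaults to the packaged table.
    """
    if table is None:
        table = load_packaged_table()
    required = {"condition", "packing_pct", "minute", "lumen_pp", "sac_pp"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    if table[["lumen_pp", "sac_pp"]].isna().any().any():
        raise ValueError("table contains missing pulse-pressure cells")
    return {
        "lumen": round(float(table["lumen_pp"].mean()), 1),
        "sac": round(float(table["sac_pp"].mean()), 1),
    }


def read_pressure_csv(path: str | Path) -> tuple[PressureTrace, PressureTrace]:
    """Read a two-site pressure recording.

    CSV columns: ``time_s, lumen_mmHg, sac_mmHg`` (header required).
    Returns (lumen, sac) traces.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "lumen_mmHg", "sac_mmHg"):
        if col not in df.columns:
            raise ValueError(f"pressure CSV missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    return (
        PressureTrace(time=t, pressure=df["lumen_mmHg"].to_numpy(float), site="lumen"),
        PressureTrace(time=t, pressure=df["sac_mmHg"].to_numpy(float), site="sac"),
    )


def write_pressure_csv(path: str | Path, lumen: PressureTrace, sac: PressureTrace) -> None:
    if len(lumen) != len(sac) or not np.allclose(lumen.time, sac.time):
        raise ValueError("lumen and sac traces must share a time base")
    pd.DataFrame(
        {"time_s": lumen.time, "lumen_mmHg": lumen.pressure, "sac_mmHg": sac.pressure}
    ).to_csv(path, index=False)
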