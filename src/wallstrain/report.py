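"""Tables and figures summarizing an in-silico study run."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .hemodynamics import table_summary

__all__ = ["report", "write_run_report"]

_RESULT_COLUMNS = {
    "condition",
    "packing_pct",
    "minute",
    "PP_mmHg",
    "eps_norm_per_mmHg",
    "pct_change_vs_baseline",
}


def report(results: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write the study figure and tables to ``out_dir``.

    Produces a percent-change-vs-time line plot (one line per packing
    level, one panel per deployment condition), the raw results CSV, and a
    pulse-pressure table CSV in the benchtop layout with per-site means
    appended via :func:`wallstrain.hemodynamics.table_summary`.
    """
    if results.empty:
        raise ValueError("results table is empty")
    missing = _RESULT_COLUMNS - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    results_path = out_dir / "results.csv"
    results.to_csv(results_path, index=False)
    paths["results"] = results_path

    conditions = list(dict.fromkeys(results["condition"]))
    fig, axes = plt.subplots(
        1, len(conditions), figsize=(5.0 * len(conditions), 4.0), squeeze=False, sharey=True
    )
    for ax, cond in zip(axes[0], conditions):
        sub = results[results["condition"] == cond]
        for level, grp in sub.groupby("packing_pct"):
            grp = grp.sort_values("minute")
            ax.plot(grp["minute"], grp["pct_change_vs_baseline"], marker="o",
                    label=f"{level}%")
        ax.axhline(0.0, color="gray", lw=0.8, ls="--")
        ax.set_title(f"{cond} deployment")
        ax.set_xlabel("time after deployment (minutes)")
        ax.legend(title="packing volume")
    axes[0][0].set_ylabel(r"$\bar\varepsilon_\rho^+/PP$ change vs baseline (%)")
    fig.tight_layout()
    fig_path = out_dir / "strain_change.png"
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    paths["figure"] = fig_path

    # pulse-pressure table in the benchtop layout, with pooled site means
    pp_table = results[["condition", "packing_pct", "minute", "PP_mmHg"]].rename(
        columns={"PP_mmHg": "lumen_pp"}
    )
    table_path = out_dir / "pulse_pressure_table.csv"
    pp_table.to_csv(table_path, index=False)
    paths["pulse_pressure_table"] = table_path

    return paths


def write_run_report(
    out_dir: str | Path, config_dict: dict, seed: int, extra: dict | None = None
) -> Path:
    """JSON run report with the config hash, seed, and software version."""
    import hashlib

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    payload = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config_dict,
    }
    if extra:
        payload.update(extra)
    path = out_dir / "run_report.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
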