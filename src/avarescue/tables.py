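"""Tabular output for sweep results and staffing summaries."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .scenario import SweepResult

__all__ = ["sweep_frame", "write_sweep_table"]


def sweep_frame(result: SweepResult, summary_extra: dict | None = None) -> pd.DataFrame:
    """Per-threshold table plus a summary block of headline quantities.

    The summary mirrors the usual reporting layout: optimal threshold, mean
    lives at the optimum and at the 150 cm reference threshold, and (when
    supplied via ``summary_extra``) the 300-cm-first-subject comparison.
    """
    rows = [
        {"threshold_cm": t, "mean_lives": m}
        for t, m in zip(result.thresholds_cm, result.mean_lives)
    ]
    frame = pd.DataFrame(rows, columns=["threshold_cm", "mean_lives"])
    summary = {
        "optimal_threshold_cm": result.optimal_threshold_cm,
        "mean_lives_at_optimum": result.mean_lives_at_optimum,
        "mean_lives_at_150cm_threshold": result.mean_lives_at_150,
    }
    if summary_extra:
        summary.update(summary_extra)
    summary_rows = pd.DataFrame(
        [{"threshold_cm": key, "mean_lives": value} for key, value in summary.items()],
        columns=["threshold_cm", "mean_lives"],
    )
    return pd.concat([frame, summary_rows], ignore_index=True)


def write_sweep_table(
    result: SweepResult, path: str | Path, summary_extra: dict | None = None
) -> None:
    """Write the sweep table as CSV; same inputs give a byte-identical file."""
    frame = sweep_frame(result, summary_extra)
    try:
        frame.to_csv(path, index=False, float_format="%.6g")
    except OSError as err:
        raise OSError(f"cannot write sweep table to {path}: {err}") from err
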