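"""Relative-expression arithmetic for RT-qPCR validation (2^-ddCt).

dCt = target Ct - reference Ct within one sample; ddCt is the difference of
dCt between a treated sample and its untreated control, and the fold change
in relative expression is 2^-ddCt. Technical replicates are averaged on the
Ct scale before the exponentiation; biological replicates are summarised on
the fold-change scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "ddct_fold_change",
    "summarize_ddct",
    "read_qpcr",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One sample's mean Ct values for target and reference genes."""

    sample: str
    target_ct: float
    reference_ct: float
    group: str = "treated"

    def __post_init__(self) -> None:
        for name, v in (("target_ct", self.target_ct), ("reference_ct", self.reference_ct)):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{self.sample}: {name} must be positive and finite, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def ddct_fold_change(treated: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Fold change 2^-ddCt of treated relative to control."""
    ddct = treated.delta_ct - control.delta_ct
    return 2.0 ** (-ddct)


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read a ``sample,group,target_ct,reference_ct`` CSV (one row per
    technical replicate is allowed)."""
    df = pd.read_csv(path)
    required = ["sample", "group", "target_ct", "reference_ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def summarize_ddct(
    measurements: pd.DataFrame | list[QpcrMeasurement],
    control_group: str = "control",
) -> pd.DataFrame:
    """Per-group mean fold change and SD across biological replicates.

    Rows sharing ``(sample, group)`` are technical replicates and are
    averaged on the Ct scale first. Each treated sample is paired with the
    control-group entry of the same ``sample`` name; if none exists and the
    control group holds exactly one sample, that one serves as the common
    calibrator. A treated group with no resolvable control is an error.

    Returns a table ``group, n, mean_fold_change, sd_fold_change`` (SD with
    the n-1 denominator; NaN — not 0 — for a single replicate).
    """
    if isinstance(measurements, list):
        df = pd.DataFrame(
            {
                "sample": [m.sample for m in measurements],
                "group": [m.group for m in measurements],
                "target_ct": [m.target_ct for m in measurements],
                "reference_ct": [m.reference_ct for m in measurements],
            }
        )
    else:
        df = measurements.copy()
    # technical replicates -> one mean Ct per (sample, group)
    agg = (
        df.groupby(["group", "sample"], sort=False)[["target_ct", "reference_ct"]]
        .mean()
        .reset_index()
    )
    agg["delta_ct"] = agg["target_ct"] - agg["reference_ct"]
    controls = agg[agg["group"] == control_group]
    if controls.empty:
        raise ValueError(f"no measurements in control group {control_group!r}")
    control_by_sample = dict(zip(controls["sample"], controls["delta_ct"]))
    sole_control = controls["delta_ct"].iloc[0] if len(controls) == 1 else None
    rows = []
    for group, sub in agg.groupby("group", sort=False):
        folds = []
        for row in sub.itertuples(index=False):
            ctrl = control_by_sample.get(row.sample, sole_control)
            if ctrl is None:
                raise ValueError(
                    f"group {group!r}, sample {row.sample!r}: no control partner "
                    f"in group {control_group!r}"
                )
            folds.append(2.0 ** (-(row.delta_ct - ctrl)))
        folds = np.asarray(folds)
        rows.append(
            {
                "group": group,
                "n": len(folds),
                "mean_fold_change": folds.mean(),
                "sd_fold_change": folds.std(ddof=1) if len(folds) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "mean_fold_change", "sd_fold_change"])
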