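"""Per-plate normalization against negative controls and Z'-factor QC.

Each well's readout is expressed as a log2 fold change against the center of
its own plate's siNC (negative-control) wells, computed independently per
(cell_line, readout, plate, replicate). On this scale 0 means "behaves like
the negative control" and negative values mean stronger inhibition than the
control. The screening window of each plate is summarized by the Z'-factor
comparing siPLK1 (positive) and siNC (negative) control separation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import QCError
from .simulate import NEGATIVE_CONTROL, POSITIVE_CONTROL

__all__ = ["normalize_screen", "zprime", "qc_report"]

#: Readouts whose raw values are counts; zeros are floored at pseudo-count 1.
COUNT_READOUTS = ("count2d", "sphere3d")


def _floor_zeros(group: pd.DataFrame, pseudocount: float | None) -> np.ndarray:
    """Replace zero raw values with a positive floor so log2 is defined.

    Counts floor at ``pseudocount`` (default 1); continuous readouts floor at
    the smallest positive observed value in the group.
    """
    values = group["raw_value"].to_numpy(dtype=float).copy()
    zero = values <= 0
    if zero.any():
        readout = group["readout"].iat[0]
        if pseudocount is not None:
            floor = pseudocount
        elif readout in COUNT_READOUTS:
            floor = 1.0
        else:
            positive = values[values > 0]
            floor = positive.min() if positive.size else 1.0
        warnings.warn(
            f"{int(zero.sum())} zero raw value(s) floored to {floor} "
            f"({readout}, plate {group['plate'].iat[0]})",
            stacklevel=2,
        )
        values[zero] = floor
    return values


def normalize_screen(
    raw: pd.DataFrame,
    center: str = "mean",
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Convert raw readouts to per-plate log2 fold changes vs siNC.

    log2fc = log2(raw) - center(log2(siNC raw)) within each
    (cell_line, readout, plate, replicate) group. ``center`` is "mean"
    (geometric mean on the raw scale; default) or "median".

    Raises :class:`QCError` if any plate group has fewer than 2 positive siNC
    wells.
    """
    if center not in ("mean", "median"):
        raise ValueError(f"center must be 'mean' or 'median', got {center!r}")
    out = []
    keys = ["cell_line", "readout", "plate", "replicate"]
    for key, group in raw.groupby(keys, sort=False):
        values = _floor_zeros(group, pseudocount)
        log2 = np.log2(values)
        sinc = log2[(group["gene_id"] == NEGATIVE_CONTROL).to_numpy()]
        if sinc.size < 2:
            raise QCError(
                f"plate group {key} has {sinc.size} usable siNC well(s); >= 2 required"
            )
        ref = float(np.mean(sinc)) if center == "mean" else float(np.median(sinc))
        norm = group[["cell_line", "readout", "plate", "well", "gene_id", "replicate"]].copy()
        norm["log2fc"] = log2 - ref
        out.append(norm)
    return pd.concat(out, ignore_index=True)


def zprime(negative: np.ndarray, positive: np.ndarray, ddof: int = 1) -> float:
    """Z'-factor screening-window statistic on log2-scale control values.

    Z' = 1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|, with sample (n-1)
    standard deviations. Returns NaN when the control means coincide (window
    undefined).
    """
    negative = np.asarray(negative, dtype=float)
    positive = np.asarray(positive, dtype=float)
    if negative.size < 2 or positive.size < 2:
        raise QCError("Z' requires >= 2 wells in each control group")
    sep = abs(positive.mean() - negative.mean())
    if sep == 0:
        return float("nan")
    return 1.0 - 3.0 * (positive.std(ddof=ddof) + negative.std(ddof=ddof)) / sep


def qc_report(raw: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Per-(cell_line, readout, plate) control summary and Z'-factor.

    Control statistics are computed on log2 raw values pooled over replicates
    (Z' is invariant to the per-plate normalization shift).
    """
    rows = []
    for (line, readout, plate), group in raw.groupby(
        ["cell_line", "readout", "plate"], sort=False
    ):
        values = _floor_zeros(group, pseudocount)
        log2 = np.log2(values)
        sinc = log2[(group["gene_id"] == NEGATIVE_CONTROL).to_numpy()]
        plk1 = log2[(group["gene_id"] == POSITIVE_CONTROL).to_numpy()]
        z = zprime(sinc, plk1) if (sinc.size >= 2 and plk1.size >= 2) else float("nan")
        rows.append(
            {
                "cell_line": line,
                "readout": readout,
                "plate": plate,
                "zprime": z,
                "n_siNC": int(sinc.size),
                "n_siPLK1": int(plk1.size),
                "siNC_mean": sinc.mean() if sinc.size else float("nan"),
                "siNC_sd": sinc.std(ddof=1) if sinc.size >= 2 else float("nan"),
                "siPLK1_mean": plk1.mean() if plk1.size else float("nan"),
                "siPLK1_sd": plk1.std(ddof=1) if plk1.size >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
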