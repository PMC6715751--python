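"""Multiplexing cell count with total viability: per-cell viability dissection.

Viability per cell is total viability divided by total cell count in the same
well, i.e. on the log2 scale the difference of the two normalized fold
changes. A gene that strongly reduces the cell count while its surviving
cells show *increased* per-cell viability marks a resistance response of the
surviving population; such genes are labeled ``viability_up_resistant``.

Per-cell viability is computed per replicate well and then aggregated, so its
significance test (one-sided increase, pooled t against the siNC wells of the
same plate) runs on replicate-level values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hits import HitThresholds, _pooled_t_pvalues_vectorized
from .simulate import NEGATIVE_CONTROL, POSITIVE_CONTROL

__all__ = [
    "viability_per_cell",
    "per_cell_viability_screen",
    "dissect",
    "classify_discordance",
    "discordance_fraction",
]

LABELS = (
    "concordant_inhibitor",
    "count_only_inhibitor",
    "viability_up_resistant",
    "neutral",
    "other",
)


def viability_per_cell(log2fc_viability_total, log2fc_count):
    """Per-cell viability log2 fold change: total viability minus count.

    On the raw scale this is the ratio (viability per cell); missing inputs
    propagate to a missing output.
    """
    return np.asarray(log2fc_viability_total, dtype=float) - np.asarray(
        log2fc_count, dtype=float
    )


def per_cell_viability_screen(norm_counts: pd.DataFrame, norm_viability: pd.DataFrame) -> pd.DataFrame:
    """Join count and total-viability wells and derive per-cell log2fc rows.

    Rows are matched on (cell_line, plate, well, gene_id, replicate); the
    result has readout ``viability_per_cell`` and keeps control wells so
    plate-level significance tests can use the siNC per-cell values.
    """
    keys = ["cell_line", "plate", "well", "gene_id", "replicate"]
    counts = norm_counts.loc[norm_counts["readout"] == "count2d", keys + ["log2fc"]]
    viab = norm_viability.loc[norm_viability["readout"] == "viability2d", keys + ["log2fc"]]
    merged = counts.merge(viab, on=keys, suffixes=("_count", "_viability"))
    merged["log2fc"] = viability_per_cell(merged["log2fc_viability"], merged["log2fc_count"])
    merged["readout"] = "viability_per_cell"
    return merged[["cell_line", "readout", "plate", "well", "gene_id", "replicate", "log2fc"]]


def dissect(
    norm_counts: pd.DataFrame,
    norm_viability: pd.DataFrame,
    hits_count: pd.DataFrame,
    hits_viability: pd.DataFrame,
    thresholds: HitThresholds | None = None,
    per_cell_up_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-gene dissection records with discordance labels, per cell line.

    Combines the count and total-viability hit tables with replicate-level
    per-cell viability, tests per-cell *increase* significance one-sided
    against the plate's siNC per-cell values, and labels each gene:

    * ``concordant_inhibitor``: count hit and total-viability hit;
    * ``viability_up_resistant``: count hit whose per-cell viability rises
      above ``per_cell_up_threshold`` with increase-direction p below the hit
      p-threshold;
    * ``count_only_inhibitor``: remaining count hits without viability hit;
    * ``neutral``: hit in neither readout; ``other``: the remainder
      (viability-only hits).
    """
    thresholds = thresholds or HitThresholds()
    percell = per_cell_viability_screen(norm_counts, norm_viability)

    records = []
    for line, group in percell.groupby("cell_line", sort=False):
        pieces = []
        for plate, plate_group in group.groupby("plate", sort=False):
            ctrl = plate_group.loc[
                plate_group["gene_id"] == NEGATIVE_CONTROL, "log2fc"
            ].to_numpy()
            genes = plate_group[
                ~plate_group["gene_id"].isin((NEGATIVE_CONTROL, POSITIVE_CONTROL))
            ]
            agg = genes.groupby("gene_id", sort=False)["log2fc"].agg(
                mean="mean", var=lambda v: v.var(ddof=1), n="size"
            )
            agg["p_up"] = _pooled_t_pvalues_vectorized(
                agg["mean"].to_numpy(),
                agg["var"].to_numpy(),
                agg["n"].to_numpy(dtype=float),
                ctrl,
                alternative="greater",
            )
            pieces.append(agg)
        percell_stats = pd.concat(pieces)

        ch = hits_count[(hits_count["cell_line"] == line) & (hits_count["readout"] == "count2d")]
        vh = hits_viability[
            (hits_viability["cell_line"] == line) & (hits_viability["readout"] == "viability2d")
        ]
        table = (
            ch.set_index("gene_id")[["log2fc_mean", "p_value", "hit_flag"]]
            .rename(
                columns={
                    "log2fc_mean": "log2fc_count",
                    "p_value": "p_count",
                    "hit_flag": "count_hit",
                }
            )
            .join(
                vh.set_index("gene_id")[["log2fc_mean", "p_value", "hit_flag"]].rename(
                    columns={
                        "log2fc_mean": "log2fc_viability_total",
                        "p_value": "p_viability",
                        "hit_flag": "viability_hit",
                    }
                ),
                how="inner",
            )
        )
        table["log2fc_viability_per_cell"] = (
            table["log2fc_viability_total"] - table["log2fc_count"]
        )
        table = table.join(percell_stats[["p_up"]].rename(columns={"p_up": "p_per_cell_up"}))

        count_hit = table["count_hit"].astype(bool)
        viab_hit = table["viability_hit"].astype(bool)
        resistant = (
            count_hit
            & (table["log2fc_viability_per_cell"] > per_cell_up_threshold)
            & (table["p_per_cell_up"] < thresholds.p_threshold)
        )
        label = pd.Series("other", index=table.index)
        label[~count_hit & ~viab_hit] = "neutral"
        label[count_hit & viab_hit] = "concordant_inhibitor"
        label[count_hit & ~viab_hit] = "count_only_inhibitor"
        label[resistant] = "viability_up_resistant"
        table["discordance_label"] = label
        table.insert(0, "cell_line", line)
        table.index.name = "gene_id"
        records.append(table.reset_index())
    return pd.concat(records, ignore_index=True)


#: Backwards-friendly alias: the labeling step of :func:`dissect`.
classify_discordance = dissect


def discordance_fraction(records: pd.DataFrame) -> int:
    """Percent of count hits lacking a total-viability hit, nearest integer.

    Accepts a dissection table (``count_hit``/``viability_hit`` columns).
    """
    count_hits = records[records["count_hit"].astype(bool)]
    if len(count_hits) == 0:
        raise ValueError("no count hits; discordance fraction undefined")
    lacking = int((~count_hits["viability_hit"].astype(bool)).sum())
    from .hits import percentage

    return int(percentage(lacking, len(count_hits), decimals=0))
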