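"""Cross-screen classification of hits.

Two taxonomies are implemented:

* a 2D dichotomy splitting cell-count hits into sample-independent common
  inhibitors (strong mean decrease, low across-line variability) versus
  sample-selective inhibitors (moderate mean decrease, high variability); and
* a four-group 2D/3D scheme assigning each gene hit anywhere to exactly one of
  ``two_d_only``, ``three_d_only``, ``common_2d_3d`` or ``selective_2d_3d``
  (everything else is ``none``), based on which culture conditions' screens it
  is a hit in.

All comparisons use strict inequalities, so a gene exactly on a boundary does
not qualify.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .errors import ConfigError

__all__ = [
    "GROUPS",
    "build_cross_screen_profiles",
    "classify_2d_dichotomy",
    "classify_four_groups",
    "group_sizes",
]

GROUPS = ("two_d_only", "three_d_only", "common_2d_3d", "selective_2d_3d", "none")


def build_cross_screen_profiles(result_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-gene cross-screen summary from per-screen result tables.

    Columns: per-screen ``log2fc:<line>:<readout>``, ``p:<line>:<readout>``
    and ``hit:<line>:<readout>``, plus ``mean_2d``/``sd_2d`` over the 2D
    cell-count screens (NaN when fewer than 2 such screens cover the gene;
    ``sd_2d`` is the across-screen sample s.d. of the per-screen means).
    """
    pieces = []
    for table in result_tables:
        for (line, readout), screen in table.groupby(["cell_line", "readout"], sort=False):
            tag = f"{line}:{readout}"
            piece = screen.set_index("gene_id")[["log2fc_mean", "p_value", "hit_flag"]]
            piece.columns = [f"log2fc:{tag}", f"p:{tag}", f"hit:{tag}"]
            pieces.append(piece)
    profiles = pd.concat(pieces, axis=1)
    count_cols = [c for c in profiles.columns if c.startswith("log2fc:") and c.endswith(":count2d")]
    counts = profiles[count_cols]
    enough = counts.notna().sum(axis=1) >= 2
    profiles["mean_2d"] = counts.mean(axis=1).where(enough)
    profiles["sd_2d"] = counts.std(axis=1, ddof=1).where(enough)
    profiles.index.name = "gene_id"
    return profiles


def classify_2d_dichotomy(
    profiles: pd.DataFrame,
    common_mean: float = -2.0,
    common_sd: float = 1.0,
    selective_mean: float = -1.0,
    selective_sd: float = 1.0,
) -> pd.Series:
    """Split genes into sample-independent common vs sample-selective 2D hits.

    common: mean_2d < ``common_mean`` (default -2, i.e. >4-fold decrease) and
    sd_2d < ``common_sd``; selective: mean_2d < ``selective_mean`` (>2-fold)
    and sd_2d > ``selective_sd``; everything else (including genes without at
    least two 2D count screens) is ``none``.
    """
    missing = profiles["mean_2d"].isna() | profiles["sd_2d"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} gene(s) lack >= 2 2D count screens; labeled 'none'",
            stacklevel=2,
        )
    common = (profiles["mean_2d"] < common_mean) & (profiles["sd_2d"] < common_sd)
    selective = (profiles["mean_2d"] < selective_mean) & (profiles["sd_2d"] > selective_sd)
    labels = pd.Series("none", index=profiles.index, name="dichotomy")
    labels[selective & ~missing] = "sample_selective"
    labels[common & ~missing] = "sample_independent_common"
    return labels


def classify_four_groups(
    hits_2d: pd.DataFrame,
    hits_3d: pd.DataFrame,
) -> pd.DataFrame:
    """Partition genes into the four-group 2D/3D taxonomy.

    ``hits_2d`` / ``hits_3d`` are result tables for the 2D cell-count screens
    and the 3D sphere-count screens (several cell lines each). Rules, applied
    in order, with "2D met" = hit in every 2D screen covering the gene and
    "3D met" = hit in every 3D screen:

    * ``common_2d_3d``: 2D met and 3D met;
    * ``two_d_only``: 2D met and hit in no 3D screen;
    * ``three_d_only``: 3D met and hit in no 2D screen;
    * ``selective_2d_3d``: hit in at least one screen but none of the above
      (sample-specific patterns);
    * ``none``: hit nowhere.

    Returns a frame indexed by gene_id with a ``group`` column; the non-none
    groups partition the set of genes hit in at least one screen.
    """
    if hits_2d is None or hits_3d is None:
        raise ConfigError("both 2D and 3D hit tables are required")

    def hit_matrix(table: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for (line, readout), screen in table.groupby(["cell_line", "readout"], sort=False):
            cols[f"{line}:{readout}"] = screen.set_index("gene_id")["hit_flag"]
        return pd.DataFrame(cols)

    m2 = hit_matrix(hits_2d)
    m3 = hit_matrix(hits_3d)
    genes = m2.index.union(m3.index)
    m2 = m2.reindex(genes)
    m3 = m3.reindex(genes)
    # A screen not covering a gene neither helps nor blocks the "all" rule.
    any_2d = m2.fillna(False).any(axis=1)
    all_2d = m2.fillna(True).all(axis=1) & m2.notna().any(axis=1)
    any_3d = m3.fillna(False).any(axis=1)
    all_3d = m3.fillna(True).all(axis=1) & m3.notna().any(axis=1)

    group = pd.Series("none", index=genes, name="group")
    hit_anywhere = any_2d | any_3d
    group[hit_anywhere] = "selective_2d_3d"
    group[all_3d & ~any_2d] = "three_d_only"
    group[all_2d & ~any_3d] = "two_d_only"
    group[all_2d & all_3d] = "common_2d_3d"
    out = group.to_frame()
    out.index.name = "gene_id"
    return out


def group_sizes(assignments: pd.DataFrame | pd.Series) -> dict[str, int]:
    """Per-group gene counts plus their total over the four hit groups."""
    labels = assignments["group"] if isinstance(assignments, pd.DataFrame) else assignments
    counts = {g: int((labels == g).sum()) for g in GROUPS}
    counts["total"] = sum(counts[g] for g in GROUPS if g != "none")
    return counts
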