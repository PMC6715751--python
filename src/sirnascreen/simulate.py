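"""Synthetic plate-structured siRNA screening campaigns with known ground truth.

The generator emulates a well-based reverse screen: 384-well plates carrying a
library of gene-targeting siRNA wells plus negative (siNC) and positive
(siPLK1) control wells, read out in triplicate under 2D monolayer culture
(imaged cell count and a total-viability signal) and/or 3D sphere-formation
culture (sphere count). Each library gene carries a planted phenotypic effect
profile drawn from one of six classes, so every downstream stage
(normalization, hit calling, classification, dissection, enrichment) can be
validated against known truth.

Noise model
-----------
Well-to-well noise is additive Gaussian on the log2 scale, i.e. multiplicative
log-normal on the raw scale, which matches the fold-change-centric analysis
downstream. 3D noise is larger than 2D noise (sphere counts are small), and
sphere counts are by default drawn from a Poisson whose log2 mean carries the
planted effect; a continuous log-normal mode is available for exact-recovery
checks.

Randomness
----------
All randomness flows from ``SimulationConfig.seed`` through two documented
child streams: ``default_rng([seed, 0])`` for effect-class assignment and
``default_rng([seed, 1])`` for the campaign readouts (a third, ``[seed, 2]``,
drives the synthetic annotation). Repeated calls with the same config are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "EFFECT_CLASSES",
    "EffectProfile",
    "SimulationConfig",
    "TruthTable",
    "assign_effect_classes",
    "simulate_campaign",
    "simulate_annotation",
    "default_layout",
]

#: Effect classes in the phenotypic taxonomy realized by the generator.
EFFECT_CLASSES = (
    "neutral",
    "common_essential",
    "two_d_only",
    "three_d_only",
    "selective",
    "count_down_viability_up",
)

NEGATIVE_CONTROL = "siNC"
POSITIVE_CONTROL = "siPLK1"
READOUTS = ("count2d", "viability2d", "sphere3d")

# Uniform ranges for planted log2 effect magnitudes, per class. Magnitudes sit
# strictly beyond the downstream hit thresholds (-1 for counts/spheres) so the
# zero-noise limit is unambiguous.
DEFAULT_EFFECT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "common_essential": {"count2d": (-3.5, -2.2), "sphere3d": (-2.5, -1.2)},
    "two_d_only": {"count2d": (-2.5, -1.2)},
    "three_d_only": {"sphere3d": (-2.5, -1.2)},
    "selective": {"any_one_line": (-3.0, -1.5)},
    "count_down_viability_up": {"count2d": (-2.5, -1.2), "per_cell": (0.6, 1.5)},
}


def _default_proportions() -> dict[str, float]:
    return {
        "neutral": 0.75,
        "common_essential": 0.05,
        "two_d_only": 0.05,
        "three_d_only": 0.05,
        "selective": 0.05,
        "count_down_viability_up": 0.05,
    }


@dataclass(frozen=True)
class EffectProfile:
    """Planted phenotypic effect of knocking down one gene.

    Effects are log2 shifts relative to the negative-control baseline:
    ``count_effect_2d`` on the 2D cell count (per cell line),
    ``viability_per_cell_effect`` on the viability of each surviving cell, and
    ``sphere_effect_3d`` on the 3D sphere count (per cell line).
    """

    gene_id: str
    class_label: str
    count_effect_2d: dict[str, float]
    viability_per_cell_effect: float
    sphere_effect_3d: dict[str, float]

    def validate(self) -> None:
        if self.class_label not in EFFECT_CLASSES:
            raise ConfigError(f"unknown effect class {self.class_label!r}")
        c2d = self.count_effect_2d.values()
        s3d = self.sphere_effect_3d.values()
        if self.class_label == "neutral":
            if any(v != 0 for v in c2d) or any(v != 0 for v in s3d) or self.viability_per_cell_effect != 0:
                raise ConfigError(f"{self.gene_id}: neutral genes must have all effects 0")
        elif self.class_label == "common_essential":
            if any(v > -2 for v in c2d) or any(v > -1 for v in s3d):
                raise ConfigError(f"{self.gene_id}: common_essential requires count<=-2 and sphere<=-1")
        elif self.class_label == "two_d_only":
            if any(v > -1 for v in c2d) or any(v != 0 for v in s3d):
                raise ConfigError(f"{self.gene_id}: two_d_only requires count<=-1, sphere=0")
        elif self.class_label == "three_d_only":
            if any(v != 0 for v in c2d) or any(v > -1 for v in s3d):
                raise ConfigError(f"{self.gene_id}: three_d_only requires sphere<=-1, count=0")
        elif self.class_label == "count_down_viability_up":
            if any(v > -1 for v in c2d) or self.viability_per_cell_effect < 0.5:
                raise ConfigError(
                    f"{self.gene_id}: count_down_viability_up requires count<=-1 and per-cell>=+0.5"
                )


@dataclass
class SimulationConfig:
    """Parameters of a simulated screening campaign.

    Defaults mirror the assay design the package targets: 384-well plates,
    triplicate measurement, three 2D cell lines and two 3D cell lines, with
    log2-scale noise larger in 3D than in 2D.
    """

    n_genes: int = 1000
    wells_per_plate: int = 384
    n_sinc_per_plate: int = 16
    n_siplk1_per_plate: int = 8
    n_replicates: int = 3
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    noise_sd_2d: float = 0.15
    noise_sd_3d: float = 0.4
    baseline_count: float = 2000.0
    baseline_sphere_count: float = 50.0
    positive_control_effect: float = -2.0
    cell_lines_2d: tuple[str, ...] = ("A549", "HT29", "U87")
    cell_lines_3d: tuple[str, ...] = ("U87", "OVCAR8")
    #: "poisson" draws integer sphere counts; "lognormal" keeps them continuous
    #: (the zero-noise limit of the multiplicative model).
    sphere_noise: str = "poisson"
    effect_ranges: dict = field(default_factory=lambda: DEFAULT_EFFECT_RANGES)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.wells_per_plate <= 0 or self.n_replicates <= 0:
            raise ConfigError("n_genes, wells_per_plate and n_replicates must be positive")
        if self.n_sinc_per_plate < 8 or self.n_siplk1_per_plate < 2:
            raise ConfigError("every plate needs >=8 siNC and >=2 siPLK1 wells")
        n_controls = self.n_sinc_per_plate + self.n_siplk1_per_plate
        if n_controls >= self.wells_per_plate:
            raise ConfigError("controls fill the whole plate; no room for library wells")
        if self.noise_sd_2d < 0 or self.noise_sd_3d < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.baseline_count <= 0 or self.baseline_sphere_count <= 0:
            raise ConfigError("baselines must be positive")
        unknown = set(self.class_proportions) - set(EFFECT_CLASSES)
        if unknown:
            raise ConfigError(f"unknown effect classes in proportions: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.class_proportions.values()):
            raise ConfigError(f"class_proportions must be nonnegative and sum to 1 (got {total})")
        if self.sphere_noise not in ("poisson", "lognormal"):
            raise ConfigError(f"sphere_noise must be 'poisson' or 'lognormal', got {self.sphere_noise!r}")

    @property
    def library_wells_per_plate(self) -> int:
        return self.wells_per_plate - self.n_sinc_per_plate - self.n_siplk1_per_plate

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("cell_lines_2d", "cell_lines_3d"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


class TruthTable:
    """Ground-truth effect profiles for a simulated library (gene -> profile)."""

    def __init__(self, profiles: dict[str, EffectProfile]):
        self.profiles = dict(profiles)

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, gene_id: str) -> EffectProfile:
        return self.profiles[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.profiles

    def genes(self) -> list[str]:
        return list(self.profiles)

    def classes(self) -> pd.Series:
        return pd.Series({g: p.class_label for g, p in self.profiles.items()}, name="class_label")

    def genes_in_class(self, class_label: str) -> list[str]:
        return [g for g, p in self.profiles.items() if p.class_label == class_label]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a table with per-cell-line effect columns."""
        lines_2d = sorted({ln for p in self.profiles.values() for ln in p.count_effect_2d})
        lines_3d = sorted({ln for p in self.profiles.values() for ln in p.sphere_effect_3d})
        rows = []
        for gene, p in self.profiles.items():
            row: dict[str, object] = {
                "gene_id": gene,
                "class_label": p.class_label,
                "viability_per_cell_effect": p.viability_per_cell_effect,
            }
            for ln in lines_2d:
                row[f"count2d_{ln}"] = p.count_effect_2d.get(ln, 0.0)
            for ln in lines_3d:
                row[f"sphere3d_{ln}"] = p.sphere_effect_3d.get(ln, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TruthTable":
        lines_2d = [c[len("count2d_"):] for c in frame.columns if c.startswith("count2d_")]
        lines_3d = [c[len("sphere3d_"):] for c in frame.columns if c.startswith("sphere3d_")]
        profiles = {}
        for row in frame.itertuples(index=False):
            d = row._asdict()
            profiles[d["gene_id"]] = EffectProfile(
                gene_id=d["gene_id"],
                class_label=d["class_label"],
                count_effect_2d={ln: float(d[f"count2d_{ln}"]) for ln in lines_2d},
                viability_per_cell_effect=float(d["viability_per_cell_effect"]),
                sphere_effect_3d={ln: float(d[f"sphere3d_{ln}"]) for ln in lines_3d},
            )
        return cls(profiles)


def _truth_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 0])


def _screen_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1])


def _annotation_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 2])


def assign_effect_classes(config: SimulationConfig) -> TruthTable:
    """Draw an effect class and effect magnitudes for every library gene.

    Classes are drawn i.i.d. from ``config.class_proportions``; magnitudes are
    drawn uniformly from the class-specific ranges in ``config.effect_ranges``.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _truth_rng(config)
    classes = [c for c in EFFECT_CLASSES if config.class_proportions.get(c, 0.0) > 0]
    probs = np.array([config.class_proportions[c] for c in classes])
    probs = probs / probs.sum()
    gene_ids = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    drawn = rng.choice(len(classes), size=config.n_genes, p=probs)
    ranges = config.effect_ranges
    all_lines = list(dict.fromkeys(list(config.cell_lines_2d) + list(config.cell_lines_3d)))

    profiles: dict[str, EffectProfile] = {}
    for gene, ci in zip(gene_ids, drawn):
        label = classes[ci]
        c2d = {ln: 0.0 for ln in config.cell_lines_2d}
        s3d = {ln: 0.0 for ln in config.cell_lines_3d}
        per_cell = 0.0
        if label == "common_essential":
            c2d = {ln: float(rng.uniform(*ranges[label]["count2d"])) for ln in config.cell_lines_2d}
            s3d = {ln: float(rng.uniform(*ranges[label]["sphere3d"])) for ln in config.cell_lines_3d}
        elif label == "two_d_only":
            mag = float(rng.uniform(*ranges[label]["count2d"]))
            c2d = {ln: mag for ln in config.cell_lines_2d}
        elif label == "three_d_only":
            mag = float(rng.uniform(*ranges[label]["sphere3d"]))
            s3d = {ln: mag for ln in config.cell_lines_3d}
        elif label == "selective":
            # Strong effect in exactly one randomly chosen cell line.
            line = all_lines[int(rng.integers(len(all_lines)))]
            mag = float(rng.uniform(*ranges[label]["any_one_line"]))
            if line in c2d:
                c2d[line] = mag
            if line in s3d:
                s3d[line] = mag
        elif label == "count_down_viability_up":
            mag = float(rng.uniform(*ranges[label]["count2d"]))
            c2d = {ln: mag for ln in config.cell_lines_2d}
            per_cell = float(rng.uniform(*ranges[label]["per_cell"]))
        profile = EffectProfile(gene, label, c2d, per_cell, s3d)
        profile.validate()
        profiles[gene] = profile
    return TruthTable(profiles)


def _well_labels(n_wells: int) -> list[str]:
    """A01..P24-style labels for standard plate sizes, sequential otherwise."""
    for rows, cols in ((8, 12), (16, 24), (32, 48)):
        if n_wells == rows * cols:
            letters = list(string.ascii_uppercase) + [
                "A" + c for c in string.ascii_uppercase
            ]
            return [f"{letters[r]}{c + 1:02d}" for r in range(rows) for c in range(cols)]
    return [f"W{i + 1:03d}" for i in range(n_wells)]


def plate_layout(config: SimulationConfig, genes: list[str]) -> pd.DataFrame:
    """Assign genes and controls to (plate, well) positions.

    Genes fill plates sequentially in library order; each plate carries
    ``n_sinc_per_plate`` siNC and ``n_siplk1_per_plate`` siPLK1 wells at fixed
    positions (the final wells of the plate). No positional bias is modeled.
    """
    wells = _well_labels(config.wells_per_plate)
    per_plate = config.library_wells_per_plate
    n_plates = -(-len(genes) // per_plate)
    rows = []
    for p in range(n_plates):
        plate = f"P{p + 1:03d}"
        chunk = genes[p * per_plate:(p + 1) * per_plate]
        labels = list(chunk)
        labels += [NEGATIVE_CONTROL] * config.n_sinc_per_plate
        labels += [POSITIVE_CONTROL] * config.n_siplk1_per_plate
        for well, label in zip(wells, labels):
            rows.append((plate, well, label))
    return pd.DataFrame(rows, columns=["plate", "well", "gene_id"])


def default_layout(config: SimulationConfig) -> list[tuple[str, str]]:
    """The campaign's (cell_line, readout) panels.

    2D lines get a cell-count screen; the first two 2D lines additionally get a
    total-viability screen (viability was multiplexed in a subset of lines);
    3D lines get a sphere-count screen.
    """
    layout = [(ln, "count2d") for ln in config.cell_lines_2d]
    layout += [(ln, "viability2d") for ln in config.cell_lines_2d[:2]]
    layout += [(ln, "sphere3d") for ln in config.cell_lines_3d]
    return layout


def simulate_campaign(
    config: SimulationConfig,
    truth: TruthTable,
    layout_readouts: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Simulate raw per-well readouts for every requested (cell_line, readout).

    Raw values follow ``baseline * 2**(effect + noise)`` with Gaussian log2
    noise; total viability is the count raw value times
    ``2**(per-cell effect + noise)``; sphere counts are Poisson draws whose
    log2 mean carries the planted effect (or the continuous mean itself in
    ``sphere_noise="lognormal"`` mode). siNC wells carry effect 0, siPLK1
    wells ``positive_control_effect``. Deterministic given ``config.seed``.
    """
    config.validate()
    if layout_readouts is None:
        layout_readouts = default_layout(config)
    genes = truth.genes()
    if len(genes) != config.n_genes:
        raise ConfigError(
            f"truth table covers {len(genes)} genes but config declares {config.n_genes}"
        )
    known_pairs = set(default_layout(config)) | {
        (ln, "viability2d") for ln in config.cell_lines_2d
    }
    for pair in layout_readouts:
        if pair not in known_pairs:
            raise ConfigError(f"readout/cell-line pair {pair} not available in this config")

    rng = _screen_rng(config)
    layout = plate_layout(config, genes)
    n_wells = len(layout)
    gene_labels = layout["gene_id"].to_numpy()
    is_sinc = gene_labels == NEGATIVE_CONTROL
    is_plk1 = gene_labels == POSITIVE_CONTROL

    def planted(line: str, kind: str) -> np.ndarray:
        eff = np.zeros(n_wells)
        if kind == "count2d":
            eff[:] = [
                0.0 if (s or p) else truth[g].count_effect_2d.get(line, 0.0)
                for g, s, p in zip(gene_labels, is_sinc, is_plk1)
            ]
        elif kind == "per_cell":
            eff[:] = [
                0.0 if (s or p) else truth[g].viability_per_cell_effect
                for g, s, p in zip(gene_labels, is_sinc, is_plk1)
            ]
        else:
            eff[:] = [
                0.0 if (s or p) else truth[g].sphere_effect_3d.get(line, 0.0)
                for g, s, p in zip(gene_labels, is_sinc, is_plk1)
            ]
        if kind != "per_cell":
            eff[is_plk1] = config.positive_control_effect
        return eff

    # Deterministic simulation order: count2d before viability2d within a line
    # so the viability panel reuses the same realized count values.
    requested = list(dict.fromkeys(layout_readouts))
    order = {"count2d": 0, "viability2d": 1, "sphere3d": 2}
    requested.sort(key=lambda cr: (cr[0], order[cr[1]]))

    frames = []
    count_cache: dict[str, np.ndarray] = {}

    def ensure_counts(line: str) -> np.ndarray:
        """Realized 2D count values per replicate for a line (generated once)."""
        if line not in count_cache:
            eff = planted(line, "count2d")
            counts = np.empty((config.n_replicates, n_wells))
            for r in range(config.n_replicates):
                noise = rng.normal(0.0, config.noise_sd_2d, n_wells)
                counts[r] = config.baseline_count * np.exp2(eff + noise)
            count_cache[line] = counts
        return count_cache[line]

    for line, readout in requested:
        for rep in range(1, config.n_replicates + 1):
            if readout == "count2d":
                raw = ensure_counts(line)[rep - 1]
            elif readout == "viability2d":
                eff = planted(line, "per_cell")
                noise = rng.normal(0.0, config.noise_sd_2d, n_wells)
                raw = ensure_counts(line)[rep - 1] * np.exp2(eff + noise)
            else:
                eff = planted(line, "sphere3d")
                noise = rng.normal(0.0, config.noise_sd_3d, n_wells)
                lam = config.baseline_sphere_count * np.exp2(eff + noise)
                raw = rng.poisson(lam).astype(float) if config.sphere_noise == "poisson" else lam
            frames.append(
                pd.DataFrame(
                    {
                        "cell_line": line,
                        "readout": readout,
                        "plate": layout["plate"],
                        "well": layout["well"],
                        "gene_id": gene_labels,
                        "replicate": rep,
                        "raw_value": raw,
                    }
                )
            )
    screen = pd.concat(frames, ignore_index=True)
    # Drop panels simulated only to support a derived readout (count2d backing
    # a viability2d request) when the caller did not ask for them.
    wanted = pd.MultiIndex.from_tuples(layout_readouts)
    mask = pd.MultiIndex.from_frame(screen[["cell_line", "readout"]]).isin(wanted)
    return screen.loc[mask].reset_index(drop=True)


def simulate_annotation(
    truth: TruthTable,
    config: SimulationConfig,
    n_sets_per_class: int = 3,
    set_size: int = 40,
    purity: float = 0.7,
    n_background_sets: int = 10,
) -> dict[str, tuple[str, tuple[str, ...]]]:
    """A synthetic gene-set annotation statistically coupled to effect class.

    For each non-neutral effect class, ``n_sets_per_class`` gene sets draw a
    fraction ``purity`` of their members from that class (with replacement
    across sets, without within a set) and the rest from the whole library;
    ``n_background_sets`` additional sets are drawn uniformly. The result maps
    set name -> (description, members) and serializes as GMT.
    """
    rng = _annotation_rng(config)
    genes = np.array(truth.genes())
    collection: dict[str, tuple[str, tuple[str, ...]]] = {}
    for label in EFFECT_CLASSES:
        if label == "neutral":
            continue
        members_pool = np.array(truth.genes_in_class(label))
        if members_pool.size == 0:
            continue
        for i in range(n_sets_per_class):
            n_core = min(int(round(purity * set_size)), members_pool.size)
            core = rng.choice(members_pool, size=n_core, replace=False)
            n_bg = set_size - n_core
            bg = rng.choice(genes, size=n_bg, replace=False) if n_bg else np.array([], dtype=genes.dtype)
            members = tuple(dict.fromkeys([*core.tolist(), *bg.tolist()]))
            name = f"{label.upper()}_SET_{i + 1}"
            collection[name] = (f"synthetic set coupled to {label}", members)
    for i in range(n_background_sets):
        members = tuple(rng.choice(genes, size=min(set_size, genes.size), replace=False).tolist())
        collection[f"BACKGROUND_SET_{i + 1}"] = ("synthetic background set", members)
    return collection
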