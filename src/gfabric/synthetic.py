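"""Synthetic replica-structured, spot-redundant expression data with planted truth.

The generator emulates a four-condition (heart-chamber), four-replica
two-color microarray experiment: each gene is probed by 1-13 redundant
spots, gene baseline means follow a median-normalized log-normal law,
biological replicas fluctuate with a per-gene coefficient of variation,
and each spot adds independent technical noise. Three kinds of ground
truth can be planted:

* differential expression — a chamber's mean is multiplied by a fold;
* coordination modules — genes in a module share one latent animal
  factor per chamber, so every same-module pair has log-scale
  correlation loading^2 (equicorrelation);
* synchrony — one gene shares a latent animal factor across two
  chambers.

On the log2 scale a gene's replica value is

    log2 m_ic + sigma_i * ( loading * F_jc + sqrt(1 - loading^2) * z_icj )

with F the shared factor and z independent noise. Foreground and
background fluorescence columns are synthesized so that a configurable
fraction of spots violates the foreground >= 2x background quality rule
in one random sample. Identical seeds give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gfabric.io_model import (
    CANONICAL_FIELDS,
    FormatError,
    write_measurements,
    write_table,
)

#: redundancy law loosely matching a 4x44K design: most transcripts single-spot
DEFAULT_REDUNDANCY_WEIGHTS = {1: 0.75, 2: 0.12, 3: 0.08, 4: 0.03, 5: 0.01, 13: 0.01}

#: raw fluorescence counts corresponding to normalized expression 1
RAW_SCALE = 1000.0


@dataclass(frozen=True)
class PlantedFold:
    """One planted differential-expression event: fold on `chamber_target`."""

    gene: str
    chamber_ref: str
    chamber_target: str
    fold: float
    direction: str = "up"  # "up" or "down" in the target chamber

    def __post_init__(self):
        if self.fold < 1:
            raise FormatError("planted fold must be >= 1")
        if self.direction not in ("up", "down"):
            raise FormatError("direction must be 'up' or 'down'")


@dataclass(frozen=True)
class PlantedModule:
    """A coordination module: genes sharing a latent factor in one chamber."""

    name: str
    genes: tuple[str, ...]
    chamber: str
    loading: float
    signs: tuple[int, ...] | None = None  # +1/-1 per gene; default all +1

    def __post_init__(self):
        if not 0.0 <= self.loading <= 1.0:
            raise FormatError("loading must be in [0, 1]")
        if self.signs is not None and len(self.signs) != len(self.genes):
            raise FormatError("signs must match genes in length")


@dataclass(frozen=True)
class PlantedSynchrony:
    """A gene sharing a latent animal factor across two chambers."""

    gene: str
    chamber_a: str
    chamber_b: str
    loading: float

    def __post_init__(self):
        if not 0.0 <= self.loading <= 1.0:
            raise FormatError("loading must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic four-chamber experiment."""

    n_genes: int = 2000
    redundancy_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_REDUNDANCY_WEIGHTS)
    )
    chambers: tuple[str, ...] = ("LA", "RA", "LV", "RV")
    n_replicas: int = 4
    baseline_sigma_log2: float = 2.0  # spread of gene means; median gene = 1
    bio_cv_range: tuple[float, float] = (0.10, 0.50)
    tech_cv: float = 0.05
    planted_de: list[PlantedFold] = field(default_factory=list)
    planted_modules: list[PlantedModule] = field(default_factory=list)
    planted_synchrony: list[PlantedSynchrony] = field(default_factory=list)
    filter_violation_fraction: float = 0.02
    sample_scales: dict[str, float] | None = None  # "chamber:replica" -> factor
    seed: int = 0

    # -- round-trip through a plain-text config file ----------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chambers"] = list(self.chambers)
        d["bio_cv_range"] = list(self.bio_cv_range)
        d["planted_de"] = [dataclasses.asdict(p) for p in self.planted_de]
        d["planted_modules"] = [
            {**dataclasses.asdict(m), "genes": list(m.genes),
             "signs": list(m.signs) if m.signs is not None else None}
            for m in self.planted_modules
        ]
        d["planted_synchrony"] = [dataclasses.asdict(s) for s in self.planted_synchrony]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["chambers"] = tuple(d.get("chambers", ("LA", "RA", "LV", "RV")))
        d["bio_cv_range"] = tuple(d.get("bio_cv_range", (0.10, 0.50)))
        d["redundancy_weights"] = {
            int(k): float(v)
            for k, v in d.get("redundancy_weights", DEFAULT_REDUNDANCY_WEIGHTS).items()
        }
        d["planted_de"] = [PlantedFold(**p) for p in d.get("planted_de", [])]
        d["planted_modules"] = [
            PlantedModule(
                name=m["name"],
                genes=tuple(m["genes"]),
                chamber=m["chamber"],
                loading=m["loading"],
                signs=tuple(m["signs"]) if m.get("signs") else None,
            )
            for m in d.get("planted_modules", [])
        ]
        d["planted_synchrony"] = [
            PlantedSynchrony(**s) for s in d.get("planted_synchrony", [])
        ]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a synthetic dataset."""

    genes: pd.DataFrame        # gene, R, bio_cv, seed, mean_<chamber>...
    de: pd.DataFrame           # gene, chamber_ref, chamber_target, fold, direction
    modules: pd.DataFrame      # module, gene, chamber, loading, sign, pair_correlation
    synchrony: pd.DataFrame    # gene, chamber_a, chamber_b, loading
    removed_spots: pd.DataFrame  # spot_id, chamber, replica, reason (planted violations)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _cv_to_sigma_log2(cv: np.ndarray) -> np.ndarray:
    """Log-normal sigma (base-2 logs) implied by a linear-scale CV."""
    return np.sqrt(np.log1p(cv**2)) / math.log(2)


def generate_measurements(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the canonical measurement table and its ground truth in memory."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    chambers = list(config.chambers)
    n_ch, n_rep = len(chambers), config.n_replicas
    replicas = [str(j + 1) for j in range(n_rep)]

    for planted in config.planted_de:
        if planted.gene not in gene_pos:
            raise FormatError(f"planted DE gene {planted.gene!r} not in universe")
    for module in config.planted_modules:
        for g in module.genes:
            if g not in gene_pos:
                raise FormatError(f"module gene {g!r} not in universe")
    for sync in config.planted_synchrony:
        if sync.gene not in gene_pos:
            raise FormatError(f"synchrony gene {sync.gene!r} not in universe")

    # redundancy and baseline law
    r_choices = np.array(sorted(config.redundancy_weights), dtype=int)
    weights = np.array(
        [config.redundancy_weights[int(r)] for r in r_choices], dtype=float
    )
    weights = weights / weights.sum()
    redundancy = rng.choice(r_choices, size=config.n_genes, p=weights)
    baseline_log2 = rng.normal(0.0, config.baseline_sigma_log2, size=config.n_genes)
    lo, hi = config.bio_cv_range
    bio_cv = rng.uniform(lo, hi, size=config.n_genes) if hi > lo else np.full(
        config.n_genes, float(lo)
    )
    sigma_log2 = _cv_to_sigma_log2(bio_cv)

    # chamber means with planted folds
    mean_log2 = np.tile(baseline_log2[:, None], (1, n_ch))
    ch_pos = {c: i for i, c in enumerate(chambers)}
    for planted in config.planted_de:
        shift = math.log2(planted.fold)
        if planted.direction == "down":
            shift = -shift
        mean_log2[gene_pos[planted.gene], ch_pos[planted.chamber_target]] += shift

    # standardized biological deviates with latent-factor structure
    z = rng.standard_normal((config.n_genes, n_ch, n_rep))
    e = z.copy()
    for module in config.planted_modules:
        factor = rng.standard_normal(n_rep)
        lam = module.loading
        signs = module.signs or tuple(1 for _ in module.genes)
        c = ch_pos[module.chamber]
        for g, s in zip(module.genes, signs):
            i = gene_pos[g]
            e[i, c, :] = s * lam * factor + math.sqrt(1 - lam**2) * z[i, c, :]
    for sync in config.planted_synchrony:
        factor = rng.standard_normal(n_rep)
        lam = sync.loading
        i = gene_pos[sync.gene]
        for chamber in (sync.chamber_a, sync.chamber_b):
            c = ch_pos[chamber]
            e[i, c, :] = lam * factor + math.sqrt(1 - lam**2) * z[i, c, :]

    gene_log2 = mean_log2[:, :, None] + sigma_log2[:, None, None] * e

    # expand to spots with technical noise
    spot_gene_idx = np.repeat(np.arange(config.n_genes), redundancy)
    n_spots = len(spot_gene_idx)
    spot_ids = [
        f"{genes[i]}_s{k + 1}"
        for i in range(config.n_genes)
        for k in range(int(redundancy[i]))
    ]
    tech_sigma_ln = math.sqrt(math.log1p(config.tech_cv**2))
    tech = (
        np.exp(rng.normal(0.0, tech_sigma_ln, size=(n_spots, n_ch, n_rep)))
        if tech_sigma_ln > 0
        else np.ones((n_spots, n_ch, n_rep))
    )
    values = np.exp2(gene_log2[spot_gene_idx]) * tech  # spots x chambers x replicas

    # raw fluorescence synthesis: net = RAW_SCALE * value, background below net/1
    net = RAW_SCALE * values
    bg_frac = rng.uniform(0.05, 0.45, size=net.shape)
    background = net * bg_frac
    foreground = net + background  # foreground >= 2x background everywhere so far
    # re-derive background so foreground - background recovers net exactly
    # (both differences are exact by Sterbenz' lemma: net <= fg <= 2 net)
    background = foreground - net
    corrupted = np.zeros(net.shape, dtype=bool)

    # plant quality violations: one random offending sample per chosen spot
    n_viol = int(round(config.filter_violation_fraction * n_spots))
    removed_rows = []
    if n_viol > 0:
        viol_spots = rng.choice(n_spots, size=n_viol, replace=False)
        for idx, spot in enumerate(viol_spots):
            c = int(rng.integers(n_ch))
            j = int(rng.integers(n_rep))
            if idx % 2 == 0:
                corrupted[spot, c, j] = True
                reason = "corrupted"
            else:
                background[spot, c, j] = foreground[spot, c, j] * 0.6
                reason = "foreground<2x background"
            removed_rows.append(
                {
                    "spot_id": spot_ids[spot],
                    "chamber": chambers[c],
                    "replica": replicas[j],
                    "reason": reason,
                }
            )

    # per-sample multiplicative scale factors (inverted by normalization)
    scales = np.ones((n_ch, n_rep))
    if config.sample_scales:
        for key, factor in config.sample_scales.items():
            chamber, replica = key.split(":")
            scales[ch_pos[chamber], replicas.index(replica)] = float(factor)
    foreground = foreground * scales[None, :, :]
    background = background * scales[None, :, :]

    # long-format canonical table, fixed row order: spot-major, chamber, replica
    rows = n_spots * n_ch * n_rep
    measurements = pd.DataFrame(
        {
            "spot_id": np.repeat(np.array(spot_ids, dtype=object), n_ch * n_rep),
            "gene": np.repeat(
                np.array([genes[i] for i in spot_gene_idx], dtype=object), n_ch * n_rep
            ),
            "chamber": np.tile(np.repeat(np.array(chambers, dtype=object), n_rep), n_spots),
            "replica": np.tile(np.array(replicas, dtype=object), n_spots * n_ch),
            "foreground": foreground.reshape(rows),
            "background": background.reshape(rows),
            "corrupted": corrupted.reshape(rows),
        },
        columns=list(CANONICAL_FIELDS),
    )

    truth_genes = pd.DataFrame(
        {
            "gene": genes,
            "R": redundancy,
            "bio_cv": bio_cv,
            "seed": config.seed,
            **{
                f"mean_{c}": np.exp2(mean_log2[:, ch_pos[c]]) for c in chambers
            },
        }
    )
    truth_de = pd.DataFrame(
        [dataclasses.asdict(p) for p in config.planted_de],
        columns=["gene", "chamber_ref", "chamber_target", "fold", "direction"],
    )
    module_rows = []
    for module in config.planted_modules:
        signs = module.signs or tuple(1 for _ in module.genes)
        for g, s in zip(module.genes, signs):
            module_rows.append(
                {
                    "module": module.name,
                    "gene": g,
                    "chamber": module.chamber,
                    "loading": module.loading,
                    "sign": s,
                    "pair_correlation": module.loading**2,
                }
            )
    truth_modules = pd.DataFrame(
        module_rows,
        columns=["module", "gene", "chamber", "loading", "sign", "pair_correlation"],
    )
    truth_sync = pd.DataFrame(
        [dataclasses.asdict(s) for s in config.planted_synchrony],
        columns=["gene", "chamber_a", "chamber_b", "loading"],
    )
    truth = GroundTruth(
        genes=truth_genes,
        de=truth_de,
        modules=truth_modules,
        synchrony=truth_sync,
        removed_spots=pd.DataFrame(
            removed_rows, columns=["spot_id", "chamber", "replica", "reason"]
        ),
    )
    return measurements, truth


def generate(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a dataset on disk: expression table, truth tables, config copy.

    Emits the exact tabular dialect :func:`gfabric.io_model.read_expression_table`
    consumes. Identical configs (including seed) produce byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    measurements, truth = generate_measurements(config)
    paths = {
        "expression": outdir / "expression.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_de": outdir / "truth_de.tsv",
        "truth_modules": outdir / "truth_modules.tsv",
        "truth_synchrony": outdir / "truth_synchrony.tsv",
        "removed_spots": outdir / "truth_removed_spots.tsv",
        "config": outdir / "config.yaml",
    }
    write_measurements(measurements, paths["expression"])
    write_table(truth.genes, paths["truth_genes"])
    write_table(truth.de, paths["truth_de"])
    write_table(truth.modules, paths["truth_modules"])
    write_table(truth.synchrony, paths["truth_synchrony"])
    write_table(truth.removed_spots, paths["removed_spots"])
    config.to_yaml(paths["config"])
    return paths
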