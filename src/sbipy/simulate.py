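"""Synthetic field-study generator with known ground truth.

Emulates a potato field survey: 13 fields x 4 plots (one plot lost, 51
samples), sand-to-loam soil textures, total C/N and pH in agronomic ranges,
one daily weather series per field, and a ~2000-ASV bacterial count table
produced by multinomial sampling of log-normal relative abundances at a mean
depth of ~18000 reads per sample.

The causal sketch mirrors the study design: a latent per-sample microbial
signal ``m`` shifts the log-abundance of a planted subset of ASVs (positive
or negative) and adds to yield on top of soil-texture effects, so that after
environmental detrending the residual yield carries the microbial signal the
screen is supposed to recover. Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .composition import SOIL_PARTITION, close, ilr_all
from .errors import ConfigError

__all__ = ["SimulationConfig", "SyntheticDataset", "GroundTruth",
           "simulate_dataset", "ground_truth"]

# texture centroids as (clay, silt, sand) mineral fractions
_TEXTURE_CENTROIDS = {
    "sand": (0.04, 0.08, 0.88),
    "loamy_sand": (0.07, 0.13, 0.80),
    "sandy_loam": (0.11, 0.24, 0.65),
    "loam": (0.17, 0.38, 0.45),
}

# per-field texture classes patterned on a sand-dominated potato survey
_FIELD_CLASSES = (
    "sand", "sandy_loam", "sand", "sandy_loam", "loam", "sand", "loamy_sand",
    "loamy_sand", "sand", "loamy_sand", "loamy_sand", "loamy_sand", "loamy_sand",
)

_PHYLA = (
    ("Proteobacteria", 0.29), ("Actinobacteria", 0.17), ("Acidobacteria", 0.12),
    ("Chloroflexi", 0.08), ("Bacteroidetes", 0.07), ("Gemmatimonadetes", 0.05),
    ("Verrucomicrobia", 0.05), ("Firmicutes", 0.04), ("Planctomycetes", 0.04),
    ("Nitrospirae", 0.02), ("Saccharibacteria", 0.02), ("Armatimonadetes", 0.01),
    ("Crenarchaeota", 0.02), ("Other", 0.02),
)


def _default_texture_effects() -> Mapping[str, float]:
    return MappingProxyType({
        "[Clay | Silt, Sand]": -4.0,
        "[Silt | Sand]": -3.0,
    })


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic survey; the seed is mandatory.

    texture_effects are yield slopes (t/ha per standard deviation) on the
    named soil balances; microbial_effect_sd is the standard deviation (t/ha)
    of the latent microbial yield component; asv_effect_size is the
    log-abundance shift of a planted ASV per standard deviation of that
    latent signal.
    """

    seed: int
    n_fields: int = 13
    plots_per_field: int = 4
    drop_one_plot: bool = True          # one mishandled plot: 51 of 52 samples
    n_asvs: int = 2000
    n_positive_planted: int = 30
    n_negative_planted: int = 20
    texture_effects: Mapping[str, float] = field(default_factory=_default_texture_effects)
    microbial_effect_sd: float = 3.0
    yield_noise_sd: float = 3.0
    asv_effect_size: float = 1.0
    asv_noise_sd: float = 0.35
    sequencing_depth: float = 18000.0
    zero_inflation: float = 0.0
    base_yield: float = 35.0
    season_days: int = 120
    season_start: str = "2013-05-15"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_fields < 1 or self.plots_per_field < 1:
            raise ConfigError("need at least one field and one plot per field")
        if self.n_positive_planted + self.n_negative_planted > self.n_asvs:
            raise ConfigError("planted ASVs exceed n_asvs")
        if self.n_asvs < 2:
            raise ConfigError("need at least 2 ASVs")
        if self.sequencing_depth <= 0:
            raise ConfigError("sequencing depth must be positive")
        if not 0 <= self.zero_inflation < 1:
            raise ConfigError("zero_inflation must be in [0, 1)")
        if self.microbial_effect_sd < 0 or self.yield_noise_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        if self.season_days < 2:
            raise ConfigError("season must cover at least 2 days")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: selected-ASV truth and true yield structure."""

    positive_asvs: tuple
    negative_asvs: tuple
    texture_effects: dict
    microbial_component: pd.Series   # t/ha per sample, adds to yield
    base_yield: float


@dataclass(frozen=True)
class SyntheticDataset:
    """One simulated survey: counts, metadata, weather, taxonomy and the truth."""

    feature_table: pd.DataFrame      # samples x ASVs, integer counts
    metadata: pd.DataFrame           # soil, pH, field id, yield per sample
    weather: pd.DataFrame            # long daily table per field
    taxonomy: pd.Series              # asv_id -> phylum
    truth: GroundTruth
    config: SimulationConfig


def _simulate_soil(rng, fields, samples, sample_field):
    """Per-plot texture (mineral fractions), total C %, N % and pH."""
    field_class = {f: _FIELD_CLASSES[i % len(_FIELD_CLASSES)]
                   for i, f in enumerate(fields)}
    field_shift = {f: rng.normal(0.0, 0.15, size=3) for f in fields}
    field_c = {f: rng.uniform(1.3, 2.8) for f in fields}
    field_ph = {f: rng.uniform(4.6, 6.2) for f in fields}

    rows = []
    for sid in samples:
        f = sample_field[sid]
        centroid = np.log(_TEXTURE_CENTROIDS[field_class[f]])
        logtex = centroid + field_shift[f] + rng.normal(0.0, 0.08, size=3)
        tex = np.exp(logtex)
        tex = tex / tex.sum()
        c_pct = float(np.clip(field_c[f] * np.exp(rng.normal(0.0, 0.12)), 0.8, 3.5))
        n_pct = float(np.clip(c_pct / rng.normal(13.0, 1.5), 0.03, 0.30))
        ph = float(np.clip(field_ph[f] + rng.normal(0.0, 0.2), 4.3, 7.4))
        rows.append({"field_id": f, "clay_pct": 100 * tex[0], "silt_pct": 100 * tex[1],
                     "sand_pct": 100 * tex[2], "c_pct": c_pct, "n_pct": n_pct, "pH": ph})
    soil = pd.DataFrame(rows, index=pd.Index(samples, name="sample_id"))
    return soil


def _simulate_weather(rng, fields, cfg: SimulationConfig) -> pd.DataFrame:
    dates = pd.date_range(cfg.season_start, periods=cfg.season_days, freq="D")
    t = np.arange(cfg.season_days)
    frames = []
    for f in fields:
        wet_prob = rng.uniform(0.35, 0.6)
        rain_scale = rng.uniform(5.0, 9.0)
        wet = rng.random(cfg.season_days) < wet_prob
        rain = np.where(wet, rng.gamma(0.9, rain_scale, size=cfg.season_days), 0.0)
        if rain.sum() == 0:  # a fully dry season never happens; force one shower
            rain[rng.integers(cfg.season_days)] = rain_scale
        temp = (8.0 + 11.0 * np.sin(np.pi * t / (cfg.season_days - 1))
                + rng.normal(0.0, 1.0) + rng.normal(0.0, 2.2, size=cfg.season_days))
        frames.append(pd.DataFrame({
            "field_id": f,
            "date": dates.strftime("%Y-%m-%d"),
            "rain_mm": np.round(rain, 2),
            "tmean_c": np.round(temp, 2),
        }))
    return pd.concat(frames, ignore_index=True)


def soil_composition(metadata: pd.DataFrame) -> pd.DataFrame:
    """Five-part soil simplex (Clay, Silt, Sand, N, C) closed from metadata.

    Mineral fractions take up the mass not held by total C and N, so the five
    parts live on one simplex as in the balance partition.
    """
    mineral = 100.0 - metadata["c_pct"] - metadata["n_pct"]
    tex_sum = metadata[["clay_pct", "silt_pct", "sand_pct"]].sum(axis=1)
    parts = pd.DataFrame({
        "Clay": metadata["clay_pct"] / tex_sum * mineral,
        "Silt": metadata["silt_pct"] / tex_sum * mineral,
        "Sand": metadata["sand_pct"] / tex_sum * mineral,
        "N": metadata["n_pct"],
        "C": metadata["c_pct"],
    }, index=metadata.index)
    return close(parts)


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Draw one complete survey from the configured generative model."""
    rng = np.random.default_rng(cfg.seed)

    fields = [f"F{i + 1:02d}" for i in range(cfg.n_fields)]
    samples, sample_field = [], {}
    for f in fields:
        for p in range(cfg.plots_per_field):
            sid = f"{f}_P{p + 1}"
            samples.append(sid)
            sample_field[sid] = f
    if cfg.drop_one_plot and len(samples) > 1:
        # one mishandled plot, by convention the last plot of the 12th field
        lost_field = fields[min(11, cfg.n_fields - 1)]
        lost = f"{lost_field}_P{cfg.plots_per_field}"
        samples.remove(lost)
    n = len(samples)

    soil = _simulate_soil(rng, fields, samples, sample_field)
    weather = _simulate_weather(rng, fields, cfg)

    # latent microbial yield component: field-level + plot-level variation
    if cfg.microbial_effect_sd > 0:
        field_part = {f: rng.normal(0.0, 0.6) for f in fields}
        z = np.array([field_part[sample_field[s]] for s in samples])
        z = z + rng.normal(0.0, 0.8, size=n)
        z = (z - z.mean()) / z.std(ddof=0)
        m = cfg.microbial_effect_sd * z
    else:
        z = np.zeros(n)
        m = np.zeros(n)
    m = pd.Series(m, index=soil.index, name="microbial_component")

    # ASV community: log-normal baselines; planted ASVs ride the latent signal
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(cfg.n_asvs)]
    planted = rng.choice(cfg.n_asvs, size=cfg.n_positive_planted + cfg.n_negative_planted,
                         replace=False)
    pos_idx = np.sort(planted[: cfg.n_positive_planted])
    neg_idx = np.sort(planted[cfg.n_positive_planted:])
    eta = rng.normal(0.0, 1.5, size=cfg.n_asvs)
    # planted ASVs get moderately abundant baselines so they are observable
    eta[planted] = rng.normal(1.0, 0.8, size=planted.size)
    b = np.zeros(cfg.n_asvs)
    b[pos_idx] = cfg.asv_effect_size
    b[neg_idx] = -cfg.asv_effect_size

    logab = (eta[None, :] + np.outer(z, b)
             + rng.normal(0.0, cfg.asv_noise_sd, size=(n, cfg.n_asvs)))
    rel = np.exp(logab - logab.max(axis=1, keepdims=True))
    if cfg.zero_inflation > 0:
        rel = rel * (rng.random(rel.shape) >= cfg.zero_inflation)
        rel[rel.sum(axis=1) == 0, 0] = 1.0
    rel = rel / rel.sum(axis=1, keepdims=True)
    depth = rng.poisson(cfg.sequencing_depth, size=n)
    depth = np.maximum(depth, 1)
    counts = np.vstack([rng.multinomial(depth[j], rel[j]) for j in range(n)])
    feature_table = pd.DataFrame(counts, index=soil.index, columns=asv_ids)

    # yield: soil-texture balances + latent microbial component + noise
    balances = ilr_all(soil_composition(soil), SOIL_PARTITION)
    zbal = (balances - balances.mean()) / balances.std(ddof=1)
    effect = sum(cfg.texture_effects.get(c, 0.0) * zbal[c] for c in zbal.columns)
    noise = rng.normal(0.0, cfg.yield_noise_sd, size=n) if cfg.yield_noise_sd > 0 else 0.0
    yield_tha = cfg.base_yield + effect + m + noise
    metadata = soil.assign(yield_tha=np.asarray(yield_tha, dtype=float))

    phyla = [p for p, _ in _PHYLA]
    probs = np.array([w for _, w in _PHYLA])
    taxonomy = pd.Series(rng.choice(phyla, p=probs / probs.sum(), size=cfg.n_asvs),
                         index=pd.Index(asv_ids, name="asv_id"), name="phylum")

    truth = GroundTruth(
        positive_asvs=tuple(asv_ids[i] for i in pos_idx),
        negative_asvs=tuple(asv_ids[i] for i in neg_idx),
        texture_effects=dict(cfg.texture_effects),
        microbial_component=m,
        base_yield=cfg.base_yield,
    )
    return SyntheticDataset(feature_table=feature_table, metadata=metadata,
                            weather=weather, taxonomy=taxonomy, truth=truth,
                            config=cfg)


def ground_truth(ds: SyntheticDataset) -> GroundTruth:
    """The planted sets and true parameters of a simulated survey."""
    return ds.truth


def null_config(cfg: SimulationConfig) -> SimulationConfig:
    """The same survey with no planted microbial signal (for calibration runs)."""
    return replace(cfg, n_positive_planted=0, n_negative_planted=0,
                   microbial_effect_sd=0.0)
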