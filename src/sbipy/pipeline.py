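"""Table IO, configuration and the orchestrated end-to-end run.

The pipeline order is: weather indices -> soil ilr balances -> predictor
standardization -> yield model -> residual yield -> feature filter -> zero
imputation -> clr -> correlation screen -> signed selection -> SBI ->
alpha diversity -> index correlations -> RDA -> SBI trend surface. Every
intermediate table is written as UTF-8 TSV with a ``#``-prefixed provenance
header (config hash and seed), so two runs with identical config and seed
produce byte-identical output trees.

Sample id is the join key everywhere; tables are normalized to lexicographic
sample order on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition, detrend, diversity, ordination, screen, weather
from .errors import EmptyTableError, ParseError, SbipyError, SbiUndefinedError
from .simulate import SyntheticDataset, soil_composition

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_feature_table",
    "read_metadata",
    "read_weather",
    "read_taxonomy",
    "write_tsv",
    "write_dataset",
    "run_pipeline",
    "run_pipeline_frames",
]

logger = logging.getLogger(__name__)

_METADATA_COLS = {"field_id", "clay_pct", "silt_pct", "sand_pct",
                  "c_pct", "n_pct", "pH", "yield_tha"}


@dataclass(frozen=True)
class PipelineConfig:
    """File locations and the analysis knobs of one pipeline run."""

    feature_table: str
    metadata: str
    weather: str
    out_dir: str
    taxonomy: str | None = None
    alpha: float = 0.05
    min_samples: int = 2
    filter_mode: str = "presence"
    correlation_method: str = "pearson"
    sbi_normalized: bool = True
    delta_fraction: float = 0.65
    weather_start: str | None = None
    weather_end: str | None = None
    conventional_gdd: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def config_hash(self) -> str:
        """Hash of the analysis knobs only, so file locations don't matter."""
        knobs = {k: v for k, v in asdict(self).items()
                 if k not in ("feature_table", "metadata", "weather",
                              "taxonomy", "out_dir")}
        payload = json.dumps(knobs, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# readers / writers


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc


def read_feature_table(path) -> pd.DataFrame:
    """Read a samples x ASVs count table (TSV, first column sample ids).

    Sparse long format (columns sample_id, asv_id, count) is accepted and
    pivoted to dense. Validates non-negative integer counts and unique ids.
    """
    df = _read_tsv(path)
    if df.empty:
        raise EmptyTableError(f"{path}: empty feature table")
    if set(df.columns[:3]) >= {"sample_id", "asv_id", "count"}:
        df = (df.pivot_table(index="sample_id", columns="asv_id", values="count",
                             fill_value=0, aggfunc="sum"))
    else:
        df = df.set_index(df.columns[0])
        df.index.name = "sample_id"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids {dupes[:5]}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate ASV ids {dupes[:5]}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError(f"{path}: non-numeric counts")
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise ParseError(
            f"{path}: negative count at sample {df.index[i]!r}, ASV {df.columns[j]!r}"
        )
    if not np.allclose(arr, np.round(arr)):
        raise ParseError(f"{path}: counts must be integers")
    if df.shape[0] < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    return df.astype(np.int64).sort_index()


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (field id, texture %, C %, N %, pH, yield)."""
    df = _read_tsv(path, index_col=0)
    df.index.name = "sample_id"
    missing = _METADATA_COLS - set(df.columns)
    if missing:
        raise ParseError(f"{path}: metadata missing columns {sorted(missing)}")
    return df.sort_index()


def read_weather(path) -> pd.DataFrame:
    """Read the long-format daily weather table."""
    df = _read_tsv(path)
    missing = {"field_id", "date", "rain_mm", "tmean_c"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: weather table missing columns {sorted(missing)}")
    return df


def read_taxonomy(path) -> pd.Series:
    """Read an asv_id -> phylum map."""
    df = _read_tsv(path)
    missing = {"asv_id", "phylum"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: taxonomy missing columns {sorted(missing)}")
    return df.set_index("asv_id")["phylum"]


def write_tsv(frame: pd.DataFrame | pd.Series, path, provenance: dict | None = None):
    """Write a table as TSV with optional ``#``-prefixed provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(frame, pd.Series):
        frame = frame.to_frame()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if provenance:
            items = " ".join(f"{k}={v}" for k, v in sorted(provenance.items()))
            fh.write(f"# sbipy {items}\n")
        frame.to_csv(fh, sep="\t", float_format="%.10g", lineterminator="\n")


def write_dataset(ds: SyntheticDataset, out_dir) -> dict:
    """Write a synthetic survey as the pipeline's four input files (+ truth)."""
    out = Path(out_dir)
    prov = {"seed": ds.config.seed, "source": "synthetic"}
    paths = {
        "feature_table": out / "feature_table.tsv",
        "metadata": out / "metadata.tsv",
        "weather": out / "weather.tsv",
        "taxonomy": out / "taxonomy.tsv",
    }
    write_tsv(ds.feature_table, paths["feature_table"], prov)
    write_tsv(ds.metadata, paths["metadata"], prov)
    out.mkdir(parents=True, exist_ok=True)
    with open(paths["weather"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# sbipy seed={ds.config.seed} source=synthetic\n")
        ds.weather.to_csv(fh, sep="\t", index=False, float_format="%.10g",
                          lineterminator="\n")
    write_tsv(ds.taxonomy, paths["taxonomy"], prov)
    truth = pd.DataFrame({
        "asv_id": list(ds.truth.positive_asvs) + list(ds.truth.negative_asvs),
        "planted_sign": ["+"] * len(ds.truth.positive_asvs)
                        + ["-"] * len(ds.truth.negative_asvs),
    }).set_index("asv_id")
    write_tsv(truth, out / "ground_truth.tsv", prov)
    write_tsv(ds.truth.microbial_component, out / "ground_truth_microbial.tsv", prov)
    return {k: str(v) for k, v in paths.items()}


# --------------------------------------------------------------------------
# orchestration


@dataclass
class PipelineResult:
    """All stage outputs of one run, as in-memory frames."""

    weather_indices: pd.DataFrame
    soil_balances: pd.DataFrame
    predictors: pd.DataFrame
    yield_model: detrend.YieldModelResult
    residual_yield: pd.Series
    filtered_counts: pd.DataFrame
    imputed: pd.DataFrame
    clr_table: pd.DataFrame
    correlations: pd.DataFrame
    sbi: screen.SbiResult
    diversity: pd.DataFrame
    index_correlations: pd.DataFrame
    rda: ordination.RdaResult
    sbi_surface: pd.DataFrame
    phylum_tally: pd.DataFrame | None = None
    stage_log: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SbipyError as exc:
                raise type(exc)(f"[stage:{name}] {exc}") from exc
        return wrapped
    return deco


def run_pipeline_frames(feature_table: pd.DataFrame, metadata: pd.DataFrame,
                        daily_weather: pd.DataFrame,
                        taxonomy: pd.Series | None = None,
                        cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on in-memory tables; see module docstring for the order."""
    if cfg is None:
        cfg = PipelineConfig(feature_table="-", metadata="-", weather="-", out_dir="-")
    log: dict = {}

    feature_table = feature_table.sort_index()
    metadata = metadata.sort_index()
    if not feature_table.index.equals(metadata.index):
        raise ParseError("feature table and metadata sample ids differ")

    widx = _stage("weather")(weather.weather_indices_by_field)(
        daily_weather, cfg.weather_start, cfg.weather_end, cfg.conventional_gdd)

    soil = _stage("soil_balances")(soil_composition)(metadata)
    balances = _stage("soil_balances")(composition.ilr_all)(
        soil, composition.SOIL_PARTITION)

    merged = balances.join(metadata[["pH", "field_id"]])
    merged = merged.join(widx, on="field_id").drop(columns="field_id")
    predictors = _stage("standardize")(detrend.standardize)(merged)

    model = _stage("yield_model")(detrend.fit_yield_model)(
        predictors, metadata["yield_tha"], alpha=cfg.alpha)
    residual = model.residuals
    log["r_squared"] = model.r_squared

    filtered = _stage("filter")(screen.filter_features)(
        feature_table, cfg.min_samples, cfg.filter_mode)
    log["asvs_in"] = feature_table.shape[1]
    log["asvs_after_filter"] = filtered.shape[1]
    logger.info("contingency filter: %d -> %d ASVs",
                log["asvs_in"], log["asvs_after_filter"])

    imputed = _stage("impute")(composition.impute_zeros)(filtered, cfg.delta_fraction)
    clr_table = _stage("clr")(composition.clr_transform)(imputed)

    correlations = _stage("correlate")(screen.correlate_asvs)(
        clr_table, residual, cfg.alpha, cfg.correlation_method)
    pos, neg = screen.select_significant(correlations, cfg.alpha)
    log["n_positive"] = len(pos)
    log["n_negative"] = len(neg)
    logger.info("selected %d positive and %d negative ASVs of %d",
                len(pos), len(neg), filtered.shape[1])

    sbi = _stage("sbi")(screen.compute_sbi)(imputed, pos, neg, cfg.sbi_normalized)

    profiles = _stage("diversity")(diversity.diversity_profile)(feature_table)
    idx_corr = _stage("diversity")(diversity.correlate_indices)(
        profiles, sbi.sbi, metadata["yield_tha"], residual)

    rda = _stage("rda")(ordination.fit_rda)(clr_table, predictors)
    surface = _stage("rda")(ordination.project_index)(rda, sbi.sbi)

    tally = None
    if taxonomy is not None:
        tally = screen.tally_by_phylum(pos, neg, taxonomy)

    return PipelineResult(
        weather_indices=widx, soil_balances=balances, predictors=predictors,
        yield_model=model, residual_yield=residual, filtered_counts=filtered,
        imputed=imputed, clr_table=clr_table, correlations=correlations,
        sbi=sbi, diversity=profiles, index_correlations=idx_corr,
        rda=rda, sbi_surface=surface, phylum_tally=tally, stage_log=log,
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Read the configured inputs, run every stage, write all artifacts.

    On an empty positive or negative selection, the correlation table is
    still written before :class:`SbiUndefinedError` propagates.
    """
    feature_table = read_feature_table(cfg.feature_table)
    metadata = read_metadata(cfg.metadata)
    daily = read_weather(cfg.weather)
    taxonomy = read_taxonomy(cfg.taxonomy) if cfg.taxonomy else None
    out = Path(cfg.out_dir)
    prov = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    try:
        res = run_pipeline_frames(feature_table, metadata, daily, taxonomy, cfg)
    except SbiUndefinedError:
        # still leave the screen's evidence on disk
        filtered = screen.filter_features(feature_table, cfg.min_samples, cfg.filter_mode)
        imputed = composition.impute_zeros(filtered, cfg.delta_fraction)
        clr_table = composition.clr_transform(imputed)
        soil = soil_composition(metadata)
        balances = composition.ilr_all(soil, composition.SOIL_PARTITION)
        merged = balances.join(metadata[["pH", "field_id"]])
        widx = weather.weather_indices_by_field(daily, cfg.weather_start,
                                                cfg.weather_end, cfg.conventional_gdd)
        merged = merged.join(widx, on="field_id").drop(columns="field_id")
        predictors = detrend.standardize(merged)
        model = detrend.fit_yield_model(predictors, metadata["yield_tha"], cfg.alpha)
        corr = screen.correlate_asvs(clr_table, model.residuals, cfg.alpha,
                                     cfg.correlation_method)
        write_tsv(corr, out / "asv_correlations.tsv", prov)
        raise

    write_tsv(res.weather_indices, out / "weather_indices.tsv", prov)
    write_tsv(res.soil_balances, out / "soil_balances.tsv", prov)
    write_tsv(res.predictors, out / "predictors.tsv", prov)
    write_tsv(res.yield_model.summary_frame(), out / "yield_model_coefficients.tsv", prov)
    write_tsv(res.residual_yield, out / "residual_yield.tsv", prov)
    write_tsv(res.filtered_counts, out / "filtered_feature_table.tsv", prov)
    write_tsv(res.imputed, out / "imputed_composition.tsv", prov)
    write_tsv(res.clr_table, out / "clr_table.tsv", prov)
    write_tsv(res.correlations, out / "asv_correlations.tsv", prov)
    write_tsv(res.sbi.sbi, out / "sbi.tsv", prov)
    write_tsv(res.diversity, out / "diversity.tsv", prov)
    write_tsv(res.index_correlations, out / "index_correlations.tsv", prov)
    eig = pd.DataFrame({
        "eigenvalue": np.concatenate([res.rda.constrained_eigenvalues,
                                      res.rda.unconstrained_eigenvalues]),
        "block": (["constrained"] * len(res.rda.constrained_eigenvalues)
                  + ["unconstrained"] * len(res.rda.unconstrained_eigenvalues)),
    })
    eig.index.name = "axis"
    write_tsv(eig, out / "rda_eigenvalues.tsv", prov)
    write_tsv(res.rda.site_scores, out / "rda_site_scores.tsv", prov)
    write_tsv(res.rda.species_scores, out / "rda_species_scores.tsv", prov)
    write_tsv(res.rda.biplot_scores, out / "rda_biplot_scores.tsv", prov)
    write_tsv(res.sbi_surface, out / "sbi_surface.tsv", prov)
    if res.phylum_tally is not None:
        write_tsv(res.phylum_tally, out / "phylum_tally.tsv", prov)
    sel = pd.DataFrame({
        "asv_id": list(res.sbi.positive_set) + list(res.sbi.negative_set),
        "sign": ["+"] * len(res.sbi.positive_set) + ["-"] * len(res.sbi.negative_set),
    }).set_index("asv_id")
    write_tsv(sel, out / "selected_asvs.tsv", prov)
    return res
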