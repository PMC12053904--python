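"""Synthetic seasonal metagenome time series with known ground truth.

The generator emulates the statistical structure of a decade-long
coastal monitoring series: per-taxon log10 abundance is a base level
plus categorical year and month effects plus Gaussian noise, then
exponentiated to an RPKM-like scale.  Pulse disturbances add a signed
log-scale effect to taxa of a targeted role (``susceptible`` taxa are
suppressed, ``responder`` taxa bloom) inside a date window shifted by
a configurable lag.  KO-level profiles are sparse nonnegative linear
combinations of taxa, so functional anomalies inherit taxonomic
disturbances.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd
import yaml

from .errors import UsageError
from .tables import FeatureMap, FeatureTable, make_metadata

__all__ = ["DisturbanceWindow", "SimulationConfig", "SimulationTruth",
           "simulate_taxa", "simulate_kos", "null_dataset", "simulate_dataset"]


@dataclass
class DisturbanceWindow:
    """A pulse disturbance acting on one role of taxa.

    ``effect`` is additive on the log10 scale (e.g. -1.0 is a tenfold
    suppression) and applies to samples collected in
    ``[start + lag, end + lag]``.
    """

    start: Date
    end: Date
    role: str                   # susceptible | responder
    effect: float               # log10 units, signed
    lag_days: int = 7

    def __post_init__(self):
        self.start = pd.Timestamp(self.start).date()
        self.end = pd.Timestamp(self.end).date()
        if self.end < self.start:
            raise UsageError(f"disturbance window end {self.end} before start {self.start}")
        if self.role not in ("susceptible", "responder"):
            raise UsageError(f"disturbance role must be susceptible|responder, "
                             f"got {self.role!r}")

    def active(self, when: Date) -> bool:
        lag = timedelta(days=self.lag_days)
        return self.start + lag <= when <= self.end + lag


def _default_windows(final_year: int) -> list[DisturbanceWindow]:
    # Two pulse events in the final (post) year, one month apart, each
    # suppressing susceptible taxa tenfold and boosting responders tenfold,
    # felt one week later.
    y = final_year
    return [
        DisturbanceWindow(Date(y, 10, 1), Date(y, 10, 31), "susceptible", -1.0),
        DisturbanceWindow(Date(y, 10, 1), Date(y, 10, 31), "responder", +1.0),
        DisturbanceWindow(Date(y, 12, 8), Date(y, 12, 31), "susceptible", -1.0),
        DisturbanceWindow(Date(y, 12, 8), Date(y, 12, 31), "responder", +1.0),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic community generator.

    Defaults emulate the study setting: ten baseline years plus one
    post-disturbance year sampled twice a month, lognormal taxa with
    seasonal (month) and interannual (year) structure, and two
    week-lagged pulse disturbances in the post year.
    """

    seed: int = 0
    start_year: int = 2011
    n_years: int = 11                  # last year is the post period
    samples_per_month: int = 2
    n_taxa: int = 120
    n_kos: int = 400
    n_families: int = 30
    n_modules: int = 25
    base_log_range: tuple[float, float] = (0.0, 2.0)   # log10 RPKM
    month_effect_sd: float = 0.30      # log10 scale
    year_effect_sd: float = 0.15
    noise_sd: float = 0.25
    ko_loading_sparsity: int = 3       # taxa per KO
    ko_noise_sd: float = 0.10
    fraction_susceptible: float = 0.10
    fraction_responder: float = 0.10
    #: None means "the default pulse pair in the final year"
    disturbances: list[DisturbanceWindow] | None = None

    def __post_init__(self):
        if self.disturbances is None:
            self.disturbances = _default_windows(self.start_year + self.n_years - 1)
        for name in ("month_effect_sd", "year_effect_sd", "noise_sd", "ko_noise_sd"):
            if getattr(self, name) < 0:
                raise UsageError(f"{name} must be >= 0")
        if self.fraction_susceptible + self.fraction_responder > 1:
            raise UsageError("role fractions sum to more than 1")
        span_start = Date(self.start_year, 1, 1)
        span_end = Date(self.start_year + self.n_years - 1, 12, 31)
        for w in self.disturbances:
            if w.start < span_start or w.end > span_end:
                raise UsageError(f"disturbance window {w.start}..{w.end} outside "
                                 f"simulated span {span_start}..{span_end}")

    @property
    def post_start(self) -> Date:
        return Date(self.start_year + self.n_years - 1, 1, 1)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "base_log_range" in raw:
            raw["base_log_range"] = tuple(raw["base_log_range"])
        if "disturbances" in raw:
            raw["disturbances"] = [
                w if isinstance(w, DisturbanceWindow) else DisturbanceWindow(**w)
                for w in raw["disturbances"]]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise UsageError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated dataset."""

    roles: pd.Series                     # taxon -> role
    base_log: pd.Series                  # taxon -> base log10 abundance
    year_effects: pd.DataFrame           # years x taxa
    month_effects: pd.DataFrame          # months (1..12) x taxa
    disturbance_effect: pd.DataFrame     # samples x taxa, applied log10 effect
    ko_loadings: pd.DataFrame | None = None   # kos x taxa

    @property
    def disturbance_indicator(self) -> pd.DataFrame:
        return self.disturbance_effect != 0

    def to_json(self, path) -> None:
        import json
        payload = {
            "roles": self.roles.to_dict(),
            "base_log": self.base_log.to_dict(),
            "year_effects": self.year_effects.to_dict(),
            "month_effects": self.month_effects.to_dict(),
            "disturbance_effect": self.disturbance_effect.to_dict(),
        }
        if self.ko_loadings is not None:
            payload["ko_loadings"] = self.ko_loadings.to_dict()
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _sample_dates(config: SimulationConfig) -> list[Date]:
    dates = []
    spm = config.samples_per_month
    for year in range(config.start_year, config.start_year + config.n_years):
        for month in range(1, 13):
            for s in range(spm):
                day = int(round((s + 0.5) / spm * 28))
                dates.append(Date(year, month, max(day, 1)))
    return dates


def simulate_taxa(config: SimulationConfig
                  ) -> tuple[FeatureTable, pd.DataFrame, SimulationTruth]:
    """Simulate the genus-level RPKM table, metadata, and ground truth."""
    rng = np.random.default_rng(config.seed)
    taxa = [f"g{i:04d}" for i in range(config.n_taxa)]
    years = list(range(config.start_year, config.start_year + config.n_years))
    months = list(range(1, 13))

    n_sus = int(round(config.fraction_susceptible * config.n_taxa))
    n_res = int(round(config.fraction_responder * config.n_taxa))
    roles = np.array(["neutral"] * config.n_taxa, dtype=object)
    picks = rng.choice(config.n_taxa, size=n_sus + n_res, replace=False)
    roles[picks[:n_sus]] = "susceptible"
    roles[picks[n_sus:]] = "responder"

    base = rng.uniform(*config.base_log_range, size=config.n_taxa)
    year_eff = rng.normal(0, config.year_effect_sd, size=(len(years), config.n_taxa))
    month_eff = rng.normal(0, config.month_effect_sd, size=(12, config.n_taxa))

    dates = _sample_dates(config)
    n = len(dates)
    noise = rng.normal(0, config.noise_sd, size=(n, config.n_taxa))

    year_idx = np.array([years.index(d.year) for d in dates])
    month_idx = np.array([d.month - 1 for d in dates])
    logv = (base[None, :] + year_eff[year_idx] + month_eff[month_idx] + noise)

    dist_eff = np.zeros((n, config.n_taxa))
    for w in config.disturbances:
        row_mask = np.array([w.active(d) for d in dates])
        col_mask = roles == w.role
        if row_mask.any() and col_mask.any():
            dist_eff[np.ix_(row_mask, col_mask)] += w.effect
    logv = logv + dist_eff

    sample_ids = [f"S{d:%Y%m%d}" for d in dates]
    values = pd.DataFrame(10.0**logv, index=sample_ids, columns=taxa)
    table = FeatureTable(values, feature_kind="genus", value_kind="rpkm")

    post_start = config.post_start
    period = ["post" if d >= post_start else "baseline" for d in dates]
    in_window = np.array([any(w.active(d) for w in config.disturbances) for d in dates])
    stage = []
    for d, p, w in zip(dates, period, in_window):
        if p == "baseline":
            stage.append("pre")
        else:
            stage.append("spill" if w else "recovery")
    metadata = make_metadata(sample_ids, dates, stage, period)

    truth = SimulationTruth(
        roles=pd.Series(roles, index=taxa, name="role"),
        base_log=pd.Series(base, index=taxa, name="base_log"),
        year_effects=pd.DataFrame(year_eff, index=years, columns=taxa),
        month_effects=pd.DataFrame(month_eff, index=months, columns=taxa),
        disturbance_effect=pd.DataFrame(dist_eff, index=sample_ids, columns=taxa),
    )
    return table, metadata, truth


def simulate_kos(taxa_table: FeatureTable, truth: SimulationTruth,
                 config: SimulationConfig) -> tuple[FeatureTable, FeatureMap]:
    """Simulate KO profiles as noisy sparse combinations of taxa.

    Each KO loads on ``ko_loading_sparsity`` taxa with positive
    weights; multiplicative lognormal noise is applied on top.  The
    loading matrix is recorded in ``truth`` and a KO->module map
    grouping consecutive KOs (with a few one-to-many entries) is
    returned for aggregation tests.
    """
    rng = np.random.default_rng(config.seed + 1)
    kos = [f"K{i:05d}" for i in range(config.n_kos)]
    loadings = np.zeros((config.n_kos, config.n_taxa))
    for i in range(config.n_kos):
        k = min(config.ko_loading_sparsity, config.n_taxa)
        idx = rng.choice(config.n_taxa, size=k, replace=False)
        loadings[i, idx] = rng.uniform(0.2, 1.0, size=k)
    if (loadings.sum(axis=1) == 0).any():
        raise UsageError("simulate_kos: all-zero loading row")
    base = taxa_table.values @ loadings.T
    noise = 10.0**rng.normal(0, config.ko_noise_sd, size=base.shape)
    values = pd.DataFrame(base * noise, index=taxa_table.data.index, columns=kos)
    truth.ko_loadings = pd.DataFrame(loadings, index=kos, columns=taxa_table.feature_ids)

    per_module = max(1, config.n_kos // config.n_modules)
    pairs = []
    for i, ko in enumerate(kos):
        mod = f"M{min(i // per_module, config.n_modules - 1):03d}"
        pairs.append((ko, mod))
        if i % 10 == 5:   # a sprinkling of one-to-many assignments
            other = f"M{(min(i // per_module, config.n_modules - 1) + 1) % config.n_modules:03d}"
            pairs.append((ko, other))
    ko_map = FeatureMap.from_pairs(pairs)
    return FeatureTable(values, feature_kind="ko", value_kind="rpkm"), ko_map


def family_map(config: SimulationConfig) -> FeatureMap:
    """Deterministic genus->family map (one-to-one, contiguous blocks)."""
    taxa = [f"g{i:04d}" for i in range(config.n_taxa)]
    per_family = max(1, config.n_taxa // config.n_families)
    pairs = [(t, f"f{min(i // per_family, config.n_families - 1):03d}")
             for i, t in enumerate(taxa)]
    return FeatureMap.from_pairs(pairs)


def null_dataset(config: SimulationConfig | None = None, **overrides
                 ) -> tuple[FeatureTable, pd.DataFrame, SimulationTruth]:
    """A dataset with every disturbance effect removed (calibration null)."""
    base = config or SimulationConfig()
    cfg = dataclasses.replace(base, disturbances=[], **overrides)
    return simulate_taxa(cfg)


def simulate_dataset(config: SimulationConfig):
    """Convenience: taxa + metadata + truth + KO table + both maps."""
    taxa, metadata, truth = simulate_taxa(config)
    ko_table, ko_map = simulate_kos(taxa, truth, config)
    return {
        "taxa": taxa, "metadata": metadata, "truth": truth,
        "kos": ko_table, "ko_map": ko_map, "family_map": family_map(config),
    }
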