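"""End-to-end orchestration of the analysis stages.

A :class:`RunConfig` (usually loaded from YAML) names either a
``simulation`` section or a set of input file paths, the stages to
run, and per-stage parameters.  :func:`run` executes the enabled
stages in dependency order, writes every output as TSV/JSON into the
output directory, and returns a manifest (config echo, seeds, row
counts, checksums).  Re-running with the same config and seed is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anomaly import SeasonalBaselineModel, flag_residuals, interval_from_residuals
from .diversity import diversity_series, metric_correlations
from .errors import DataError, UsageError
from .indicators import default_combinations, indval, select_stage_associated
from .responders import (ResponderPanel, panel_center, panel_rescale, panel_total,
                         pearson_screen)
from .simulate import SimulationConfig, family_map, simulate_kos, simulate_taxa
from .structure import center_scale, euclidean_distances, hclust_complete, \
    nn_dissimilarity, pca, permanova
from .tables import (FeatureMap, FeatureTable, aggregate_features,
                     check_table_metadata, read_metadata, relative_abundance,
                     top_k_features, write_metadata)

log = logging.getLogger("tideline")

ALL_STAGES = ("simulate", "diversity", "structure", "responders", "anomaly",
              "indicators")

DEFAULT_PARAMS = {
    "level": 0.95,
    "exclusion_threshold": 4.0,
    "n_permutations": 999,
    "alpha": 0.05,
    "top_k": 25,
    "detection_threshold": 0.0,
    "fit_scope": "all",
    "interval_kind": "empirical",
}


@dataclass
class RunConfig:
    """Validated pipeline run configuration."""

    outdir: Path
    seed: int = 0
    simulation: dict | None = None
    inputs: dict | None = None
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if (self.simulation is None) == (self.inputs is None):
            raise UsageError("config must set exactly one of 'simulation' or 'inputs'")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise UsageError(f"unknown stages {unknown}; valid: {list(ALL_STAGES)}")
        if self.inputs is not None and "simulate" in self.stages:
            self.stages = [s for s in self.stages if s != "simulate"]
        bad = set(self.params) - set(DEFAULT_PARAMS)
        if bad:
            raise UsageError(f"unknown params {sorted(bad)}")
        self.params = {**DEFAULT_PARAMS, **self.params}

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None, stages=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if outdir is not None:
            raw["outdir"] = outdir
        if seed is not None:
            raw["seed"] = seed
        if stages:
            raw["stages"] = list(stages)
        if "outdir" not in raw:
            raise UsageError("config: 'outdir' is required (or pass --outdir)")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Runner:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outputs: dict[str, Path] = {}
        self.rowcounts: dict[str, int] = {}
        self.data: dict[str, object] = {}

    # -- output helpers -----------------------------------------------
    def _write_df(self, name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = self.cfg.outdir / f"{name}.tsv"
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(path, sep="\t", index=index)
        self.outputs[name] = path
        self.rowcounts[name] = len(df)

    def _write_json(self, name: str, payload: dict) -> None:
        path = self.cfg.outdir / f"{name}.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        self.outputs[name] = path
        self.rowcounts[name] = len(payload)

    def _need(self, key: str, stage: str):
        if key not in self.data:
            raise UsageError(
                f"stage {stage!r} requires {key!r}; enable the producing stage "
                f"or provide it under 'inputs'")
        return self.data[key]

    # -- data acquisition ---------------------------------------------
    def load_inputs(self) -> None:
        inp = self.cfg.inputs
        missing = [k for k in ("table", "metadata") if k not in inp]
        if missing:
            raise UsageError(f"inputs: missing required keys {missing}")
        for key, path in inp.items():
            if not Path(path).exists():
                raise UsageError(f"inputs: file not found for {key!r}: {path}")
        self.data["taxa"] = FeatureTable.read_tsv(inp["table"], feature_kind="genus")
        self.data["metadata"] = read_metadata(inp["metadata"])
        check_table_metadata(self.data["taxa"], self.data["metadata"])
        if "family_map" in inp:
            self.data["family_map"] = FeatureMap.read_tsv(inp["family_map"])
        if "ko_table" in inp:
            self.data["kos"] = FeatureTable.read_tsv(inp["ko_table"], feature_kind="ko")
        if "ko_map" in inp:
            self.data["ko_map"] = FeatureMap.read_tsv(inp["ko_map"])
        if "panel" in inp:
            self.data["panel"] = ResponderPanel.read_tsv(inp["panel"])

    def stage_simulate(self) -> None:
        sim_cfg = SimulationConfig.from_dict(
            {**(self.cfg.simulation or {}), "seed": self.cfg.seed})
        taxa, metadata, truth = simulate_taxa(sim_cfg)
        kos, ko_map = simulate_kos(taxa, truth, sim_cfg)
        fam_map = family_map(sim_cfg)
        panel = ResponderPanel({t: r for t, r in truth.roles.items()
                                if r in ("susceptible", "responder")})
        self.data.update(taxa=taxa, metadata=metadata, truth=truth, kos=kos,
                         ko_map=ko_map, family_map=fam_map, panel=panel)
        taxa.to_tsv(self.cfg.outdir / "taxa.tsv")
        self.outputs["taxa"] = self.cfg.outdir / "taxa.tsv"
        self.rowcounts["taxa"] = taxa.shape[0]
        kos.to_tsv(self.cfg.outdir / "kos.tsv")
        self.outputs["kos"] = self.cfg.outdir / "kos.tsv"
        self.rowcounts["kos"] = kos.shape[0]
        write_metadata(metadata, self.cfg.outdir / "metadata.tsv")
        self.outputs["metadata"] = self.cfg.outdir / "metadata.tsv"
        self.rowcounts["metadata"] = len(metadata)
        ko_map.to_tsv(self.cfg.outdir / "ko_map.tsv")
        self.outputs["ko_map"] = self.cfg.outdir / "ko_map.tsv"
        self.rowcounts["ko_map"] = len(ko_map.parents)
        fam_map.to_tsv(self.cfg.outdir / "family_map.tsv")
        self.outputs["family_map"] = self.cfg.outdir / "family_map.tsv"
        self.rowcounts["family_map"] = len(fam_map.parents)
        panel.to_tsv(self.cfg.outdir / "panel.tsv")
        self.outputs["panel"] = self.cfg.outdir / "panel.tsv"
        self.rowcounts["panel"] = len(panel.roles)
        truth.to_json(self.cfg.outdir / "truth.json")
        self.outputs["truth"] = self.cfg.outdir / "truth.json"
        self.rowcounts["truth"] = len(truth.roles)

    # -- analysis stages ----------------------------------------------
    def stage_diversity(self) -> None:
        taxa = self._need("taxa", "diversity")
        md = self._need("metadata", "diversity")
        p = self.cfg.params
        prof = diversity_series(taxa, md, detection_threshold=p["detection_threshold"])
        self._write_df("diversity", prof)
        self._write_df("diversity_correlations", metric_correlations(prof), index=False)
        rel = relative_abundance(taxa)
        top = top_k_features(rel, p["top_k"])
        self._write_df("top_features",
                       pd.DataFrame({"rank": range(1, len(top) + 1), "feature": top}),
                       index=False)

    def stage_structure(self) -> None:
        taxa = self._need("taxa", "structure")
        md = self._need("metadata", "structure")
        p = self.cfg.params
        z = center_scale(taxa)
        pc = pca(z, n_components=min(5, min(z.z.shape)))
        pc1 = pd.DataFrame({"date": md.loc[z.sample_ids, "date"],
                            "pc1": pc.scores["PC1"]})
        self._write_df("pc1", pc1.sort_values("date"))
        self._write_df("nn_dissimilarity", nn_dissimilarity(z, md))
        dist = euclidean_distances(z)
        res = permanova(dist, md.loc[z.sample_ids, "stage"],
                        n_permutations=p["n_permutations"], seed=self.cfg.seed)
        self._write_json("permanova", {
            "pseudo_F": res.pseudo_f, "R2": res.r2, "p_value": res.p_value,
            "n_permutations": res.n_permutations, "seed": res.seed})
        if "kos" in self.data and "ko_map" in self.data:
            modules = aggregate_features(self.data["kos"], self.data["ko_map"],
                                         "module", strict=False)
            zm = center_scale(modules)
            # cluster the module profiles (columns) on Euclidean distance
            from scipy.spatial.distance import pdist, squareform
            dmod = squareform(pdist(zm.values.T, metric="euclidean"))
            merges = hclust_complete(dmod)
            mdf = pd.DataFrame(merges, columns=["left", "right", "height", "size"])
            mdf.insert(0, "step", range(1, len(mdf) + 1))
            self._write_df("hclust_modules", mdf, index=False)
            self.data["modules"] = modules

    def stage_responders(self) -> None:
        taxa = self._need("taxa", "responders")
        panel = self._need("panel", "responders")
        rel = relative_abundance(taxa)
        totals = panel_total(rel, panel, role="responder").to_frame()
        totals["date"] = self._need("metadata", "responders").loc[totals.index, "date"]
        self._write_df("responder_totals", totals[["date", "panel_total"]])
        scaled = panel_rescale(rel, panel, role="responder")
        self._write_df("responder_scaled", scaled)
        self._write_df("responder_centered", panel_center(scaled))
        screen = pearson_screen(rel, panel.features("susceptible"),
                                panel.features("responder"), adjust="bh")
        self._write_df("responder_correlations", screen, index=False)

    def stage_anomaly(self) -> None:
        taxa = self._need("taxa", "anomaly")
        md = self._need("metadata", "anomaly")
        fmap = self._need("family_map", "anomaly")
        p = self.cfg.params
        families = aggregate_features(relative_abundance(taxa), fmap, "family")
        model = SeasonalBaselineModel.from_table(families, md,
                                                 fit_scope=p["fit_scope"])
        res = model.fit()
        self._write_df("family_anova", res.anova())
        interval = res.baseline_interval(level=p["level"],
                                         exclusion_threshold=p["exclusion_threshold"],
                                         kind=p["interval_kind"])
        self._write_df("family_interval", interval.bounds)
        report = res.flag_anomalies(interval)
        self._write_df("family_anomalies", report, index=False)
        self._write_df("family_monthly_panel",
                       res.monthly_anomaly_panel(
                           report, exclusion_threshold=p["exclusion_threshold"]),
                       index=False)
        self.data["family_report"] = report
        if "kos" in self.data and "ko_map" in self.data:
            kos = self.data["kos"]
            ko_model = SeasonalBaselineModel.from_table(
                relative_abundance(kos), md, fit_scope=p["fit_scope"])
            ko_res = ko_model.fit()
            med = ko_res.module_median_residuals(self.data["ko_map"])
            base_ids = md.index[md["period"] == "baseline"]
            mod_interval = interval_from_residuals(
                med, base_ids, level=p["level"],
                exclusion_threshold=p["exclusion_threshold"], kind=p["interval_kind"])
            self._write_df("module_interval", mod_interval.bounds)
            mod_report = flag_residuals(med, mod_interval, md)
            self._write_df("module_anomalies", mod_report, index=False)
            self.data["module_report"] = mod_report

    def stage_indicators(self) -> None:
        kos = self._need("kos", "indicators")
        md = self._need("metadata", "indicators")
        p = self.cfg.params
        stages_per_sample = md.loc[kos.sample_ids, "stage"]
        post_stages = set(md.loc[md["period"] == "post", "stage"].unique())
        combos = default_combinations(list(stages_per_sample), post_stages)
        results = indval(kos, stages_per_sample, allowed_combinations=combos,
                         n_permutations=p["n_permutations"], seed=self.cfg.seed)
        single, union = select_stage_associated(
            results, post_stages, alpha=p["alpha"],
            observed_stages=set(stages_per_sample))
        out = results.copy()
        out["best_combination"] = out["best_combination"].map(
            lambda c: "+".join(sorted(c)))
        out["selected_list"] = ""
        out.loc[out.index.isin(single), "selected_list"] = "single_post_stage"
        out.loc[out.index.isin(union), "selected_list"] = "all_post_stages"
        self._write_df("indicators", out)

    def run(self) -> dict:
        cfg = self.cfg
        cfg.outdir.mkdir(parents=True, exist_ok=True)
        if cfg.inputs is not None:
            self.load_inputs()
        order = [s for s in ALL_STAGES if s in cfg.stages]
        for stage in order:
            log.info("stage %s: start", stage)
            getattr(self, f"stage_{stage}")()
            log.info("stage %s: done", stage)
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "stages": order,
            "params": cfg.params,
            "simulation": cfg.simulation,
            "inputs": {k: str(v) for k, v in (cfg.inputs or {}).items()} or None,
            "outputs": {name: {"path": str(path.relative_to(cfg.outdir)),
                               "rows": self.rowcounts[name],
                               "sha256": _sha256(path)}
                        for name, path in sorted(self.outputs.items())},
        }
        (cfg.outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    return _Runner(config).run()
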