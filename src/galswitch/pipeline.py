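"""End-to-end orchestration: simulate -> preprocess -> classify -> predict
-> sensors, under one seeded configuration, with a machine-readable run
report.

Stage products are plain DataFrames (written as TSV when an output
directory is given), so any stage can be re-run from disk.  The sample
loop streams: events for one sample are simulated, gated,
saturation-corrected and summarized, then discarded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import epistasis as _epistasis
from . import io as _io
from . import sensors as _sensors
from . import synthetic as _synth
from .cytometry import (EventTable, correct_saturation, default_bin_edges,
                        gate_events, growth_rate, on_cutoff_from_controls,
                        pseudolog, summarize_sample)

__all__ = ["RunConfig", "run_pipeline", "preprocess_synthetic",
           "aggregate_samples", "build_doubles_table", "build_singles_table"]

STAGES = ("simulate", "preprocess", "classify", "predict", "sensors")
STAGE_DEPS = {"preprocess": ("simulate",), "classify": ("preprocess",),
              "predict": ("classify",), "sensors": ()}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    outdir: str | None = None
    stages: tuple = STAGES
    input_mode: str = "synthetic"  # or "files"
    # generator scale
    class_counts: dict | None = None
    dropout_rate: float = 0.02
    replicate_count: int = 2
    n_events: int = 5000
    # cytometry
    rect_quantile: float = 0.95
    centroid_exclusion: float = 0.40
    min_gated_events: int = 100
    on_cutoff_quantile: float = 0.999
    n_control_samples: int = 3
    # classify
    min_cluster_size_grid: tuple = (5, 10, 15, 25)
    # predict
    cv_k: int = 0              # 0 disables downsampled CV
    cv_iterations: int = 200
    # sensors
    sensor_composition: dict | None = None
    sensor_replicates: int = 8
    sim_params: dict = field(default_factory=dict)  # SimulationParams overrides

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        enabled = set(self.stages)
        for stage, deps in STAGE_DEPS.items():
            if stage in enabled:
                missing = [d for d in deps if d not in enabled]
                if missing:
                    raise ValueError(
                        f"stage {stage!r} requires {missing} to be enabled")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def simulation_params(self) -> _synth.SimulationParams:
        params = _synth.SimulationParams(**self.sim_params)
        if self.class_counts is not None:
            params.class_counts = self.class_counts
        params.dropout_rate = self.dropout_rate
        params.replicate_count = self.replicate_count
        params.n_events = self.n_events
        return params

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["min_cluster_size_grid"] = list(self.min_cluster_size_grid)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def process_sample(events: EventTable, on_cutoff: float,
                   bin_edges: np.ndarray, cfg: RunConfig):
    """Gate, saturation-correct and summarize one sample."""
    gated, ginfo = gate_events(events, cfg.rect_quantile,
                               cfg.centroid_exclusion, cfg.min_gated_events)
    corrected, sat_info = correct_saturation(gated)
    summary = summarize_sample(corrected, on_cutoff, bin_edges,
                               rate_events=events)
    summary.censored = summary.censored or ginfo["censored"]
    summary.extra.update(n_saturated=sat_info["n_saturated"],
                         n_gate_input=ginfo["n_input"])
    return summary


def preprocess_synthetic(truth: _synth.TruthTable, cfg: RunConfig,
                         params: _synth.SimulationParams,
                         genotype_ids=None):
    """Simulate and summarize every sample of the design.

    Returns (samples table, per-sample profile arrays dict, on_cutoff).
    The ON cutoff is derived from pooled autofluorescent-control draws
    before any sample is processed.
    """
    bin_edges = default_bin_edges()
    controls = [
        _synth.simulate_autofluorescence(cfg.n_events, cfg.seed, r, params)
        for r in range(cfg.n_control_samples)]
    on_cutoff = on_cutoff_from_controls(controls, cfg.on_cutoff_quantile)

    ids = list(genotype_ids if genotype_ids is not None
               else truth.table["genotype_id"])
    rows, vectors = [], {}
    for gid in ids:
        n_rep = int(truth.row(gid)["replicate_count"])
        for rep in range(n_rep):
            for cond in ("glucose", "galactose"):
                ev = _synth.simulate_events(gid, cond, truth, cfg.n_events,
                                            cfg.seed, rep, params)
                s = process_sample(ev, on_cutoff, bin_edges, cfg)
                rows.append(dict(
                    sample_id=ev.sample_id, genotype_id=gid, condition=cond,
                    replicate=rep, fracON=s.fracON, mean_yfp=s.mean_yfp,
                    density=s.density, n_gated=s.n_gated,
                    n_events=s.n_events, censored=s.censored))
                vectors[ev.sample_id] = s.density_vector
    samples = pd.DataFrame(rows)
    return samples, vectors, on_cutoff


def aggregate_samples(samples: pd.DataFrame, vectors: dict,
                      dilution: float = 150.0 / 9.0, hours: float = 12.0):
    """Per-genotype records and mean profiles from per-sample summaries.

    Growth is computed per replicate from its paired glucose/galactose
    densities, then averaged; the profile matrix stores replicate-mean
    bin densities, glucose then galactose.  Genotypes missing a condition
    are excluded (reported in the returned log).
    """
    records, profiles, dropped = [], {}, []
    for gid, grp in samples.groupby("genotype_id", sort=False):
        glu = grp[grp["condition"] == "glucose"]
        gal = grp[grp["condition"] == "galactose"]
        if len(glu) == 0 or len(gal) == 0:
            dropped.append(gid)
            continue
        mus, gens = [], []
        for rep in sorted(set(glu["replicate"]) & set(gal["replicate"])):
            dg = float(glu[glu["replicate"] == rep]["density"].iloc[0])
            da = float(gal[gal["replicate"] == rep]["density"].iloc[0])
            mu, gen = growth_rate(dg, da, dilution, hours)
            mus.append(mu)
            gens.append(gen)
        mus = np.asarray(mus, dtype=float)
        n = int(np.isfinite(mus).sum())
        mu_mean = float(np.nanmean(mus)) if n else np.nan
        se = float(np.nanstd(mus, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        prof = np.concatenate([
            np.mean(np.stack([vectors[s] for s in glu["sample_id"]]), axis=0),
            np.mean(np.stack([vectors[s] for s in gal["sample_id"]]), axis=0)])
        profiles[gid] = prof
        records.append(dict(
            genotype_id=gid,
            fracON_glu=float(glu["fracON"].mean()),
            fracON_gal=float(gal["fracON"].mean()),
            mean_yfp_glu=float(glu["mean_yfp"].mean()),
            mean_yfp_gal=float(gal["mean_yfp"].mean()),
            density_glu=float(glu["density"].mean()),
            density_gal=float(gal["density"].mean()),
            mu=mu_mean, se_mu=se,
            generations=float(np.nanmean(gens)) if gens else np.nan,
            n_rep=n,
            censored=bool(grp["censored"].any())))
    records = pd.DataFrame(records).set_index("genotype_id", drop=False)
    profiles = _io.profiles_to_frame(profiles)
    return records, profiles, dropped


def build_doubles_table(records: pd.DataFrame, design: pd.DataFrame,
                        assignments: pd.DataFrame) -> pd.DataFrame:
    """Double-mutant table with each single's locus, allele and class."""
    single_class = {}
    singles = design[design["n_mutant_loci"] == 1]
    for _, d in singles.iterrows():
        gid = d["genotype_id"]
        if gid in assignments.index:
            single_class[gid] = assignments.loc[gid, "class_intermediate"]
    rows = []
    doubles = design[(design["n_mutant_loci"] == 2) & (~design["dropout"])]
    for _, d in doubles.iterrows():
        gid = d["genotype_id"]
        if gid not in records.index:
            continue
        loci = [l for l in _synth.LOCI
                if d[f"{l.lower()}_allele"] != "WT"]
        a1, a2 = (d[f"{loci[0].lower()}_allele"],
                  d[f"{loci[1].lower()}_allele"])
        rows.append(dict(
            genotype_id=gid, locus1=loci[0], allele1=a1,
            class1=single_class.get(a1), locus2=loci[1], allele2=a2,
            class2=single_class.get(a2),
            mu=float(records.loc[gid, "mu"]),
            n_rep=int(records.loc[gid, "n_rep"])))
    return pd.DataFrame(rows)


def build_singles_table(records: pd.DataFrame,
                        design: pd.DataFrame) -> pd.DataFrame:
    """Single-mutant (plus WT) replicate stats for the multiplicative null."""
    rows = []
    for _, d in design[design["n_mutant_loci"] <= 1].iterrows():
        gid = d["genotype_id"]
        if gid not in records.index:
            continue
        allele = gid if gid != "WT" else "WT"
        rows.append(dict(allele=allele,
                         mu=float(records.loc[gid, "mu"]),
                         se_mu=float(records.loc[gid, "se_mu"]),
                         n_rep=int(records.loc[gid, "n_rep"])))
    return pd.DataFrame(rows)


def _infer_background(records: pd.DataFrame,
                      assignments: pd.DataFrame) -> float:
    """Background growth = mean growth of broad-Uninducible genotypes,
    the measurable proxy for growth without functional GAL regulation."""
    unind = assignments[assignments["class_broad"] == "Uninducible"].index
    vals = records.loc[records.index.intersection(unind), "mu"].dropna()
    return float(vals.mean()) if len(vals) else 0.0


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run report."""
    config.validate()
    params = config.simulation_params()
    t0 = time.time()
    report: dict = {"config_hash": config.config_hash(),
                    "seed": config.seed, "stages": {}}
    out = Path(config.outdir) if config.outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)

    artifacts: dict = {}
    enabled = list(config.stages)

    if "simulate" in enabled:
        library = _synth.generate_allele_library(params.class_counts,
                                                 config.seed, params)
        designs = _synth.generate_design(library, config.dropout_rate,
                                         config.seed, config.replicate_count)
        truth = _synth.build_truth_table(library, designs, config.seed,
                                         params)
        design_df = _synth.design_to_frame(designs)
        artifacts.update(library=library, designs=designs, truth=truth,
                         design_df=design_df)
        report["stages"]["simulate"] = {
            "n_alleles": len(library),
            "n_genotypes": int((~design_df["dropout"]).sum()),
            "n_doubles": int(((design_df["n_mutant_loci"] == 2)
                              & ~design_df["dropout"]).sum())}
        if out:
            _io.write_tsv(_synth.library_to_frame(library),
                          out / "library.tsv")
            _io.write_tsv(design_df, out / "design.tsv")
            _io.write_tsv(truth.table.reset_index(drop=True),
                          out / "truth.tsv")

    if "preprocess" in enabled:
        truth = artifacts["truth"]
        samples, vectors, on_cutoff = preprocess_synthetic(truth, config,
                                                           params)
        records, profiles, dropped = aggregate_samples(
            samples, vectors, params.dilution, params.hours)
        artifacts.update(samples=samples, records=records, profiles=profiles,
                         on_cutoff=on_cutoff)
        report["stages"]["preprocess"] = {
            "n_samples": len(samples),
            "n_censored": int(samples["censored"].sum()),
            "n_genotypes": len(records),
            "n_dropped": len(dropped),
            "on_cutoff": float(on_cutoff)}
        if out:
            _io.write_tsv(samples, out / "sample_summaries.tsv")
            _io.write_tsv(records.reset_index(drop=True), out / "records.tsv")
            _io.write_tsv(profiles.reset_index(), out / "profiles.tsv")

    if "classify" in enabled:
        records, profiles = artifacts["records"], artifacts["profiles"]
        assignments, est = _classify.assign_classes(
            profiles, records, config.min_cluster_size_grid, params=params)
        artifacts["assignments"] = assignments
        counts = assignments["class_intermediate"].value_counts().to_dict()
        report["stages"]["classify"] = {
            "n_classified": len(assignments),
            "best_min_cluster_size": est.best_min_cluster_size_,
            "variance_explained": est.variance_explained_,
            "class_counts": counts,
            "n_rescued": int((assignments["provenance"] == "rescued").sum())}
        if out:
            _io.write_tsv(assignments.reset_index(drop=True),
                          out / "class_assignments.tsv")
            _io.write_tsv(est.evaluations_, out / "cluster_evaluations.tsv")

    if "predict" in enabled:
        records = artifacts["records"]
        design_df = artifacts["design_df"]
        assignments = artifacts["assignments"]
        doubles = build_doubles_table(records, design_df, assignments)
        singles = build_singles_table(records, design_df)
        background = _infer_background(records, assignments)

        mult = _epistasis.MultiplicativeNullModel(background=background)
        mult.fit(singles)
        reports = [(_epistasis.predict_and_score(mult, doubles,
                                                 "multiplicative"))]
        models = {}
        for scheme in ("intermediate5", "broad3"):
            for aware in (True, False):
                name = f"classmean_{scheme}_" + (
                    "locus_aware" if aware else "blinded")
                m = _epistasis.fit_class_model(doubles, scheme, aware)
                models[name] = m
                reports.append(_epistasis.predict_and_score(m, doubles, name))
        var_df = pd.concat([r.to_frame() for r in reports],
                           ignore_index=True)
        cv_summary = None
        if config.cv_k > 0:
            cv = _epistasis.downsample_cv(
                doubles, config.cv_k, config.cv_iterations, config.seed)
            cv_summary = {"median": cv["median"], "iqr": cv["iqr"],
                          "k": cv["k"]}
        artifacts.update(doubles=doubles, variance_reports=reports,
                         models=models)
        report["stages"]["predict"] = {
            "n_doubles": len(doubles),
            "background": background,
            "variance_explained": {r.model: r.variance_explained
                                   for r in reports},
            "n_parameters": {name: m.n_parameters_
                             for name, m in models.items()},
            "cv": cv_summary}
        if out:
            _io.write_tsv(var_df, out / "variance_report.tsv")
            pred = mult.predict_df(doubles)
            pred["observed"] = doubles["mu"].to_numpy()
            _io.write_tsv(pred, out / "predictions_multiplicative.tsv")
            cm = models["classmean_intermediate5_locus_aware"]
            pdf = cm.predict_df(doubles)
            pdf["observed"] = doubles["mu"].to_numpy()
            _io.write_tsv(pdf, out / "predictions_classmean.tsv")

    if "sensors" in enabled:
        panel = _synth.simulate_sensor_panel(
            config.seed, config.sensor_composition, config.sensor_replicates,
            params=params)
        contrasts = _sensors.contrast_backgrounds(panel)
        sensorless = panel[panel["arm"] == "dGAL3+GALK"]
        nulls = _sensors.fit_leakiness_null(sensorless)
        above = _sensors.test_above_null(panel, nulls)
        calls = _sensors.call_dependencies(panel, contrasts)
        artifacts.update(sensor_panel=panel, contrasts=contrasts,
                         nulls=nulls, above_null=above, calls=calls)
        report["stages"]["sensors"] = {
            "n_pairs": int(panel["pair_id"].nunique()),
            "n_significant_contrasts": int(contrasts["significant"].sum()),
            "null_fits": {g: dict(asym=f.asym_, xmid=f.xmid_, scal=f.scal_,
                                  converged=f.converged_)
                          for g, f in nulls.items()},
            "verdicts": {
                "gal3": calls["gal3_verdict"].value_counts().to_dict(),
                "gal1": calls["gal1_verdict"].value_counts().to_dict()},
            "n_harmonious": int(calls["harmonious"].sum())}
        if out:
            _io.write_tsv(panel, out / "sensor_panel.tsv")
            _io.write_tsv(contrasts, out / "sensor_contrasts.tsv")
            _io.write_tsv(above, out / "sensor_above_null.tsv")
            _io.write_tsv(calls, out / "dependency_calls.tsv")
            nf = pd.DataFrame([
                dict(galk_panel=g, asym=f.asym_, xmid=f.xmid_, scal=f.scal_,
                     converged=f.converged_) for g, f in nulls.items()])
            _io.write_tsv(nf, out / "sensor_null_fits.tsv")

    report["elapsed_s"] = round(time.time() - t0, 2)
    report["completed_stages"] = [s for s in enabled
                                  if s in report["stages"]]
    if out:
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    report["artifacts"] = artifacts
    return report
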