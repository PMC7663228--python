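"""End-to-end pipeline: simulate -> accel -> preprocess -> nominate -> fit ->
select -> bch -> report, with one config, per-stage child seeds, artifact
checksums and a run manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bch as bch_mod
from . import lca, nomination, reporting, selection, synthetic
from .accelerometry import CutPoints, process_series
from .config import SimulationConfig, default_config
from .preprocessing import IndicatorMatrix, build_indicator_matrix
from .rng import child_rng

log = logging.getLogger(__name__)

STAGES = ("simulate", "accel", "preprocess", "nominate", "fit", "select",
          "bch", "report")

# stage -> (required input artifacts, produced artifacts)
_STAGE_IO = {
    "simulate": ((), ("cohort.csv", "cohort_complete.csv", "ballots.csv")),
    "accel": (("cohort_complete.csv",), ("pa_summary.csv",)),
    "preprocess": (("cohort.csv",), ("indicators.csv",)),
    "nominate": (("ballots.csv", "cohort_complete.csv"), ("tally.csv",)),
    "fit": (("indicators.csv",), ()),         # fit_K<k>.json filled at runtime
    "select": (("indicators.csv",), ("selection.csv",)),
    "bch": (("tally.csv",), ("distal.json",)),
    "report": (("cohort_complete.csv", "tally.csv"), ("report.json",)),
}


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "results/run"
    simulation: SimulationConfig = field(default_factory=lambda: default_config())
    # accelerometry stage
    accel_enabled: bool = True
    accel_epoch_s: int = 10
    accel_min_wear_min: float = 500.0
    accel_window_min: tuple = (360, 1440)
    accel_min_valid_days: int = 2
    accel_write_epoch_sample: int = 3
    # main fit
    fit_k: int = 5
    fit_n_starts: int = 12
    fit_short_iters: int = 30
    fit_n_final: int = 2
    fit_max_iter: int = 1000
    fit_tol: float = 1e-7
    # selection
    select_enabled: bool = True
    select_kmin: int = 2
    select_kmax: int = 8
    select_n_starts: int = 8
    select_blrt_reps: int = 0
    # distal outcome
    bch_n_boot: int = 500
    # nomination
    nominate_fraction: float = 0.18

    def validate(self) -> None:
        errors = []
        if self.fit_k < 1:
            errors.append("fit_k: must be >= 1")
        if not 0 < self.nominate_fraction <= 1:
            errors.append("nominate_fraction: must be in (0, 1]")
        if self.select_kmin > self.select_kmax:
            errors.append("select_kmin: must be <= select_kmax")
        if self.select_kmin < 2:
            errors.append("select_kmin: must be >= 2")
        if self.bch_n_boot < 10:
            errors.append("bch_n_boot: must be >= 10")
        if self.accel_epoch_s <= 0:
            errors.append("accel_epoch_s: must be positive")
        try:
            self.simulation.validate()
        except ValueError as exc:
            errors.append(f"simulation: {exc}")
        if errors:
            raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["accel_window_min"] = list(self.accel_window_min)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "accel_window_min" in d:
            d["accel_window_min"] = tuple(d["accel_window_min"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    artifacts: dict          # path -> sha256
    timings: dict            # stage -> seconds
    package_version: str

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _require(out: Path, names) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing upstream artifact(s) {missing} in {out}; run the "
            "producing stage first")


def run_pipeline(config: PipelineConfig, stages=None) -> RunManifest:
    """Execute the requested stages in dependency order."""
    config.validate()
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    sim = config.simulation
    sim.seed = seed

    timings = {}
    seeds = {"root": seed}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s [seed=%d] starting", name, seed)
        fn()
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, timings[name])

    # ------------------------------------------------------------------
    def simulate():
        cohort = synthetic.generate_cohort(sim)
        rates = {c: r for c, r in sim.missing_rates.items()}
        if config.accel_enabled:
            # accelerometry missingness arises from wear compliance instead
            rates.pop("mvpa", None)
            rates.pop("sedentary", None)
        res = synthetic.inject_missingness(cohort, rates, seed=seed)
        ballots = synthetic.generate_ballots(cohort, sim.nomination, seed=seed)
        _write_csv(res.original, out / "cohort_complete.csv")
        _write_csv(res.data, out / "cohort.csv")
        _write_csv(ballots, out / "ballots.csv")
        seeds["simulate"] = seed

    def accel():
        _require(out, _STAGE_IO["accel"][0])
        cohort = pd.read_csv(out / "cohort_complete.csv")
        cut = CutPoints.youth_cpm(epoch_s=config.accel_epoch_s)
        rows = []
        epoch_dir = out / "epochs"
        for i, row in enumerate(cohort.itertuples()):
            rng = child_rng(seed, "epochs", i)
            series = synthetic.simulate_week(
                row.participant_id, row.mvpa, row.sedentary,
                bool(row.accel_compliant), rng, cut=cut,
                native_epoch_s=config.accel_epoch_s)
            if i < config.accel_write_epoch_sample:
                epoch_dir.mkdir(exist_ok=True)
                _write_csv(series.to_frame(),
                           epoch_dir / f"{row.participant_id}.csv")
            res = process_series(
                series, cut=cut, target_epoch_s=config.accel_epoch_s,
                window_min=tuple(config.accel_window_min),
                min_wear_min=config.accel_min_wear_min,
                min_valid_days=config.accel_min_valid_days)
            rows.append({
                "participant_id": row.participant_id,
                "included": int(res["included"]),
                "n_valid_days": res["n_valid_days"],
                "weekday_mvpa_min": res["weekday_mvpa_min"],
                "weekday_sed_min": res["weekday_sed_min"],
                "meets_guideline": (int(res["meets_guideline"])
                                    if res["included"] else np.nan),
            })
        _write_csv(pd.DataFrame(rows), out / "pa_summary.csv")
        seeds["accel"] = seed

    def preprocess():
        _require(out, _STAGE_IO["preprocess"][0])
        cohort = pd.read_csv(out / "cohort.csv")
        pa = None
        if config.accel_enabled:
            _require(out, ("pa_summary.csv",))
            pa = pd.read_csv(out / "pa_summary.csv")
        matrix = build_indicator_matrix(cohort, pa_summary=pa)
        _write_csv(matrix.to_frame(), out / "indicators.csv")

    def nominate():
        _require(out, _STAGE_IO["nominate"][0])
        ballots = pd.read_csv(out / "ballots.csv")
        cohort = pd.read_csv(out / "cohort_complete.csv")
        roster = synthetic.roster_from_cohort(cohort)
        tally = nomination.nominate(ballots, roster,
                                    fraction=config.nominate_fraction)
        _write_csv(tally, out / "tally.csv")

    def fit_stage():
        _require(out, _STAGE_IO["fit"][0])
        matrix = IndicatorMatrix.from_frame(pd.read_csv(out / "indicators.csv"))
        spec = lca.ModelSpec(n_classes=config.fit_k)
        result = lca.fit(matrix, spec, n_starts=config.fit_n_starts,
                         short_iters=config.fit_short_iters,
                         n_final=config.fit_n_final,
                         max_iter=config.fit_max_iter, tol=config.fit_tol,
                         seed=seed)
        result.save(out / f"fit_K{config.fit_k}.json")
        post = pd.DataFrame(
            result.posteriors,
            columns=[f"class_{k + 1}" for k in range(config.fit_k)])
        post.insert(0, "participant_id", matrix.participant_ids)
        post["modal"] = result.modal + 1
        _write_csv(post, out / f"posteriors_K{config.fit_k}.csv")
        seeds["fit"] = seed

    def select():
        _require(out, _STAGE_IO["select"][0])
        matrix = IndicatorMatrix.from_frame(pd.read_csv(out / "indicators.csv"))
        cfg = selection.SelectionConfig(
            n_starts=config.select_n_starts,
            blrt_reps=config.select_blrt_reps, seed=seed)
        table = selection.select_classes(
            matrix, range(config.select_kmin, config.select_kmax + 1), cfg)
        _write_csv(table, out / "selection.csv")
        seeds["select"] = seed

    def bch_stage():
        _require(out, (f"posteriors_K{config.fit_k}.csv", "tally.csv"))
        post = pd.read_csv(out / f"posteriors_K{config.fit_k}.csv")
        tally = pd.read_csv(out / "tally.csv")
        merged = post.merge(tally, on="participant_id", how="left")
        cols = [c for c in post.columns if c.startswith("class_")]
        p = merged[cols].to_numpy()
        modal = merged["modal"].to_numpy() - 1
        y = merged["supporter"].fillna(False).astype(bool).to_numpy()
        q = bch_mod.classification_error_matrix(p, modal)
        w = bch_mod.bch_weights(q, modal)
        estimates = bch_mod.class_outcome_proportions(
            w, y, merged["school_id"].to_numpy(),
            n_boot=config.bch_n_boot, seed=seed)
        payload = {
            "classification_error_matrix": q.tolist(),
            "estimates": [asdict(e) for e in estimates],
            "n_boot": config.bch_n_boot,
        }
        with open(out / "distal.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        seeds["bch"] = seed

    def report():
        _require(out, (f"fit_K{config.fit_k}.json",
                       f"posteriors_K{config.fit_k}.csv",
                       "cohort_complete.csv", "tally.csv"))
        with open(out / f"fit_K{config.fit_k}.json") as fh:
            saved = json.load(fh)
        post_df = pd.read_csv(out / f"posteriors_K{config.fit_k}.csv")
        cohort = pd.read_csv(out / "cohort_complete.csv")
        tally = pd.read_csv(out / "tally.csv")
        cohort = cohort.merge(
            tally[["participant_id", "supporter"]], on="participant_id",
            how="left", suffixes=("_drop", ""))
        cohort["supporter"] = cohort["supporter"].fillna(False).astype(bool)
        cols = [c for c in post_df.columns if c.startswith("class_")]
        result = lca.FitResult(
            params=lca.LcaParameters.from_dict(saved["params"]),
            log_likelihood=saved["log_likelihood"],
            n_parameters=saved["n_parameters"],
            posteriors=post_df[cols].to_numpy(),
            modal=post_df["modal"].to_numpy() - 1,
            converged=saved["converged"], n_iter=saved["n_iter"],
            n_starts_used=saved["n_starts_used"],
            best_start_seed=saved["best_start_seed"])
        flags = cohort["supporter"].to_numpy()
        summary = reporting.cohort_summary(cohort, flags)
        profiles = reporting.profile_table(result)
        dist = reporting.class_distribution(result, flags)
        breakdown = reporting.school_breakdown(
            result.modal, cohort["school_id"].to_numpy(), flags)
        _write_csv(summary, out / "summary.csv")
        _write_csv(profiles, out / "profile_table.csv")
        _write_csv(breakdown, out / "school_breakdown.csv")
        bundle = {
            "class_distribution": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in dist.items()},
            "schools_without_supporters":
                reporting.schools_without_supporters(breakdown).to_dict(),
            "supporter_share": float(np.mean(flags)),
            "relative_entropy": selection.relative_entropy(result.posteriors),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True, default=str)

    fns = {"simulate": simulate, "accel": accel, "preprocess": preprocess,
           "nominate": nominate, "fit": fit_stage, "select": select,
           "bch": bch_stage, "report": report}
    for name in stages:
        if name == "accel" and not config.accel_enabled:
            continue
        if name == "select" and not config.select_enabled:
            continue
        run_stage(name, fns[name])

    artifacts = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            artifacts[str(path.relative_to(out))] = _sha256(path)
    manifest = RunManifest(config=config.to_dict(), seeds=seeds,
                           artifacts=artifacts, timings=timings,
                           package_version=_version())
    manifest.save(out / "manifest.json")
    return manifest


def _version() -> str:
    from . import __version__
    return __version__
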