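"""End-to-end orchestration: simulate -> flux -> fit -> screen -> select -> cluster.

Each stage reads and writes plain files in the run directory, so every
intermediate is auditable and no stage mutates its inputs.  A manifest
(JSON) records the configuration snapshot, input hashes, per-stage seeds
and timings, output paths and the package version; reruns with an equal
manifest reproduce the deterministic stages exactly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cluster_depth_profile, cluster_rainfall_surface
from .columns import (RESPONSES, derive_ratio_columns,
                      validate_horizon_table)
from .edaphic import (build_global_model, exclusion_pairs_from_correlation,
                      screen_residuals, select_models)
from .flux import (accumulate_series, read_chambers_csv, read_curves_csv,
                   write_curves_csv)
from .kinetics import FitConfig, PoolDecayModel
from .synth import LandscapeConfig, generate_horizon_table, generate_incubation

__all__ = ["RunManifest", "run_all", "run_simulate", "run_flux", "run_fit",
           "run_screen", "run_select", "run_cluster", "ValidationError"]


class ValidationError(ValueError):
    """Bad or missing inputs/configuration (CLI exit code 1)."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    inputs: dict[str, str]
    outputs: dict[str, str]
    timings: dict[str, float]
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))


# -- individual stages ------------------------------------------------------

def run_simulate(out_dir: Path, seed: int,
                 config: dict | None = None) -> dict[str, Path]:
    cfg = LandscapeConfig(**{**(config or {}), "seed": seed})
    table, truth = generate_horizon_table(cfg)
    series, curves = generate_incubation(table, truth, cfg)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = out_dir / "horizon_table.csv"
    table.to_csv(table_path, index=False)
    chamber_rows = []
    for s in series:
        rec = s.records.copy()
        rec.insert(0, "sample_id", s.sample_id)
        rec["dry_soil_mass_g"] = s.dry_soil_mass
        rec["chamber_volume_l"] = s.chamber_volume
        chamber_rows.append(rec)
    chambers_path = out_dir / "chambers.csv"
    pd.concat(chamber_rows, ignore_index=True).to_csv(chambers_path, index=False)
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, default=float))
    return {"horizon_table": table_path, "chambers": chambers_path,
            "truth": truth_path}


def run_flux(chambers_csv: Path, out_csv: Path,
             clamp_negative: bool = True) -> Path:
    series = read_chambers_csv(chambers_csv)
    curves = [accumulate_series(s, clamp_negative=clamp_negative)
              for s in series]
    write_curves_csv(curves, out_csv)
    return out_csv


def run_fit(curves_csv: Path, horizon_csv: Path, out_csv: Path,
            seed: int, iterations: int = 10_000, burn_in: int = 2_000,
            method: str = "two-step") -> Path:
    curves = read_curves_csv(curves_csv)
    table = pd.read_csv(horizon_csv)
    if "SOC" not in table.columns:
        raise ValidationError("horizon table missing column: SOC")
    soc = table.set_index("horizon_id")["SOC"]
    seeds = np.random.SeedSequence(seed).generate_state(len(curves)) % (2**31)
    rows = []
    for curve, sub_seed in zip(curves, seeds):
        if curve.sample_id not in soc.index:
            raise ValidationError(
                f"curve {curve.sample_id} has no horizon-table row")
        cfg = FitConfig(iterations=iterations, burn_in=burn_in,
                        seed=int(sub_seed))
        res = PoolDecayModel(curve, float(soc[curve.sample_id]) * 1e4,
                             cfg).fit(method=method)
        row = {"sample_id": curve.sample_id,
               "gamma1": res.params["gamma1"],
               "k1_per_day": res.params["k1"],
               "k2_per_day": res.params["k2"],
               "cost": res.cost}
        if res.posterior is not None:
            ci = res.conf_int()
            for p, out in (("gamma1", "gamma1"), ("k1", "k1_per_day"),
                           ("k2", "k2_per_day")):
                row[f"{out}_lo"] = ci.loc[p, "lower"]
                row[f"{out}_hi"] = ci.loc[p, "upper"]
            row["acceptance_rate"] = res.acceptance_rate
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_csv, index=False)
    return out_csv


def _analysis_table(horizon_csv: Path,
                    kinetics_csv: Path | None) -> pd.DataFrame:
    table = derive_ratio_columns(pd.read_csv(horizon_csv))
    if kinetics_csv is not None:
        kin = pd.read_csv(kinetics_csv).rename(columns={
            "k1_per_day": "k1", "k2_per_day": "k2"})
        table = table.drop(columns=[c for c in ("k1", "k2", "gamma1")
                                    if c in table.columns])
        table = table.merge(
            kin[["sample_id", "gamma1", "k1", "k2"]],
            left_on="horizon_id", right_on="sample_id", how="left")
    try:
        validate_horizon_table(table)
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc
    return table


def run_screen(horizon_csv: Path, out_csv: Path,
               kinetics_csv: Path | None = None) -> tuple[Path, dict]:
    table = _analysis_table(horizon_csv, kinetics_csv)
    frames, screens = [], {}
    for resp in RESPONSES:
        sc = screen_residuals(table, resp)
        screens[resp] = sc
        f = sc.table.copy()
        f.insert(0, "response", resp)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(out_csv, index=False)
    return out_csv, screens


def run_select(horizon_csv: Path, screens: dict, out_csv: Path,
               kinetics_csv: Path | None = None,
               max_terms: int = 12) -> tuple[Path, dict]:
    table = _analysis_table(horizon_csv, kinetics_csv)
    global_model = build_global_model(screens.values())
    terms = global_model.terms
    if len(terms) > max_terms:
        # keep the most strongly screened predictors (smallest best p-value)
        best_p = {}
        for sc in screens.values():
            for _, r in sc.table.iterrows():
                best_p[r["predictor"]] = min(
                    best_p.get(r["predictor"], 1.0), r["p"])
        terms = sorted(sorted(terms, key=lambda t: best_p.get(t, 1.0))
                       [:max_terms])
    exclusions = exclusion_pairs_from_correlation(table, terms)
    tables = {}
    frames = []
    for resp in RESPONSES:
        sel = select_models(table, resp, terms,
                            interactions=global_model.interactions,
                            exclusion_pairs=exclusions)
        tables[resp] = sel
        f = sel.table.copy()
        f.insert(0, "response", resp)
        f["terms"] = f["terms"].map(lambda t: " + ".join(t) or "(intercept)")
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(out_csv, index=False)
    return out_csv, tables


def run_cluster(horizon_csv: Path, out_dir: Path,
                kinetics_csv: Path | None = None) -> dict[str, Path]:
    table = _analysis_table(horizon_csv, kinetics_csv)
    out = {}
    for mode, fn in (("depth", cluster_depth_profile),
                     ("rainfall", cluster_rainfall_surface)):
        labels, summary = fn(table)
        lab_path = out_dir / f"cluster_{mode}_labels.csv"
        pd.DataFrame({"row": np.arange(len(labels)),
                      "cluster": labels}).to_csv(lab_path, index=False)
        sum_path = out_dir / f"cluster_{mode}_summary.csv"
        summary.to_csv(sum_path, index=False)
        out[f"{mode}_labels"] = lab_path
        out[f"{mode}_summary"] = sum_path
    return out


# -- full pipeline ----------------------------------------------------------

def run_all(out_dir: str | Path, seed: int = 0,
            config: dict | None = None,
            fit_iterations: int = 10_000,
            fit_burn_in: int = 2_000,
            fit_method: str = "two-step") -> RunManifest:
    """Run the whole analysis on a fresh synthetic landscape.

    Writes all stage outputs plus ``manifest.json`` and ``report.txt``
    (the top models, delta AICc <= 2, per response) into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or {}
    timings: dict[str, float] = {}
    outputs: dict[str, Path] = {}

    def stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kw)
        except ValidationError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    sim = stage("simulate", run_simulate, out_dir, seed, config)
    outputs.update(sim)
    outputs["curves"] = stage(
        "flux", run_flux, sim["chambers"], out_dir / "curves.csv")
    outputs["kinetics"] = stage(
        "fit", run_fit, outputs["curves"], sim["horizon_table"],
        out_dir / "kinetics.csv", seed=seed + 1,
        iterations=fit_iterations, burn_in=fit_burn_in, method=fit_method)
    screen_path, screens = stage(
        "screen", run_screen, sim["horizon_table"], out_dir / "screen.csv",
        kinetics_csv=outputs["kinetics"])
    outputs["screen"] = screen_path
    select_path, selections = stage(
        "select", run_select, sim["horizon_table"], screens,
        out_dir / "selection.csv", kinetics_csv=outputs["kinetics"])
    outputs["selection"] = select_path
    outputs.update(stage("cluster", run_cluster, sim["horizon_table"],
                         out_dir, kinetics_csv=outputs["kinetics"]))

    report = ["socpools run report", "=" * 40]
    for resp, sel in selections.items():
        report.append(f"\nTop models for {resp} (delta AICc <= 2):")
        for _, r in sel.top().iterrows():
            terms = " + ".join(r["terms"]) or "(intercept)"
            report.append(
                f"  AICc {r['aicc']:8.1f}  R2m {r['r2m']:.3f}  "
                f"R2c {r['r2c']:.3f}  {terms}")
    report_path = out_dir / "report.txt"
    report_path.write_text("\n".join(report) + "\n")
    outputs["report"] = report_path

    manifest = RunManifest(
        config={**config, "fit_iterations": fit_iterations,
                "fit_burn_in": fit_burn_in, "fit_method": fit_method},
        seed=seed,
        inputs={k: _sha256(p) for k, p in
                (("horizon_table", sim["horizon_table"]),
                 ("chambers", sim["chambers"]))},
        outputs={k: str(p) for k, p in outputs.items()},
        timings=timings,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
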