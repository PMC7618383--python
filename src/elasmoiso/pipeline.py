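"""End-to-end orchestration: config, staging, logging and report bundles.

``run_all`` wires the library stages together over files: (optional)
synthetic simulation → raw-measurement calibration → seasonal envelopes and
isoscapes per CO2 case → CO2-case validation against serial bivalves →
Bayesian temperature inversion per taxon → summary statistics, rank tests
and habitat classification. Every run writes a resolved copy of its config
and a log with versions and seeds next to the outputs, and reruns with the
same config and seeds are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, bayes, climate, habitat, isotopes, synthetic, validation

__all__ = ["RunConfig", "PipelineError", "run_all"]

log = logging.getLogger("elasmoiso")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and input fingerprint."""

    def __init__(self, stage: str, fingerprint: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {fingerprint}: {cause}")
        self.stage = stage
        self.fingerprint = fingerprint


@dataclass
class RunConfig:
    """Schema-validated settings for an end-to-end run."""

    output_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    co2_cases: tuple[str, ...] = ("3x", "6x")
    reference_case: str = "3x"
    measurements_path: str | None = None
    grid_paths: dict = field(default_factory=dict)  # co2_case -> path
    bivalve_path: str | None = None
    site: dict = field(default_factory=lambda: {
        "name": climate.SEYMOUR_ISLAND.name,
        "lat_bounds": list(climate.SEYMOUR_ISLAND.lat_bounds),
        "lon_bounds": list(climate.SEYMOUR_ISLAND.lon_bounds),
    })
    region: dict = field(default_factory=lambda: {
        "name": "Drake sector",
        "lat_bounds": [-75.0, -50.0],
        "lon_bounds": [-80.0, -40.0],
    })
    thresholds: dict = field(default_factory=dict)
    envelope_tolerance: float = 0.0
    noise_sd: float = 0.3
    min_n_inversion: int = 4
    sampler: dict = field(default_factory=lambda: {
        "n_walkers": 12,
        "n_steps": 600,
        "n_warmup": 200,
    })
    prior_n_draws: int = 500

    def __post_init__(self) -> None:
        if self.reference_case not in self.co2_cases:
            raise ValueError("reference_case must be among co2_cases")
        if not self.simulate:
            missing = [c for c in self.co2_cases if c not in self.grid_paths]
            if missing:
                raise ValueError(f"grid_paths missing for cases {missing}")
            for what, p in (("measurements", self.measurements_path),
                            ("bivalves", self.bivalve_path)):
                if p is None:
                    raise ValueError(f"{what} path required when simulate is off")
                if not Path(p).exists():
                    raise ValueError(f"{what} path does not exist: {p}")
            for case, p in self.grid_paths.items():
                if not Path(p).exists():
                    raise ValueError(f"grid path for {case!r} does not exist: {p}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "co2_cases" in d:
            d["co2_cases"] = tuple(d["co2_cases"])
        return cls(**d)

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["co2_cases"] = list(d["co2_cases"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _stage(name: str, fingerprint: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with context
            raise PipelineError(name, fingerprint, exc) from exc
        log.info("stage %-14s done in %.2fs", name, time.perf_counter() - t0)
        return out

    return wrap


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a report dict mirroring the files written."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "resolved_config.json")
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    log.info("elasmoiso %s run, seed %d", __version__, config.seed)

    site = climate.SiteSpec.from_dict(config.site)
    region = climate.SiteSpec.from_dict(config.region)
    report: dict = {"version": __version__, "seed": config.seed}

    # --- simulate or load inputs --------------------------------------------
    grids: dict[str, climate.ClimateGrid] = {}
    if config.simulate:
        for i, case in enumerate(config.co2_cases):
            grids[case] = _stage("simulate", f"case={case}")(
                synthetic.make_climate_grid, case, seed=config.seed + i
            )
    else:
        for case in config.co2_cases:
            grids[case] = _stage("load-grid", config.grid_paths[case])(
                climate.load_grid, config.grid_paths[case], case
            )

    envelopes = {
        case: _stage("envelope", f"case={case}")(
            climate.extract_site_series, grids[case], site
        )
        for case in config.co2_cases
    }
    env_rows = []
    for case, env in envelopes.items():
        env_rows.append({"co2_case": case, **env.summary()})
    pd.DataFrame(env_rows).to_csv(out / "envelopes.csv", index=False)
    report["envelopes"] = env_rows

    ref_env = envelopes[config.reference_case]

    if config.simulate:
        scen = synthetic.default_scenarios()
        measurements = _stage("simulate", "teeth")(
            synthetic.make_tooth_dataset, scen, ref_env, config.seed
        )
        with open(out / "fixture_manifest.json", "w") as fh:
            json.dump(synthetic.scenario_manifest(scen, config.seed), fh, indent=2)
        bivalves = [
            _stage("simulate", "bivalves")(
                synthetic.make_bivalve_series,
                ref_env,
                None if k % 2 == 0 else [5, 6, 7, 8, 9, 10],
                12,
                2,
                0.1,
                config.seed + 100 + k,
                f"SYN-{k:02d}",
                "Cucullaea" if k % 2 else "Retrotapes",
            )
            for k in range(4)
        ]
    else:
        measurements = _stage("load", config.measurements_path)(
            pd.read_csv, config.measurements_path
        )
        bdf = _stage("load", config.bivalve_path)(pd.read_csv, config.bivalve_path)
        bivalves = validation.BivalveSeries.from_frame(bdf)

    measurements.to_csv(out / "measurements.csv", index=False)

    # --- isoscapes -----------------------------------------------------------
    iso_rows = []
    for case in config.co2_cases:
        _, summ = _stage("isoscape", f"case={case}")(
            climate.isoscape, grids[case], region
        )
        iso_rows.append(summ)
    pd.DataFrame(iso_rows).to_csv(out / "isoscape_summary.csv", index=False)
    report["isoscapes"] = iso_rows

    # --- CO2-case validation -------------------------------------------------
    fit = _stage("validate-case", f"{len(bivalves)} shells")(
        validation.envelope_fit, bivalves, envelopes, config.envelope_tolerance
    )
    fit.to_frame().to_csv(out / "case_fit.csv", index=False)
    report["selected_case"] = fit.selected_case
    report["case_fractions"] = fit.fractions

    # --- bivalve transposition ----------------------------------------------
    bulk = np.concatenate([b.d18Oc for b in bivalves])
    transposed, tsummary = _stage("transpose", "bulk bivalves")(
        validation.transpose_bulk_bivalves, bulk
    )
    report["bivalve_d18Op_equiv"] = tsummary

    # --- inversion per taxon -------------------------------------------------
    prior = _stage("prior", f"case={fit.selected_case}")(
        bayes.build_prior, grids[fit.selected_case], region,
        None, config.prior_n_draws, config.seed,
    )
    cfg = bayes.SamplerConfig(seed=config.seed, **config.sampler)
    inv_rows = []
    draws_frames = []
    for taxon, g in measurements.groupby("taxon", sort=True):
        if g.shape[0] < config.min_n_inversion:
            continue
        summary = _stage("invert", f"taxon={taxon}")(
            bayes.infer_temperature, g["d18Op"].to_numpy(), prior,
            config.noise_sd, False, False, cfg, str(taxon),
        )
        inv_rows.append(
            {
                "taxon": taxon,
                "n": summary.n_measurements,
                "mean_T": summary.posterior_mean_T,
                "ci_lo": summary.ci95[0],
                "ci_hi": summary.ci95[1],
                "rhat": summary.rhat,
                "ess": summary.ess,
                "converged": summary.converged,
            }
        )
        draws_frames.append(
            pd.DataFrame({"taxon": taxon, "draw": summary.posterior_draws})
        )
    pd.DataFrame(inv_rows).to_csv(out / "inversion.csv", index=False)
    if draws_frames:
        pd.concat(draws_frames).to_csv(out / "posterior_draws.csv", index=False)
    report["inversion"] = inv_rows

    # --- stats and classification -------------------------------------------
    telm_groups = [g["d18Op"].to_numpy() for _, g in measurements.groupby("telm")]
    telm_labels = [str(t) for t in sorted(measurements["telm"].unique())]
    if len(telm_groups) >= 2:
        h, df_, p = _stage("compare", "telms")(habitat.kruskal_wallis, telm_groups)
        report["kruskal_wallis_telm"] = {"H": h, "df": df_, "p": p}
        dunn = habitat.dunn_posthoc(telm_groups, labels=telm_labels)
        dunn.to_csv(out / "dunn_telm.csv", index=False)
    summary_telm = habitat.summarize_by(measurements, ["telm"])
    summary_telm.to_csv(out / "summary_telm.csv", index=False)
    habitat.summarize_by(measurements, ["telm", "guild"]).to_csv(
        out / "summary_telm_guild.csv", index=False
    )
    guild = _stage("compare", "guilds")(habitat.guild_compare, measurements)
    guild.to_csv(out / "guild_compare.csv", index=False)
    outl = habitat.flag_outliers(measurements["d18Op"])
    outl.to_csv(out / "outliers.csv", index=False)
    report["n_outliers"] = int(outl["outlier"].sum())

    th = habitat.ClassifierThresholds(**config.thresholds)
    biv_median = tsummary.get("median", float("nan"))
    calls = []
    for (taxon, telm), g in measurements.groupby(["taxon", "telm"], sort=True):
        call = _stage("classify", f"{taxon}/T{telm}")(
            habitat.classify_habitat_use, g["d18Op"].to_numpy(), ref_env,
            biv_median, None, th, str(taxon), int(telm),
        )
        calls.append(dataclasses.asdict(call))
    pd.DataFrame(calls).to_csv(out / "habitat_calls.csv", index=False)
    report["habitat_calls"] = calls

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    log.info("pipeline complete: %s", out)
    return report
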