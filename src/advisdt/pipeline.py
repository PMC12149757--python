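"""End-to-end orchestration: simulate -> tabulate -> fit -> metrics -> report.

Every stage draws its randomness from a seed derived from the master seed by
numpy's SeedSequence spawn-key rule (stage k uses
``SeedSequence(master, spawn_key=(k,))``), so stages can be re-run in
isolation and the whole run is reproducible.  All produced files are listed
in a JSON manifest with content hashes, stage timings and convergence flags.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tabio
from .config import CONDITIONS, ExperimentConfig, ProfileDistribution
from .counts import drop_degenerate_cells, tabulate_counts
from .reliance import contingency_table
from .sdt import SDTModelSpec, dprime_difference, fit_hierarchical_sdt, posterior_summary
from .selfreport import RegressionSpec, fit_mixed_regression
from .simulate import simulate_experiment

# MCMC sizes for the two named run profiles
PROFILES = {
    "full": {"chains": 4, "draws": 10_000, "tune": 2_000},
    "reduced": {"chains": 4, "draws": 2_000, "tune": 500},
}

STAGES = ("simulate", "fit-sdt", "metrics", "fit-selfreport", "report")


def stage_seed(master_seed: int, stage: str) -> int:
    k = STAGES.index(stage)
    ss = np.random.SeedSequence(master_seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    master_seed: int
    profile: str
    config: dict
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)       # path -> sha256
    timings: dict = field(default_factory=dict)       # stage -> seconds
    convergence: dict = field(default_factory=dict)   # fit name -> bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: RunManifest, out_dir: Path, path: Path) -> None:
    manifest.outputs[str(path.relative_to(out_dir))] = _sha256(path)


def _save_posterior(post, dirpath: Path) -> list[Path]:
    """Store draws as one .npy per parameter (byte-deterministic for a seed)."""
    dirpath.mkdir(parents=True, exist_ok=True)
    arrays = {
        "participant_ids": post.participant_ids,
        "conditions": post.conditions,
        "strata": post.strata,
        "cell_labels": np.array([f"{c}|{s}" for c, s in post.cell_labels]),
        "d": post.d.astype(np.float32), "c": post.c.astype(np.float32),
        "d_mu": post.d_mu, "c_mu": post.c_mu,
        "lambda_d": post.lambda_d, "lambda_c": post.lambda_c,
    }
    paths = []
    for name, arr in arrays.items():
        p = dirpath / f"{name}.npy"
        np.save(p, arr)
        paths.append(p)
    return paths


def run_pipeline(
    config: ExperimentConfig | None = None,
    dist: ProfileDistribution | None = None,
    out_dir: str | Path = "advisdt_run",
    seed: int = 0,
    profile: str = "full",
) -> RunManifest:
    """Run the complete analysis on a synthetic cohort and write all outputs."""
    if config is None:
        config = ExperimentConfig()
    if dist is None:
        dist = ProfileDistribution()
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; options: {sorted(PROFILES)}")
    mcmc = PROFILES[profile]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(master_seed=seed, profile=profile,
                           config=json.loads(config.model_dump_json()))
    for s in STAGES:
        manifest.stage_seeds[s] = stage_seed(seed, s)

    # ---- stage 1: simulate ----
    t0 = time.perf_counter()
    trials, reports, profiles = simulate_experiment(
        config, dist, manifest.stage_seeds["simulate"])
    tabio.write_trials(trials, out / "trials.csv")
    tabio.write_reports(reports, out / "reports.csv")
    sidecar = {
        "config": manifest.config,
        "seed": manifest.stage_seeds["simulate"],
        "profiles": [p.to_dict() for p in profiles],
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    for name in ("trials.csv", "reports.csv", "ground_truth.json"):
        _register(manifest, out, out / name)
    manifest.timings["simulate"] = time.perf_counter() - t0

    # ---- stage 2: SDT fits ----
    t0 = time.perf_counter()
    sdt_seed = manifest.stage_seeds["fit-sdt"]
    fits = {}
    for i, (name, session, grouping) in enumerate([
        ("session1", 1, "all"),
        ("session2_overall", 2, "all"),
        ("session2_phase", 2, "phase"),
        ("session2_advice", 2, "advice"),
    ]):
        counts = tabulate_counts(trials[trials["session"] == session], grouping)
        if grouping != "all":
            counts = drop_degenerate_cells(counts)
        spec = SDTModelSpec(seed=(sdt_seed + i) % 2**31, **mcmc)
        post = fit_hierarchical_sdt(counts, spec)
        fits[name] = post
        post.summary().to_csv(out / f"sdt_{name}_summary.csv", index=False)
        draw_files = _save_posterior(post, out / f"sdt_{name}_draws")
        manifest.convergence[f"sdt_{name}"] = post.converged
        _register(manifest, out, out / f"sdt_{name}_summary.csv")
        for p in draw_files:
            _register(manifest, out, p)

    diff_summaries = []
    for variant, fit_name in [("overall", "session2_overall"),
                              ("advice-correct", "session2_advice"),
                              ("advice-incorrect", "session2_advice")]:
        diff = dprime_difference(fits[fit_name], fits["session1"], variant)
        diff_summaries.append(diff.summary())
    pd.concat(diff_summaries, ignore_index=True).to_csv(
        out / "dprime_differences.csv", index=False)
    _register(manifest, out, out / "dprime_differences.csv")
    manifest.timings["fit-sdt"] = time.perf_counter() - t0

    # ---- stage 3: reliance metrics ----
    t0 = time.perf_counter()
    s1 = trials[trials["session"] == 1]
    s2 = trials[trials["session"] == 2]
    table = contingency_table(s2, s1, ["advice_correct", "condition"])
    table.to_csv(out / "reliance_tables.csv", index=False)
    _register(manifest, out, out / "reliance_tables.csv")
    manifest.timings["metrics"] = time.perf_counter() - t0

    # ---- stage 4: self-report regressions ----
    t0 = time.perf_counter()
    sr_seed = manifest.stage_seeds["fit-selfreport"]
    regressions = {}
    for i, item in enumerate(("trust", "distrust")):
        spec = RegressionSpec(item=item, seed=(sr_seed + i) % 2**31, **mcmc)
        post = fit_mixed_regression(reports, spec)
        regressions[item] = post
        post.summary().to_csv(out / f"selfreport_{item}_summary.csv", index=False)
        manifest.convergence[f"selfreport_{item}"] = post.converged
        _register(manifest, out, out / f"selfreport_{item}_summary.csv")
    manifest.timings["fit-selfreport"] = time.perf_counter() - t0

    # ---- stage 5: report ----
    t0 = time.perf_counter()
    report_text = render_report(fits, diff_summaries, table, regressions)
    (out / "report.txt").write_text(report_text)
    _register(manifest, out, out / "report.txt")
    manifest.timings["report"] = time.perf_counter() - t0

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def render_report(fits, diff_summaries, reliance_table, regressions) -> str:
    """Human-readable posterior means and 95% HDIs for every stage."""
    lines = ["Advised-classification analysis report", "=" * 40, ""]

    lines.append("Group-level sensitivity d' (posterior mean [95% HDI])")
    for name, post in fits.items():
        lines.append(f"  {name}:")
        for cond, stratum in post.cell_labels:
            m, (lo, hi) = posterior_summary(post.group_draws(cond, stratum, "d_mu"))
            lines.append(f"    {cond:17s} {stratum:10s} {m:6.2f}  [{lo:5.2f}, {hi:5.2f}]")
    lines.append("")

    lines.append("d' differences, advised minus unadvised (cohort mean per condition)")
    for summ in diff_summaries:
        variant = summ["variant"].iloc[0]
        for cond in CONDITIONS:
            sub = summ[summ["condition"] == cond]
            lines.append(f"  {variant:16s} {cond:17s} mean of participant means "
                         f"{sub['mean'].mean():6.2f}")
    lines.append("")

    lines.append("Reliance contingency tables (counts; rate = yes / (yes + not))")
    for _, row in reliance_table.iterrows():
        pct = "undefined" if pd.isna(row["rate"]) else f"{100 * row['rate']:.2f}%"
        lines.append(
            f"  {row['metric']:10s} advice_correct={row['advice_correct']:6s} "
            f"condition={row['condition']:17s} "
            f"not={row['n_not']:6d} yes={row['n_yes']:6d} rate={pct}")
    lines.append("")

    lines.append("Self-report mixed regressions (Estimate [95% CI])")
    for item, post in regressions.items():
        lines.append(f"  {item}:")
        for _, row in post.summary().iterrows():
            lines.append(f"    {row['coefficient']:28s} {row['Estimate']:6.2f} "
                         f"[{row['l-95% CI']:6.2f}, {row['u-95% CI']:6.2f}]")
    lines.append("")
    return "\n".join(lines)
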