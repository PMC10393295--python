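"""End-to-end orchestration: generate -> preprocess -> iCSD -> canonical ->
WD / spike metrics -> model evaluation -> report.

Every stage is a plain function over a :class:`~lamcsd.config.RunConfig`
and an output directory, so the CLI subcommands and ``run_pipeline`` share
one implementation.  All randomness descends from ``config.seed`` through
per-animal seeds recorded in the manifest.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .canonical import pca_canonical, stack_cohort
from .config import RunConfig
from .core import CSDPattern, GridPattern, UnitTable, derive_rng
from .csd_metrics import (
    normalize_wd,
    pairwise_wd,
    trial_vs_animal_variability,
    wd_csd,
)
from .icsd import build_forward, delta_icsd
from .laminar_model import SimResult, build_default_network, simulate
from .preprocess import (
    baseline_subtract,
    crop_window,
    interpolate_grid,
    lowpass_filter,
    select_channels,
    trial_average,
)
from .spike_metrics import (
    WindowSet,
    classify_units,
    ks_similarity,
    leave_one_out_compare,
    outlier_assessment,
    population_rate,
    rate_correlation,
    PopulationRate,
    POPULATIONS,
    _population_units,
)
from .synthetic import (
    DEFAULT_COMPONENTS,
    VariabilitySpec,
    default_population_specs,
    filter_cohort,
    generate_cohort_manifest,
    synth_ground_truth_csd,
    synth_lfp_trials,
    synth_spike_cohort,
)

log = logging.getLogger("lamcsd.pipeline")

#: Model population -> cohort analysis population.
MODEL_POPULATION_MAP = {
    "E2/3": "RS L2/3", "E4": "RS L4", "E5": "RS L5", "E6": "RS L6",
}


def variability_from_config(cfg: RunConfig) -> VariabilitySpec:
    return VariabilitySpec(
        animal_latency_sd=cfg.animal_latency_sd_ms,
        animal_depth_sd=cfg.animal_depth_sd_um,
        animal_amplitude_cv=cfg.animal_amplitude_cv,
        trial_noise_sd=cfg.trial_noise_sd_uv,
        gamma_period=cfg.gamma_period_ms,
        gamma_amplitude=cfg.gamma_amplitude_uv,
    )


def _time_axis(cfg: RunConfig) -> np.ndarray:
    """Sample-aligned truth/analysis time axis covering [-250, 250) ms."""
    fs = cfg.lfp_fs_hz
    return np.arange(int(round(-0.25 * fs)), int(round(0.25 * fs))) / fs * 1e3


def windows_from_config(cfg: RunConfig) -> WindowSet:
    return WindowSet(
        baseline=cfg.baseline_window_ms,
        peak=cfg.peak_window_ms,
        sustained=cfg.sustained_window_ms,
    )


# --------------------------------------------------------------------------
# per-animal CSD branch
# --------------------------------------------------------------------------


def synth_animal_recording(cfg: RunConfig, animal_seed: int, n_trials: int | None = None):
    """Ground truth and surrogate recording for one animal."""
    depths = cfg.electrode_depths()
    tax = _time_axis(cfg)
    truth = synth_ground_truth_csd(
        DEFAULT_COMPONENTS, depths, tax,
        animal_jitter=variability_from_config(cfg), seed=animal_seed,
    )
    op = build_forward(depths, R=cfg.icsd_radius_um, sigma=cfg.conductivity_s_per_m)
    rec = synth_lfp_trials(
        truth, depths, n_trials or cfg.pipeline_csd_trials,
        variability_from_config(cfg), op, seed=animal_seed, fs=cfg.lfp_fs_hz,
    )
    return truth, rec


def preprocess_recording(cfg: RunConfig, rec) -> GridPattern:
    """Filter, spatially downsample and trial-average one recording."""
    rec = lowpass_filter(rec, cutoff=cfg.lowpass_cutoff_hz, order=cfg.filter_order)
    rec = select_channels(rec, target_pitch=cfg.target_pitch_um)
    tax = _time_axis(cfg)
    avg = trial_average(rec, (tax[0], tax[-1] + 1e3 / cfg.lfp_fs_hz))
    if cfg.baseline_subtract:
        avg = baseline_subtract(avg, cfg.baseline_window_ms)
    return avg


def lfp_to_pattern(cfg: RunConfig, avg: GridPattern) -> CSDPattern:
    """Inverse CSD on the analysis window, interpolated to the common grid."""
    op = build_forward(
        avg.depth_axis, R=cfg.icsd_radius_um, sigma=cfg.conductivity_s_per_m
    )
    csd = delta_icsd(op, avg)
    return interpolate_grid(
        crop_window(csd, cfg.analysis_window_ms), M=cfg.grid_m, K=cfg.grid_k
    )


def animal_csd_pattern(cfg: RunConfig, animal_seed: int) -> CSDPattern:
    _, rec = synth_animal_recording(cfg, animal_seed)
    return lfp_to_pattern(cfg, preprocess_recording(cfg, rec))


def single_trial_patterns(
    cfg: RunConfig, animal_seed: int, n_trials: int
) -> list[CSDPattern]:
    """Single-trial CSD patterns (same chain without trial averaging)."""
    _, rec = synth_animal_recording(cfg, animal_seed, n_trials=n_trials)
    rec = lowpass_filter(rec, cutoff=cfg.lowpass_cutoff_hz, order=cfg.filter_order)
    rec = select_channels(rec, target_pitch=cfg.target_pitch_um)
    out = []
    for k in range(n_trials):
        one = replace(rec, trial_onsets=rec.trial_onsets[k : k + 1])
        tax = _time_axis(cfg)
        avg = trial_average(one, (tax[0], tax[-1] + 1e3 / cfg.lfp_fs_hz))
        if cfg.baseline_subtract:
            avg = baseline_subtract(avg, cfg.baseline_window_ms)
        out.append(lfp_to_pattern(cfg, avg))
    return out


# --------------------------------------------------------------------------
# spike branch
# --------------------------------------------------------------------------


def synth_animal_spikes(cfg: RunConfig, animal_id: str, animal_seed: int) -> UnitTable:
    """Per-animal spike table with mild animal-level rate jitter."""
    rng = derive_rng(animal_seed, 51)
    specs = []
    for spec in default_population_specs(cfg.spike_units_per_population):
        gain = float(rng.lognormal(0.0, 0.15))
        specs.append(
            replace(
                spec,
                baseline_rate=spec.baseline_rate * gain,
                peak_rate=spec.peak_rate * gain,
                sustained_rate=spec.sustained_rate * gain,
            )
        )
    table = synth_spike_cohort(specs, cfg.n_trials, seed=animal_seed, animal_id=animal_id)
    return classify_units(table)


# --------------------------------------------------------------------------
# pipeline stages
# --------------------------------------------------------------------------


def stage_generate(cfg: RunConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = generate_cohort_manifest(
        cfg.n_animals, cfg.n_missing_lfp, cfg.n_bad_probe, cfg.n_no_units,
        cfg.n_trials, cfg.seed,
    )
    io.save_manifest(outdir / "manifest.csv", manifest)
    csd_animals = filter_cohort(manifest, "csd")
    spike_animals = filter_cohort(manifest, "spikes")[: cfg.pipeline_spike_animals]
    seeds = {m.animal_id: m.seed for m in manifest}
    spikes_dir = outdir / "spikes"
    spikes_dir.mkdir(exist_ok=True)
    for aid in spike_animals:
        io.save_spikes(spikes_dir / f"{aid}.csv", synth_animal_spikes(cfg, aid, seeds[aid]))
    log.info("generate: %d animals (%d csd, %d spike tables)",
             len(manifest), len(csd_animals), len(spike_animals))
    return {
        "n_animals": len(manifest),
        "csd_retained": csd_animals,
        "spike_retained": filter_cohort(manifest, "spikes"),
        "spike_tables": spike_animals,
    }


def stage_preprocess(cfg: RunConfig, outdir: Path) -> list[str]:
    manifest = io.load_manifest(outdir / "manifest.csv")
    seeds = {m.animal_id: m.seed for m in manifest}
    csd_animals = filter_cohort(manifest, "csd")
    avg_dir = outdir / "avg_lfp"
    avg_dir.mkdir(exist_ok=True)
    for aid in csd_animals:
        _, rec = synth_animal_recording(cfg, seeds[aid])
        io.save_pattern(avg_dir / f"{aid}.h5", preprocess_recording(cfg, rec))
    log.info("preprocess: %d trial-averaged LFP grids", len(csd_animals))
    return csd_animals


def stage_csd(cfg: RunConfig, outdir: Path) -> list[str]:
    avg_dir = outdir / "avg_lfp"
    csd_dir = outdir / "csd"
    csd_dir.mkdir(exist_ok=True)
    animals = sorted(p.stem for p in avg_dir.glob("*.h5"))
    for aid in animals:
        avg = io.load_pattern(avg_dir / f"{aid}.h5")
        io.save_pattern(csd_dir / f"{aid}.h5", lfp_to_pattern(cfg, avg))
    log.info("csd: %d patterns on the %dx%d grid", len(animals), cfg.grid_m, cfg.grid_k)
    return animals


def load_cohort_patterns(outdir: Path) -> dict[str, CSDPattern]:
    csd_dir = outdir / "csd"
    return {p.stem: io.load_pattern(p) for p in sorted(csd_dir.glob("*.h5"))}


def stage_canonical(cfg: RunConfig, outdir: Path) -> dict:
    patterns = load_cohort_patterns(outdir)
    matrix = stack_cohort(patterns)
    template = next(iter(patterns.values()))
    canon = pca_canonical(matrix, template)
    io.save_pattern(outdir / "canonical_pc1.h5", canon.pc1)
    io.save_pattern(outdir / "cohort_mean.h5", canon.cohort_mean)
    pd.DataFrame(
        {"component": np.arange(1, canon.explained_variance_ratio.size + 1),
         "explained_variance_ratio": canon.explained_variance_ratio}
    ).to_csv(outdir / "explained_variance.csv", index=False)
    pd.DataFrame({"animal_id": list(patterns), "loading": canon.loadings}).to_csv(
        outdir / "loadings.csv", index=False
    )
    log.info("canonical: PC1 explains %.1f%% of variance",
             100 * canon.explained_variance_ratio[0])
    return {
        "explained_variance_ratio": canon.explained_variance_ratio.tolist(),
        "stack_shape": list(matrix.shape),
    }


def stage_compare(cfg: RunConfig, outdir: Path, with_trials: bool = True) -> dict:
    patterns = load_cohort_patterns(outdir)
    pc1 = io.load_pattern(outdir / "canonical_pc1.h5")
    mat, condensed = pairwise_wd(patterns, depth_weight=cfg.depth_weight)
    mat.to_csv(outdir / "wd_pairwise.csv")
    wd_to_pc1 = {
        aid: wd_csd(p, pc1, depth_weight=cfg.depth_weight).wd_total
        for aid, p in patterns.items()
    }
    ref = np.array(list(wd_to_pc1.values()))
    norm = normalize_wd(ref, ref)
    pd.DataFrame(
        {"animal_id": list(wd_to_pc1), "wd_to_pc1": ref, "normalized": norm}
    ).to_csv(outdir / "wd_to_pc1.csv", index=False)

    summary = {
        "n_patterns": len(patterns),
        "n_pairwise": int(condensed.size),
        "max_pairwise_wd": float(condensed.max()),
        "frac_below_half_max_pairwise": float(
            np.mean(condensed < 0.5 * condensed.max())
        ),
        "frac_below_half_max_to_pc1": float(np.mean(norm < 0.5)),
    }

    if with_trials and cfg.pipeline_trial_wd_subset >= 2:
        manifest = io.load_manifest(outdir / "manifest.csv")
        seeds = {m.animal_id: m.seed for m in manifest}
        trial_wds: dict[str, np.ndarray] = {}
        for aid in patterns:
            trials = single_trial_patterns(cfg, seeds[aid], cfg.pipeline_trial_wd_subset)
            _, tcond = pairwise_wd(trials, depth_weight=cfg.depth_weight)
            trial_wds[aid] = tcond
        ks = trial_vs_animal_variability(trial_wds, condensed)
        ks.to_csv(outdir / "trial_variability.csv", index=False)
        pooled = ks[ks["animal_id"] == "pooled"].iloc[0]
        summary["trial_vs_animal_ks"] = float(pooled["ks_statistic"])
        summary["n_trial_variable_animals"] = int(
            ks.loc[ks["animal_id"] != "pooled", "trials_more_variable"].sum()
        )
    io.save_json(outdir / "wd_summary.json", summary)
    return summary


def stage_spikes(cfg: RunConfig, outdir: Path) -> dict:
    spikes_dir = outdir / "spikes"
    cohort = {
        p.stem: io.load_spikes(p, n_trials=cfg.n_trials)
        for p in sorted(spikes_dir.glob("*.csv"))
    }
    cohort = {a: classify_units(t) for a, t in cohort.items()}
    windows = windows_from_config(cfg)
    ks = leave_one_out_compare(cohort, "ks", windows, min_cells=cfg.min_cells)
    corr = leave_one_out_compare(cohort, "corr", windows, min_cells=cfg.min_cells)
    ks.to_csv(outdir / "spike_ks.csv", index=False)
    corr.to_csv(outdir / "spike_corr.csv", index=False)
    summary = {"n_spike_animals": len(cohort)}
    for pop in POPULATIONS:
        sub = ks[ks["population"] == pop]
        if len(sub):
            summary[pop] = {
                "KSS_b": float(sub["ks_baseline"].mean()),
                "KSS_p": float(sub["ks_peak"].mean()),
                "KSS_s": float(sub["ks_sustained"].mean()),
            }
        subc = corr[corr["population"] == pop]
        if len(subc):
            summary.setdefault(pop, {})["r"] = float(subc["r"].mean())
    io.save_json(outdir / "spike_summary.json", summary)
    return summary


def model_csd_pattern(cfg: RunConfig, result: SimResult) -> CSDPattern:
    """Evoked model CSD on the analysis grid: the pre-onset deposit (constant
    background drive) is subtracted before cropping, mirroring the evoked
    (baseline-referenced) cohort patterns."""
    pat = result.csd_pattern()
    t0 = max(pat.time_axis[0], -50.0)
    if (pat.time_axis < 0).sum() >= 2:
        pat = baseline_subtract(pat, (t0, 0.0))
    return interpolate_grid(
        crop_window(pat, cfg.analysis_window_ms), M=cfg.grid_m, K=cfg.grid_k
    )


def model_population_rates(result: SimResult) -> dict[str, PopulationRate]:
    """Map simulated population rates onto the cohort analysis populations,
    resampled to the 1 ms rate grid on [-250, 250) ms."""
    t_target = np.arange(-250.0, 250.0, 1.0) + 0.5
    out = {}
    def resample(r):
        return np.interp(t_target, result.time_axis, r, left=r[0], right=r[-1])
    for model_pop, pop in MODEL_POPULATION_MAP.items():
        out[pop] = PopulationRate(pop, t_target, resample(result.rates[model_pop]))
    i_pops = [p for p in result.rates if p.startswith("I")]
    fs_rate = np.mean([result.rates[p] for p in i_pops], axis=0)
    out["FS"] = PopulationRate("FS", t_target, resample(fs_rate))
    return out


def stage_simulate(cfg: RunConfig, outdir: Path, presets=("original", "final")) -> dict:
    model_dir = outdir / "model"
    model_dir.mkdir(exist_ok=True)
    info = {}
    for preset in presets:
        net = build_default_network(preset)
        res = simulate(net, seed=cfg.seed)
        pat = model_csd_pattern(cfg, res)
        io.save_pattern(model_dir / f"{preset}_csd.h5", pat)
        rates = model_population_rates(res)
        pd.DataFrame(
            {"t_ms": next(iter(rates.values())).t_ms,
             **{pop: r.rate for pop, r in rates.items()}}
        ).to_csv(model_dir / f"{preset}_rates.csv", index=False)
        info[preset] = {"peak_rates": {p: float(r.max()) for p, r in res.rates.items()}}
    return info


def evaluate_model_against_cohort(
    model_pattern: CSDPattern,
    model_rates: dict[str, PopulationRate] | None,
    cohort: dict,
    cfg: RunConfig | None = None,
) -> dict:
    """Score a model pattern (and optionally rates) against cohort artifacts.

    ``cohort`` needs ``pc1`` and ``mean`` patterns plus ``wd_to_pc1`` (raw
    per-animal WDs).  Optional rate scoring needs ``rates`` (cohort-average
    PopulationRate per population) and the leave-one-out score tables
    ``loo_ks`` / ``loo_corr`` for outlier assessment.  Model rates are
    compared after a single global gain fit (the rate model is in arbitrary
    units); correlations are gain-free.
    """
    cfg = cfg or RunConfig()
    if model_pattern.shape != (cfg.grid_m, cfg.grid_k):
        model_pattern = interpolate_grid(model_pattern, cfg.grid_m, cfg.grid_k)
    pc1 = cohort["pc1"]
    ref = np.asarray(cohort["wd_to_pc1"], dtype=float)
    wd = wd_csd(model_pattern, pc1, depth_weight=cfg.depth_weight).wd_total
    out = {
        "wd_to_pc1": float(wd),
        "normalized_wd_to_pc1": float(normalize_wd([wd], ref)[0]),
        "wd_outlier": outlier_assessment(
            float(normalize_wd([wd], ref)[0]), normalize_wd(ref, ref)
        ),
    }
    if "mean" in cohort:
        wdm = wd_csd(model_pattern, cohort["mean"], depth_weight=cfg.depth_weight).wd_total
        out["wd_to_mean"] = float(wdm)

    if model_rates is not None and "rates" in cohort:
        windows = windows_from_config(cfg)
        # global gain: least squares over all populations' analysis windows
        num = den = 0.0
        for pop, mr in model_rates.items():
            cr = cohort["rates"].get(pop)
            if cr is None:
                continue
            mask = (mr.t_ms >= 0) & (mr.t_ms <= 100)
            num += float(mr.rate[mask] @ cr.rate[mask])
            den += float(mr.rate[mask] @ mr.rate[mask])
        gain = num / den if den > 0 else 1.0
        out["rate_gain"] = gain
        rate_scores = {}
        for pop, mr in model_rates.items():
            cr = cohort["rates"].get(pop)
            if cr is None:
                continue
            entry = {}
            try:
                entry["r"] = rate_correlation(mr, cr, (0.0, 100.0))
            except Exception:
                entry["r"] = float("nan")
            for wname, win in windows.items():
                mask_m = (mr.t_ms >= win[0]) & (mr.t_ms < win[1])
                mask_c = (cr.t_ms >= win[0]) & (cr.t_ms < win[1])
                entry[f"ks_{wname}"] = ks_similarity(
                    gain * mr.rate[mask_m], cr.rate[mask_c]
                )
            rate_scores[pop] = entry
        out["rate_scores"] = rate_scores
        for metric, table_key, col in (
            ("corr", "loo_corr", "r"),
        ):
            table = cohort.get(table_key)
            if table is not None and len(table):
                verdicts = {}
                for pop, entry in rate_scores.items():
                    scores = table.loc[table["population"] == pop, col].dropna()
                    if len(scores):
                        verdicts[pop] = outlier_assessment(entry["r"], scores.to_numpy())
                out["corr_outliers"] = verdicts
    return out


def stage_evaluate(cfg: RunConfig, outdir: Path, presets=("original", "final")) -> dict:
    pc1 = io.load_pattern(outdir / "canonical_pc1.h5")
    mean = io.load_pattern(outdir / "cohort_mean.h5")
    wd_tbl = pd.read_csv(outdir / "wd_to_pc1.csv")
    cohort = {"pc1": pc1, "mean": mean, "wd_to_pc1": wd_tbl["wd_to_pc1"].to_numpy()}

    loo_corr_path = outdir / "spike_corr.csv"
    cohort_rates = None
    if (outdir / "spikes").exists():
        tables = {
            p.stem: classify_units(io.load_spikes(p, n_trials=cfg.n_trials))
            for p in sorted((outdir / "spikes").glob("*.csv"))
        }
        if tables:
            cohort_rates = {}
            for pop in POPULATIONS:
                rates = []
                for t in tables.values():
                    units = _population_units(t)
                    ids = units.loc[units["population"] == pop, "unit_id"]
                    if len(ids):
                        rates.append(population_rate(t, ids, pop).rate)
                if rates:
                    t_ms = np.arange(-250.0, 250.0, 1.0) + 0.5
                    cohort_rates[pop] = PopulationRate(pop, t_ms, np.mean(rates, axis=0))
            cohort["rates"] = cohort_rates
    if loo_corr_path.exists():
        cohort["loo_corr"] = pd.read_csv(loo_corr_path)

    results = {}
    for preset in presets:
        pat = io.load_pattern(outdir / "model" / f"{preset}_csd.h5")
        rates = None
        rates_path = outdir / "model" / f"{preset}_rates.csv"
        if rates_path.exists() and cohort_rates:
            df = pd.read_csv(rates_path)
            rates = {
                pop: PopulationRate(pop, df["t_ms"].to_numpy(), df[pop].to_numpy())
                for pop in df.columns if pop != "t_ms"
            }
        results[preset] = evaluate_model_against_cohort(pat, rates, cohort, cfg)
    io.save_json(outdir / "evaluation.json", results)
    return results


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage; returns (and writes) the machine-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.save_json(outdir / "config.json", {"config": cfg.to_dict(), "digest": cfg.digest()})
    summary: dict = {"config_digest": cfg.digest(), "seed": cfg.seed}
    try:
        summary["generate"] = stage_generate(cfg, outdir)
        stage_preprocess(cfg, outdir)
        stage_csd(cfg, outdir)
        summary["canonical"] = stage_canonical(cfg, outdir)
        summary["compare"] = stage_compare(cfg, outdir)
        summary["spikes"] = stage_spikes(cfg, outdir)
        summary["simulate"] = stage_simulate(cfg, outdir)
        summary["evaluation"] = stage_evaluate(cfg, outdir)
    except Exception as exc:  # abort with stage context
        summary["failed"] = repr(exc)
        io.save_json(outdir / "summary.json", summary)
        raise
    io.save_json(outdir / "summary.json", summary)
    return summary


def make_report(outdir: str | Path) -> dict:
    """Regenerate figures and a consolidated JSON from saved artifacts.

    Missing artifacts are listed in the report rather than raised.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    report: dict = {"missing": []}

    def heatmap(pattern: GridPattern, title: str, fname: str):
        fig, ax = plt.subplots(figsize=(5, 4))
        vmax = np.abs(pattern.values).max() or 1.0
        im = ax.pcolormesh(
            pattern.time_axis, pattern.depth_axis, pattern.values,
            cmap="RdBu_r", vmin=-vmax, vmax=vmax, shading="auto",
        )
        ax.invert_yaxis()
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("depth (µm)")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(figdir / fname, dpi=120)
        plt.close(fig)

    pc1_path = outdir / "canonical_pc1.h5"
    if pc1_path.exists():
        heatmap(io.load_pattern(pc1_path), "canonical pattern (PC 1)", "pc1.png")
    else:
        report["missing"].append(str(pc1_path))

    wd_path = outdir / "wd_to_pc1.csv"
    if wd_path.exists():
        tbl = pd.read_csv(wd_path)
        report["wd_to_pc1"] = tbl.to_dict(orient="list")
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.boxplot(tbl["normalized"], tick_labels=["animals"])
        eval_path = outdir / "evaluation.json"
        if eval_path.exists():
            ev = io.load_json(eval_path)
            report["evaluation"] = ev
            for i, (preset, res) in enumerate(ev.items()):
                ax.plot(1, res["normalized_wd_to_pc1"], "D",
                        label=f"{preset} model")
            ax.legend(fontsize=8)
        ax.set_ylabel("WD to PC1 (normalized)")
        fig.tight_layout()
        fig.savefig(figdir / "wd_boxplot.png", dpi=120)
        plt.close(fig)
    else:
        report["missing"].append(str(wd_path))

    model_dir = outdir / "model"
    if model_dir.exists():
        for pat_path in sorted(model_dir.glob("*_csd.h5")):
            heatmap(io.load_pattern(pat_path), pat_path.stem, f"{pat_path.stem}.png")

    for name in ("wd_summary.json", "spike_summary.json"):
        p = outdir / name
        if p.exists():
            report[name.removesuffix(".json")] = io.load_json(p)
        else:
            report["missing"].append(str(p))

    io.save_json(outdir / "report.json", report)
    return report
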