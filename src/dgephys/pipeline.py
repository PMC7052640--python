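"""Simulate → measure → stats orchestration.

``run_pipeline`` executes the full characterization workflow on synthetic
per-sector populations: every cell is driven through the V–I pulse family,
the α-EPSP train, the Chirp15 protocol, and the f–I family; the measurement
modules turn each cell into one row of the 18-measurement table; and the
statistics stage emits per-sector summary tables, sector comparisons,
correlation matrices, and PCA scores. Per-cell measurement failures are
logged and recorded as NaN without aborting the batch; reruns with the same
config and seed produce byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import popstats, stimuli, subthreshold, suprathreshold
from .bundle import CellRecord, TraceBundle, write_bundle
from .config import RunConfig
from .errors import ContaminatedProtocolError, DGEphysError
from .neuron import MembraneParams, simulate_spiking, simulate_subthreshold
from .population import default_population_specs, sample_sector_population

log = logging.getLogger("dgephys")

CSV_FLOAT_FORMAT = "%.10g"

MEASUREMENT_TABLE_COLUMNS = (
    ["cell_id", "sector"]
    + popstats.MEASUREMENT_COLUMNS
    + ["f_50", "f_100", "f_150", "f_200", "rheobase", "class_label", "r_squared", "V_hold", "flags"]
)


def _simulate(params: MembraneParams, stim, seed, noise_sd, substeps):
    if params.spike is not None:
        return simulate_spiking(params, stim, seed=seed, noise_sd=noise_sd, substeps=substeps)
    return simulate_subthreshold(params, stim, noise_sd=noise_sd, seed=seed, substeps=substeps)


def simulate_cell(
    params: MembraneParams,
    sector: str,
    cell_id: str,
    seed: int,
    config: RunConfig | None = None,
) -> CellRecord:
    """Run the full protocol battery on one cell and bundle the traces."""
    cfg = config or RunConfig()
    st = cfg["stimuli"]
    sim = cfg["simulation"]
    dt = st["sample_interval"]
    noise = sim["noise_sd"]
    substeps = sim["substeps"]
    rec = CellRecord(cell_id=cell_id, sector=sector, seed=seed)
    rng = np.random.default_rng(seed)
    sub_seeds = iter(rng.integers(0, 2**31 - 1, size=64))

    # V–I family: fall back to the ±25 pA protocol for high-R_in cells
    r_estimate = 1000.0 / (params.g_L + params.g_h * params.s_inf(params.resting_potential()))
    amps = (
        st["vi_amplitudes_high_rin"]
        if r_estimate > cfg["population"]["high_rin_threshold"]
        else st["vi_amplitudes"]
    )
    for amp in amps:
        stim = stimuli.make_pulse(amp, pre=st["pulse_pre"], post=st["pulse_post"], sample_interval=dt)
        rec.traces[f"vi_{int(amp):+d}"] = _simulate(params, stim, next(sub_seeds), noise, substeps)

    alpha = stimuli.make_alpha_train(
        i_max=st["alpha_i_max"], alpha=st["alpha_rate_ms"], n_events=st["alpha_n_events"],
        interval=st["alpha_interval"], sample_interval=dt,
    )
    rec.traces["alpha"] = _simulate(params, alpha, next(sub_seeds), noise, substeps)

    chirp = stimuli.make_chirp(
        amplitude=st["chirp_amplitude"], f_end=st["chirp_f_end"], duration=st["chirp_duration"],
        sample_interval=dt, prepulse_amplitude=st["prepulse_amplitude"],
        prepulse_duration=st["prepulse_duration"], prepulse_gap=st["prepulse_gap"],
    )
    rec.traces["chirp"] = _simulate(params, chirp, next(sub_seeds), noise, substeps)

    for amp in st["fi_amplitudes"]:
        stim = stimuli.make_pulse(amp, pre=st["pulse_pre"], post=st["pulse_post"], sample_interval=dt)
        rec.traces[f"fi_{int(amp)}"] = _simulate(params, stim, next(sub_seeds), noise, substeps)

    rec.ground_truth = {
        "params": asdict(params),
        "sector": sector,
        "true_spike_times": {
            k: t.metadata["true_spike_times"].tolist()
            for k, t in rec.traces.items()
            if "true_spike_times" in t.metadata
        },
    }
    return rec


def measure_cell(rec: CellRecord, config: RunConfig | None = None) -> dict:
    """Compute the measurement-table row for one cell's protocol bundle."""
    cfg = config or RunConfig()
    meas = cfg["measurement"]
    flags: list[str] = []
    row = {"cell_id": rec.cell_id, "sector": rec.sector}

    def guard(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except DGEphysError as e:
            tag = "SPIKE_CONTAMINATION" if isinstance(e, ContaminatedProtocolError) else "MEASUREMENT_ERROR"
            flags.append(f"{name}:{tag}")
            log.warning("cell=%s measurement=%s flag=%s detail=%s", rec.cell_id, name, tag, e)
            return None

    vi_steps = [
        (t.stimulus.params["amplitude"], t) for k, t in rec.traces.items() if k.startswith("vi_")
    ]
    fit = guard("R_in", subthreshold.input_resistance_fit, vi_steps) if vi_steps else None
    row["R_in"] = fit.value if fit else np.nan
    row["r_squared"] = fit.r_squared if fit else np.nan

    alpha = rec.traces.get("alpha")
    s_alpha = guard("S_alpha", subthreshold.summation_ratio, alpha) if alpha else None
    row["S_alpha"] = s_alpha.value if s_alpha else np.nan
    if s_alpha and s_alpha.flags:
        flags.extend(f"S_alpha:{f}" for f in s_alpha.flags)

    chirp = rec.traces.get("chirp")
    if chirp is not None:
        row["V_RMP"] = chirp.v_rmp
        row["V_hold"] = chirp.v_rmp
        rbar = guard("R_in_bar", subthreshold.pulse_input_resistance, chirp)
        row["R_in_bar"] = rbar.value if rbar else np.nan
        sag = guard("sag", subthreshold.sag_percentage, chirp)
        row["sag"] = sag.value if sag else np.nan
        prof = guard(
            "impedance", subthreshold.impedance_profile, chirp,
            f_band=tuple(meas["f_band"]), tail_ms=meas["impedance_tail_ms"],
        )
        if prof is not None:
            res = subthreshold.resonance_measures(prof)
            row["f_R"], row["Q"], row["Z_max"] = res.f_R, res.Q, res.Z_max
            row["Phi_L"] = subthreshold.total_inductive_phase(prof, phase_tol=meas["phase_tol"])
        else:
            row["f_R"] = row["Q"] = row["Z_max"] = row["Phi_L"] = np.nan
    else:
        row["V_RMP"] = row["V_hold"] = np.nan
        row["R_in_bar"] = row["sag"] = row["f_R"] = row["Q"] = row["Z_max"] = row["Phi_L"] = np.nan

    fi_steps = [
        (t.stimulus.params["amplitude"], t) for k, t in rec.traces.items() if k.startswith("fi_")
    ]
    if len(fi_steps) >= 2:
        profile = suprathreshold.fi_curve(fi_steps)
        for amp, rate in zip(profile.amplitudes, profile.rates):
            row[f"f_{int(amp)}"] = rate
        row["rheobase"] = profile.rheobase
        row["class_label"] = profile.class_label
        if profile.flags:
            flags.extend(profile.flags)
        top = max(fi_steps, key=lambda s: s[0])[1]
        ap = suprathreshold.ap_features(top, v_rmp=row.get("V_RMP"))
        for name in ("V_th", "V_AP_peak", "V_AP", "T_APHW", "dVdt_max", "dVdt_min", "T_1AP", "T_1ISI"):
            row[name] = getattr(ap, name)
    row["flags"] = ";".join(flags)
    return row


def measure_bundle(bundle: TraceBundle, config: RunConfig | None = None) -> pd.DataFrame:
    rows = [measure_cell(rec, config) for rec in bundle.cells.values()]
    df = pd.DataFrame(rows)
    for col in MEASUREMENT_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    # stable row order regardless of container iteration order
    return df[MEASUREMENT_TABLE_COLUMNS].sort_values("cell_id", ignore_index=True)


def simulate_populations(config: RunConfig | None = None, specs=None) -> TraceBundle:
    """Sample the three sector populations and simulate the full battery for each cell."""
    cfg = config or RunConfig()
    seed = cfg["seed"]
    if specs is None:
        specs = default_population_specs(cfg["population"]["n_per_sector"])
    bundle = TraceBundle()
    idx = 0
    for k, spec in enumerate(specs):
        cells = sample_sector_population(spec, seed=(seed * 7919 + k) % (2**31 - 1))
        for params, sector in cells:
            cid = f"{sector[:5]}_{idx:04d}"
            cell_seed = (seed * 1000003 + idx * 101 + 17) % (2**31 - 1)
            bundle.add(simulate_cell(params, sector, cid, cell_seed, cfg))
            idx += 1
        log.info("sector=%s simulated n=%d", spec.name, spec.n)
    return bundle


def write_stats_outputs(table: pd.DataFrame, outdir: Path, config: RunConfig) -> dict:
    """Emit summary/comparison/correlation/PCA tables; returns the result objects."""
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"# config_hash={config.hash()} seed={config['seed']}\n"

    def save(df: pd.DataFrame, name: str, index=False):
        p = outdir / name
        with open(p, "w") as f:
            f.write(stamp)
            df.to_csv(f, index=index, float_format=CSV_FLOAT_FORMAT)

    summary = popstats.summary_table(table)
    save(summary, "summary_by_sector.csv")

    comparisons = []
    for col in popstats.MEASUREMENT_COLUMNS + ["f_100", "f_150", "f_200"]:
        if col not in table.columns or table[col].std() == 0 or table[col].isna().all():
            continue
        try:
            c = popstats.compare_groups(table, col)
        except DGEphysError:
            continue
        rec = {"measurement": col, "anova_p": c.anova_p, "kruskal_p": c.kruskal_p}
        for pair, p in c.pairwise_wilcoxon.items():
            rec[f"wilcoxon:{pair[0]}|{pair[1]}"] = p
        for pair, p in c.pairwise_tukey.items():
            rec[f"tukey:{pair[0]}|{pair[1]}"] = p
        comparisons.append(rec)
    comp_df = pd.DataFrame(comparisons)
    save(comp_df, "sector_comparisons.csv")

    corr = popstats.correlation_matrix(table)
    save(corr.R, "correlation_R.csv", index=True)
    save(corr.P, "correlation_P.csv", index=True)

    pca = None
    try:
        pca = popstats.pca_embed(table)
        save(pca.scores, "pca_scores.csv", index=True)
        save(pca.loadings, "pca_loadings.csv", index=True)
        save(
            pd.DataFrame({"explained_fraction": pca.explained_fraction}),
            "pca_explained.csv",
        )
    except DGEphysError as e:
        log.warning("stage=pca flag=SKIPPED detail=%s", e)
    return {"summary": summary, "comparisons": comp_df, "correlation": corr, "pca": pca}


def run_pipeline(config: RunConfig | None = None, outdir: str | Path | None = None, specs=None):
    """End-to-end run: simulate populations, measure, write tables/figures.

    Returns ``(table, stats)``: the measurement table and the statistics
    objects. All outputs land under ``outdir`` (config ``output.dir`` by
    default), stamped with the config hash and master seed.
    """
    cfg = config or RunConfig()
    outdir = Path(outdir or cfg["output"]["dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_populations(cfg, specs=specs)
    if cfg["output"]["write_bundle"]:
        write_bundle(bundle, outdir / "traces.h5")
    table = measure_bundle(bundle, cfg)
    with open(outdir / "measurements.csv", "w") as f:
        f.write(f"# config_hash={cfg.hash()} seed={cfg['seed']}\n")
        table.to_csv(f, index=False, float_format=CSV_FLOAT_FORMAT)
    stats = write_stats_outputs(table, outdir, cfg)
    if cfg["output"]["figures"]:
        from . import report
        report.standard_figures(table, stats, outdir)
    return table, stats
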