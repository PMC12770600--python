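"""End-to-end recipes: cohort -> metrics -> statistics, and model sweeps.

Two recipes mirror the study's experiment shapes:

* the empirical recipe generates a synthetic longitudinal cohort, computes
  the seven timescale metrics for every scan/ROI, and runs the group
  statistics (session contrasts, network contrasts, hierarchy correlation,
  repeated-measures ANOVA, outcome analyses at session 2);
* the model recipe sweeps the excitable network over a branching-ratio
  grid, transforms each activity trace to the BOLD domain through the
  canonical HRF, computes metrics in both domains and reports where each
  metric peaks.

Every run writes its resolved configuration (with seed and package
version) next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortSpec,
    SubjectScan,
    default_parcellation,
    generate_cohort,
    save_cohort,
)
from .hemodynamics import HrfParams, to_bold
from .simulator import KCConfig, build_network, run_simulation
from .stats import (
    METRICS,
    fdr_bh,
    network_mean_int,
    qc_summary,
    rm_anova_oneway,
    spearman_hierarchy,
    subject_means,
    two_way_anova,
    welch_t,
)
from .timescales import DegenerateSeriesError, NoCrossingWarning, compute_all_metrics

__all__ = [
    "DEFAULT_SIGMA_GRID",
    "cohort_metric_table",
    "analyze_cohort",
    "run_empirical_recipe",
    "sweep_with_bold",
    "run_model_recipe",
]

#: Branching-ratio grid used by the scaled model recipe.
DEFAULT_SIGMA_GRID = (0.80, 0.85, 0.90, 0.95, 0.97, 1.00, 1.03, 1.05, 1.10, 1.20)


def cohort_metric_table(scans: list[SubjectScan]) -> pd.DataFrame:
    """Tidy per-ROI metric table: one row per (scan, ROI), one column per
    metric, with subject/group/outcome/session/network labels."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NoCrossingWarning)
        for scan in scans:
            parc = scan.data.parcellation
            for roi in parc.roi_names:
                metrics = compute_all_metrics(scan.data.series(roi))
                rows.append(
                    {
                        "subject": scan.subject_id,
                        "group": scan.group,
                        "outcome": scan.outcome,
                        "session": scan.session,
                        "roi": roi,
                        "network": parc.network_of[roi],
                        **metrics.as_dict(),
                    }
                )
    return pd.DataFrame(rows)


def _contrast_frame(contrasts: list) -> pd.DataFrame:
    frame = pd.DataFrame([dataclasses.asdict(c) for c in contrasts])
    if not frame.empty:
        frame["p_adjusted"] = fdr_bh(frame["p_raw"].to_numpy())
    return frame


def analyze_cohort(
    table: pd.DataFrame, metric: str = "int", *, include_controls_as_level: bool = True
) -> dict[str, Any]:
    """The study's statistical layer on one cohort metric table.

    Returns a dict with:

    * ``session_contrasts`` — control vs patient global-mean Welch t per
      session, FDR-corrected across sessions;
    * ``network_contrasts_session1`` — per-network control vs patient
      contrasts at session 1, FDR-corrected across networks;
    * ``hierarchy`` — Spearman rho between control and patient session-1
      network-mean orderings (exact permutation p);
    * ``rm_anova`` — repeated-measures ANOVA across timepoints; when
    ``include_controls_as_level`` the index-matched control is entered as a
      paired sixth level (k = 6 with five patient sessions);
    * ``outcome_contrasts_session2`` — per-network good vs poor contrasts
      at session 2, FDR-corrected;
    * ``two_way_anova`` — outcome x network ANOVA at session 2;
    * ``network_means`` — per-network mean +/- sd for controls and
      session-1 patients.
    """
    sessions = sorted(table.loc[table["group"] == "patient", "session"].unique())
    global_means = subject_means(table, metric)
    ctr = global_means[global_means["group"] == "control"][metric].to_numpy()

    session_contrasts = []
    for session in sessions:
        pat = global_means[
            (global_means["group"] == "patient") & (global_means["session"] == session)
        ][metric].to_numpy()
        session_contrasts.append(welch_t(ctr, pat, label=f"CTR vs PAT{session}"))
    session_frame = _contrast_frame(session_contrasts)

    net_means = subject_means(table, metric, by_network=True)
    networks = sorted(table["network"].unique())
    net_contrasts = []
    for net in networks:
        sel = net_means[net_means["network"] == net]
        a = sel[sel["group"] == "control"][metric].to_numpy()
        b = sel[(sel["group"] == "patient") & (sel["session"] == 1)][metric].to_numpy()
        net_contrasts.append(welch_t(a, b, label=f"CTR vs PAT1 {net}"))
    network_frame = _contrast_frame(net_contrasts)

    ctr_net = network_mean_int(table, "control", 1, metric)
    pat_net = network_mean_int(table, "patient", 1, metric)
    merged = ctr_net.merge(pat_net, on="network", suffixes=("_ctr", "_pat"))
    hierarchy = spearman_hierarchy(
        merged[f"{metric}_mean_ctr"].to_numpy(), merged[f"{metric}_mean_pat"].to_numpy()
    )

    pat_means = global_means[global_means["group"] == "patient"].copy()
    long = pat_means[["subject", "session", metric]].copy()
    long["session"] = long["session"].astype(str)
    if include_controls_as_level:
        # Pair control i with patient i as a sixth within-subject level.
        ctr_rows = global_means[global_means["group"] == "control"].sort_values("subject")
        pat_ids = sorted(pat_means["subject"].unique())
        n_pairs = min(len(ctr_rows), len(pat_ids))
        paired = pd.DataFrame(
            {
                "subject": pat_ids[:n_pairs],
                "session": "CTR",
                metric: ctr_rows[metric].to_numpy()[:n_pairs],
            }
        )
        # unpaired patients would leave empty cells in the within design
        long = long[long["subject"].isin(pat_ids[:n_pairs])]
        long = pd.concat([paired, long], ignore_index=True)
    rm = rm_anova_oneway(long, metric)

    outcome_contrasts = []
    s2 = net_means[(net_means["group"] == "patient") & (net_means["session"] == 2)]
    for net in networks:
        sel = s2[s2["network"] == net]
        good = sel[sel["outcome"] == "good"][metric].to_numpy()
        poor = sel[sel["outcome"] == "poor"][metric].to_numpy()
        outcome_contrasts.append(welch_t(poor, good, label=f"poor vs good {net} @S2"))
    outcome_frame = _contrast_frame(outcome_contrasts)

    anova2 = two_way_anova(
        net_means[(net_means["group"] == "patient") & (net_means["session"] == 2)],
        metric,
    )

    return {
        "session_contrasts": session_frame,
        "network_contrasts_session1": network_frame,
        "hierarchy": hierarchy,
        "rm_anova": rm,
        "outcome_contrasts_session2": outcome_frame,
        "two_way_anova": _contrast_frame(anova2),
        "network_means": merged,
    }


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_provenance(out: Path, payload: dict) -> None:
    payload = dict(payload)
    payload["package_version"] = __version__
    payload["config_hash"] = _config_hash(payload)
    (out / "resolved_config.json").write_text(json.dumps(payload, indent=2, default=str))


def run_empirical_recipe(
    out_dir: str | Path,
    spec: CohortSpec | None = None,
    metric: str = "int",
    *,
    save_scans: bool = False,
) -> dict[str, Any]:
    """Cohort generation -> metrics -> group statistics, written to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec if spec is not None else CohortSpec()
    scans = generate_cohort(spec, default_parcellation())
    if save_scans:
        save_cohort(scans, out / "cohort")
    table = cohort_metric_table(scans)
    table.to_csv(out / "metrics.csv", index=False)
    qc_summary(scans).to_csv(out / "qc.csv", index=False)
    results = analyze_cohort(table, metric)
    for name in (
        "session_contrasts",
        "network_contrasts_session1",
        "outcome_contrasts_session2",
        "two_way_anova",
        "network_means",
    ):
        results[name].to_csv(out / f"{name}.csv", index=False)
    summary = {
        "hierarchy_rho": results["hierarchy"].rho,
        "hierarchy_p": results["hierarchy"].p,
        "hierarchy_p_method": results["hierarchy"].p_method,
        "rm_anova_F": results["rm_anova"].statistic,
        "rm_anova_p": results["rm_anova"].p_raw,
        "rm_anova_label": results["rm_anova"].label,
        "n_scans": len(scans),
        "metric": metric,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    _write_provenance(out, {"recipe": "empirical", "spec": dataclasses.asdict(spec)})
    results["summary"] = summary
    results["metrics_table"] = table
    return results


def sweep_with_bold(
    config_base: KCConfig,
    sigma_grid=DEFAULT_SIGMA_GRID,
    n_trials: int = 10,
    tr: float = 2.0,
    hrf: HrfParams | None = None,
) -> pd.DataFrame:
    """Branching-ratio sweep with metrics in both domains.

    One tidy row per (sigma, trial, domain) where domain is "neuronal"
    (activity density at the simulator step) or "bold" (HRF-convolved,
    TR-decimated).  Seeding matches :func:`simulator.sweep_sigma`.
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    k = config_base.mean_degree
    if hrf is None:
        hrf = HrfParams(dt=config_base.dt_ms / 1000.0)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NoCrossingWarning)
        for i, sigma in enumerate(sigma_grid):
            config = dataclasses.replace(config_base, lambda_prop=float(sigma / k))
            for trial in range(n_trials):
                ss = np.random.SeedSequence([config_base.seed, i, trial])
                net_ss, dyn_ss = ss.spawn(2)
                topology = build_network(
                    config.n_neurons, config.mean_degree, np.random.default_rng(net_ss)
                )
                trace = run_simulation(
                    config, topology, rng=np.random.default_rng(dyn_ss)
                )
                try:
                    neuronal = compute_all_metrics(trace.to_timeseries()).as_dict()
                except DegenerateSeriesError:
                    neuronal = {m: float("nan") for m in METRICS}
                rows.append(
                    {"sigma": sigma, "trial": trial, "domain": "neuronal", **neuronal}
                )
                if trace.density.size * trace.dt < tr:
                    continue  # trace shorter than one TR: neuronal-only row
                bold = to_bold(trace, hrf, tr=tr)
                # DFA needs >= 64 samples; shorter traces get no BOLD row.
                if bold.values.size >= 64:
                    try:
                        bold_metrics = compute_all_metrics(
                            bold.to_timeseries()
                        ).as_dict()
                    except DegenerateSeriesError:
                        bold_metrics = {m: float("nan") for m in METRICS}
                    rows.append(
                        {"sigma": sigma, "trial": trial, "domain": "bold",
                         **bold_metrics}
                    )
    return pd.DataFrame(rows)


def peak_sigma(sweep: pd.DataFrame, metric: str = "int", domain: str | None = None) -> float:
    """Grid σ with the maximal trial-mean value of one metric."""
    df = sweep if domain is None else sweep[sweep["domain"] == domain]
    means = df.groupby("sigma", observed=True)[metric].mean()
    return float(means.idxmax())


def run_model_recipe(
    out_dir: str | Path,
    config: KCConfig | None = None,
    sigma_grid=DEFAULT_SIGMA_GRID,
    n_trials: int = 10,
    tr: float = 2.0,
    bold_duration_s: float = 300.0,
    bold_trials: int = 3,
) -> dict[str, Any]:
    """σ sweep + HRF transform + peak-location report, written to disk.

    Two sweeps are run: the short-trace neuronal sweep (``config``'s step
    count, ``n_trials`` per σ) for the timescale-vs-σ peak report, and a
    long-trace sweep (``bold_duration_s`` of activity, ``bold_trials`` per
    σ, offset seeds) whose traces are long enough to support TR-domain
    metrics after HRF convolution — 300 s at TR = 2 s gives 150 BOLD
    samples per trace.  The default configuration is the desk-scale sweep
    (N = 10,000 neurons); the full-scale parameters remain reachable
    through ``config``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = KCConfig(n_neurons=10_000)
    neuronal_sweep = sweep_with_bold(config, sigma_grid, n_trials, tr)
    neuronal_sweep = neuronal_sweep[neuronal_sweep["domain"] == "neuronal"]
    neuronal_sweep.to_csv(out / "sweep_neuronal.csv", index=False)

    bold_steps = int(round(bold_duration_s * 1000.0 / config.dt_ms))
    bold_config = dataclasses.replace(
        config,
        total_steps=bold_steps + config.transient_steps,
        seed=config.seed + 1,  # distinct trials from the neuronal sweep
    )
    bold_sweep = sweep_with_bold(bold_config, sigma_grid, bold_trials, tr)
    bold_sweep.to_csv(out / "sweep_bold.csv", index=False)

    combined = pd.concat([neuronal_sweep, bold_sweep[bold_sweep["domain"] == "bold"]])
    peaks = {
        domain: {m: peak_sigma(combined, m, domain) for m in METRICS}
        for domain in combined["domain"].unique()
    }
    (out / "peaks.json").write_text(json.dumps(peaks, indent=2))
    _write_provenance(
        out,
        {
            "recipe": "model",
            "config": dataclasses.asdict(config),
            "sigma_grid": list(np.asarray(sigma_grid, dtype=float)),
            "n_trials": n_trials,
            "tr": tr,
            "bold_duration_s": bold_duration_s,
            "bold_trials": bold_trials,
        },
    )
    return {"sweep_neuronal": neuronal_sweep, "sweep_bold": bold_sweep, "peaks": peaks}
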