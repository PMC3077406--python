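"""Driver that regenerates the package's reference tables and plots.

``reproduce_figures`` emits, deterministically for a given seed:

* two Monte Carlo estimate tables (inverse-optics and retinal estimators,
  both rotation rates, slants 20-80 deg) — the simulation contrast;
* three analysis tables from synthetic behavioural data: per-condition
  sqrt(def) regression slopes, the velocity-effect test, and the
  observed-vs-predicted regression;

plus quick-look PNG plots of the estimator curves and the synthetic data.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import analysis, montecarlo, synthetic_observer as so
from .bayes_core import inverse_optics_config, retinal_config
from .config import RunConfig, write_table

log = logging.getLogger(__name__)

__all__ = ["reproduce_figures", "make_behavioral_tables"]


def make_behavioral_tables(
    seed: int,
    n_subjects: int = 34,
    k_by_condition: Optional[Dict[str, float]] = None,
    noise_sd_tan: float = so.DEFAULT_NOISE_SD_TAN,
) -> pd.DataFrame:
    """Synthetic AVV + PVV + AVP trial table with responses.

    AVV and PVV share regime assignment and def values (the passive block
    replays the active block's flow); AVP re-crosses its own slants.
    """
    kmap = k_by_condition or so.DEFAULT_K_BY_CONDITION
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31, size=4)
    avv = so.generate_trials(so.ConditionSpec("AVV"), n_subjects, seed=int(sub_seeds[0]))
    pvv = so.generate_trials(
        so.ConditionSpec("PVV"), n_subjects, seed=int(sub_seeds[1]), replay_from=avv
    )
    # physical block keeps each subject's regime from the active block
    regimes = avv.drop_duplicates("subject_id").set_index("subject_id")["regime"]
    avp = so.generate_trials(
        so.ConditionSpec("AVP"),
        n_subjects,
        regime_assignment=[regimes[s] for s in range(n_subjects)],
        seed=int(sub_seeds[2]),
    )
    trials = pd.concat([avv, pvv, avp], ignore_index=True)
    return so.simulate_responses(
        trials, kmap, noise_sd_tan=noise_sd_tan, seed=int(sub_seeds[3])
    )


def _plot_simulation(table: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for omega, grp in table.groupby("omega_rad_s"):
        grp = grp.sort_values("def_rad_s")
        ax.plot(np.sqrt(grp["def_rad_s"]), grp["estimate_tan"], "o-", label=f"omega={omega}")
    ax.set_xlabel("sqrt(def) (sqrt(rad/s))")
    ax.set_ylabel("estimated slant-tangent")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_behaviour(trials: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.6), sharey=True)
    for ax, (label, grp) in zip(axes, trials.groupby("condition")):
        for regime, sub in grp.groupby("regime"):
            ax.plot(np.sqrt(sub["def_max"]), sub["response_tan"], ".", ms=3, label=regime)
        ax.set_title(label)
        ax.set_xlabel("sqrt(def)")
    axes[0].set_ylabel("response (tangent)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def reproduce_figures(
    outdir, seed: int = 0, sigma_omega_frac: float = 0.5, grid_n: int = 1024
) -> dict:
    """Regenerate the simulation and synthetic-behaviour tables into ``outdir``.

    ``sigma_omega_frac`` sets the inverse-optics rotation-prior spread as a
    fraction of each omega_E (0.5 reproduces the two-curve signature).
    Returns a manifest mapping logical names to file paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(command="reproduce-figures", seed=seed)
    manifest = {}

    log.info("Monte Carlo simulations (both estimators, both rotation rates)")
    omegas = montecarlo.DEFAULT_OMEGAS
    inv_cfgs = {
        f"inverse_optics_w{om}": inverse_optics_config(
            om, sigma_Omega_rad_s=sigma_omega_frac * om, grid_n=grid_n
        )
        for om in omegas
    }
    sim_tables = {}
    for name, cfg_est in inv_cfgs.items():
        om = cfg_est.rotation_prior.omega_E_rad_s
        t = montecarlo.run_simulation(
            montecarlo.SimulationDesign(
                configs={name: cfg_est}, omega_list_rad_s=[om], seed=seed
            )
        )
        sim_tables[name] = t
    inv_table = pd.concat(sim_tables.values(), ignore_index=True)
    inv_table["model"] = "inverse_optics"
    ret_table = montecarlo.run_simulation(
        montecarlo.SimulationDesign(
            configs={"retinal": retinal_config(grid_n=grid_n)}, seed=seed
        )
    )
    for name, tbl in (("sim_inverse_optics", inv_table), ("sim_retinal", ret_table)):
        p = out / f"{name}.csv"
        write_table(tbl, p, seed, cfg.hash)
        manifest[name] = str(p)

    log.info("synthetic behavioural tables and analyses")
    trials = make_behavioral_tables(seed)
    p = out / "synthetic_trials.csv"
    write_table(trials, p, seed, cfg.hash)
    manifest["synthetic_trials"] = str(p)

    slope_rows = []
    for label, grp in trials.groupby("condition"):
        res = analysis.no_intercept_slope(
            grp["response_tan"], np.sqrt(grp["def_max"])
        )
        slope_rows.append(
            (label, res.slope, res.slope_stderr, res.agreement_r2, res.n)
        )
    slopes = pd.DataFrame(
        slope_rows, columns=["condition", "slope", "stderr", "agreement_r2", "n"]
    )
    p = out / "analysis_sqrtdef_slopes.csv"
    write_table(slopes, p, seed, cfg.hash)
    manifest["analysis_sqrtdef_slopes"] = str(p)

    vt_rows = []
    for label, grp in trials.groupby("condition"):
        res = analysis.velocity_effect_test(grp, n_permutations=500, seed=seed)
        vt_rows.append((label, res.slope, res.regime_coef, res.p_value, res.n))
    vt = pd.DataFrame(
        vt_rows, columns=["condition", "sqrtdef_slope", "regime_coef", "p_value", "n"]
    )
    p = out / "analysis_velocity_effect.csv"
    write_table(vt, p, seed, cfg.hash)
    manifest["analysis_velocity_effect"] = str(p)

    ovp = analysis.observed_vs_predicted(trials, so.DEFAULT_K_BY_CONDITION)
    ovp_df = pd.DataFrame([ovp.to_dict()])
    ovp_df["conf_int"] = [json.dumps(ovp.conf_int)]
    p = out / "analysis_observed_vs_predicted.csv"
    write_table(ovp_df, p, seed, cfg.hash)
    manifest["analysis_observed_vs_predicted"] = str(p)

    _plot_simulation(inv_table, out / "sim_inverse_optics.png", "inverse-optics estimator")
    _plot_simulation(ret_table, out / "sim_retinal.png", "retinal estimator")
    _plot_behaviour(trials, out / "synthetic_behaviour.png")
    manifest.update(
        {
            "plot_inverse_optics": str(out / "sim_inverse_optics.png"),
            "plot_retinal": str(out / "sim_retinal.png"),
            "plot_behaviour": str(out / "synthetic_behaviour.png"),
        }
    )
    return manifest
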