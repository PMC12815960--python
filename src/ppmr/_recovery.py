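"""Parameter-recovery runs: generate a calibrated preset, push it through
matching + PPMR + mixed-model fitting, and summarise replicate estimates.

Used by the acceptance machinery and by recovery-based tests; this is the
package's own end-to-end path, not a shortcut around it.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ppmr import dapstom_io, glmm_pipeline, size_structure, synthetic_data

__all__ = ["run_preset_replicate", "summarize_replicates"]


def run_preset_replicate(
    preset_name: str,
    seed: int,
    n_stomachs: int = 5000,
    response: str = "log10_ppmr",
    with_effort: bool = False,
) -> dict:
    """One full simulate -> match -> compute -> fit replicate.

    Returns the fitted intercept/slope (and, for interaction fits, the
    conditional temperature slopes at the low/high effort-tercile medians).
    """
    cfg = dataclasses.replace(
        synthetic_data.preset(preset_name), n_stomachs=n_stomachs, seed=seed
    )
    ds = synthetic_data.generate(cfg)
    matched = dapstom_io.build_matched_table(
        ds.stomachs,
        dapstom_io.EnvLayer(ds.sst),
        dapstom_io.EffortTable(ds.effort) if with_effort else None,
    )
    tab = glmm_pipeline.build_analysis_table(matched)
    spec = glmm_pipeline.ModelSpec(response=response, with_effort=with_effort)
    fit = glmm_pipeline.fit_model(spec, tab)
    out = {
        "seed": seed,
        "n": len(tab),
        "intercept": float(fit.params["Intercept"]),
        "slope": float(fit.params["temperature"]),
        "slope_se": float(fit.bse["temperature"]),
        "converged": fit.converged,
    }
    if with_effort:
        bins = size_structure.effort_terciles(tab["effort_hours"].dropna())
        lines = glmm_pipeline.stratified_trendlines(fit, bins).set_index("stratum")
        out["slope_low"] = float(lines.loc["low", "slope"])
        out["slope_high"] = float(lines.loc["high", "slope"])
    return out


def summarize_replicates(replicates: list[dict], key: str) -> dict:
    """Mean, Monte-Carlo SE (std of replicate estimates / sqrt(R)), and the
    replicate values for one recovered quantity."""
    vals = np.array([r[key] for r in replicates], dtype=float)
    return {
        "mean": float(vals.mean()),
        "mc_se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
        "values": vals.tolist(),
        "n_replicates": len(vals),
    }
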