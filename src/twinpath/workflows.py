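"""Thin orchestration helpers: simulate-to-CSV, fit-to-JSON, ladder-to-CSV.

These are the scripted entry points the examples use; statistical
nonconvergence is reported in the output, never raised.  Every stochastic
output embeds its seed and the package version.
"""
from __future__ import annotations

import json
import warnings
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import GROUPS, TwinDataset, write_twin_table
from .estimation import fit_wls
from .inference import model_ladder, preset_ladder, test_statistic
from .moments import polychoric_matrix
from .simulate import GeneratingModel, atr_preset, simulate_dataset

__all__ = ["simulate_to_csv", "fit_report", "ladder_report"]


def _version() -> str:
    try:
        return version("twinpath")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _metadata(seed):
    return {"seed": int(seed), "package": "twinpath", "version": _version()}


def simulate_to_csv(out_csv, seed: int, gm: Optional[GeneratingModel] = None,
                    scale: float = 1.0, truth_json=None) -> TwinDataset:
    """Write a simulated twin table plus a generating-truth JSON file."""
    gm = gm if gm is not None else atr_preset()
    if scale != 1.0:
        gm = gm.scaled(scale)
    ds = simulate_dataset(gm, seed)
    write_twin_table(ds, out_csv)
    if truth_json is not None:
        truth = _metadata(seed)
        truth.update({
            "phenotypes": list(gm.codebook.names),
            "group_sizes": {g: int(n) for g, n in gm.group_sizes.items()},
            "completeness_pair": float(gm.completeness),
            "thresholds": gm.thresholds.tolist(),
            "cpm_mode": bool(gm.cpm_mode),
        })
        if gm.cpm_mode:
            truth["factor_ace"] = gm.factor_ace.tolist()
            truth["factor_loadings"] = gm.factor_loadings.tolist()
        else:
            truth["loadings_a"] = gm.loadings_a.tolist()
            truth["loadings_c"] = gm.loadings_c.tolist()
            truth["loadings_e"] = gm.loadings_e.tolist()
        truth["specific_a"] = gm.specific_a.tolist()
        truth["specific_c"] = gm.specific_c.tolist()
        truth["specific_e"] = gm.specific_e.tolist()
        Path(truth_json).write_text(json.dumps(truth, indent=1))
    return ds


def fit_report(ds: TwinDataset, spec, seed: int = 0, weight_mode: str = "diagonal",
               n_starts: int = 5, out_json=None) -> dict:
    """Fit one spec to a dataset; JSON-serializable report with decomposition."""
    groups = [g for g in GROUPS if g in set(ds.groups)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        moments = [polychoric_matrix(ds, g) for g in groups]
    fit = fit_wls(spec, moments, weight_mode=weight_mode, n_starts=n_starts, seed=seed)
    report = _metadata(seed)
    report.update({
        "model": spec.name,
        "converged": bool(fit.converged),
        "f_min": float(fit.f_min),
        "n_total": int(fit.n_total),
        "groups": list(fit.groups_used),
        "parameters": {k: float(v) for k, v in fit.params().items()},
    })
    if fit.converged:
        T, df, p = test_statistic(fit)
        report["test_of_fit"] = {"T": T, "df": df, "p": p}
    if fit.decomposition is not None:
        report["decomposition"] = {
            ph: {col: float(v) for col, v in row.items()}
            for ph, row in fit.decomposition.to_frame().iterrows()
        }
        if fit.decomposition.factor_shares is not None:
            report["factor_shares"] = list(fit.decomposition.factor_shares)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=1))
    return report


def ladder_report(source, entries: Optional[Sequence] = None, seed: int = 0,
                  n_boot: int = 200, out_csv=None) -> pd.DataFrame:
    """Run a model-comparison ladder and return (optionally write) its table."""
    entries = entries if entries is not None else preset_ladder()
    result = model_ladder(source, entries, seed=seed, n_boot=n_boot)
    frame = result.to_frame()
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame
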