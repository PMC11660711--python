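"""Publication-style result tables and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["format_estimate", "summary_table", "spec_grid", "write_manifest"]

RESULT_COLUMNS = ["approach", "estimator", "measure", "estimate", "ci_low", "ci_high"]


def format_estimate(estimate: float, ci: Optional[tuple] = None) -> str:
    """Render ``x.xx (x.xx,x.xx)``; NaNs render as ``NE`` (not estimated)."""
    if estimate is None or not np.isfinite(estimate):
        return "NE"
    text = f"{estimate:.2f}"
    if ci is not None and np.all(np.isfinite(ci)):
        text += f" ({ci[0]:.2f},{ci[1]:.2f})"
    return text


def summary_table(results: pd.DataFrame) -> pd.DataFrame:
    """One row per (approach, estimator) with formatted dHR / cHR / RR.

    ``results`` follows the long results-CSV contract (:data:`RESULT_COLUMNS`).
    An empty bundle yields an empty table with the header only.
    """
    if len(results) == 0:
        return pd.DataFrame(columns=["approach", "estimator", "dHR", "cHR", "RR"])
    rows = []
    for (approach, estimator), g in results.groupby(
        ["approach", "estimator"], sort=False
    ):
        row = {"approach": approach, "estimator": estimator}
        for measure in ("dHR", "cHR", "RR"):
            hit = g.loc[g["measure"] == measure]
            if len(hit):
                r = hit.iloc[0]
                ci = (
                    (r["ci_low"], r["ci_high"])
                    if np.isfinite(r["ci_low"]) and np.isfinite(r["ci_high"])
                    else None
                )
                row[measure] = format_estimate(r["estimate"], ci)
            else:
                row[measure] = "NE"
        rows.append(row)
    return pd.DataFrame(rows, columns=["approach", "estimator", "dHR", "cHR", "RR"])


def spec_grid(rows: list[dict]) -> pd.DataFrame:
    """Sensitivity grid over weighting-model specifications.

    One input dict per specification with keys ``label``, ``diagnostics``
    (a WeightDiagnostics) and ``effects`` (an EffectEstimates); rows are
    ordered by specification label.
    """
    out = []
    for r in rows:
        d, e = r["diagnostics"], r["effects"]
        out.append(
            {
                "specification": r["label"],
                "mean_sd": f"{d.mean:.2f} ({d.sd:.2f})",
                "min_max": f"{d.min:.2f} ({d.max:.2f})",
                "cHR": format_estimate(e.chr, e.chr_ci),
                "RR": format_estimate(e.rr, e.rr_ci),
            }
        )
    frame = pd.DataFrame(
        out, columns=["specification", "mean_sd", "min_max", "cHR", "RR"]
    )
    return frame.sort_values("specification").reset_index(drop=True)


def write_manifest(path, seed: int, config: dict, outputs: list[str]) -> None:
    """Run manifest: package version, seed, config hash, produced files."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "package": "gswitch",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "outputs": outputs,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
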