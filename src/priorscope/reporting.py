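"""Static report rendering: comparison tables, convergence tables, density
and trace exports, study tables, and run manifests.

All outputs are delimited text (comma-separated, header row, UTF-8) or JSON;
plots are exported as plot-ready data files, never images.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sensitivity import SensitivityResult
from .simulation import BIAS_FLAG_THRESHOLD, CellResult, study_frame

__all__ = [
    "render_fit_report",
    "render_sensitivity_report",
    "render_study_table",
    "parse_study_table",
    "write_manifest",
]


def _ensure_dir(out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir


def write_manifest(out_dir, config_text: str, seed: int, extra: dict | None = None) -> Path:
    """Write a JSON manifest (config hash + inline copy, seed, versions)
    sufficient to reproduce the run bit-for-bit."""
    import scipy

    from . import __version__

    out_dir = _ensure_dir(out_dir)
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode("utf-8")).hexdigest(),
        "config": config_text,
        "seed": int(seed),
        "versions": {
            "priorscope": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path


def render_fit_report(analysis, out_dir) -> list:
    """Write chain, summary and convergence files for a single analysis."""
    out_dir = _ensure_dir(out_dir)
    files = []
    chain_path = out_dir / f"chain_{analysis.label}.csv"
    analysis.chain.to_frame().to_csv(chain_path, index=False)
    files.append(chain_path)
    summary_path = out_dir / f"summary_{analysis.label}.csv"
    analysis.summary.table.to_csv(summary_path)
    files.append(summary_path)
    conv_path = out_dir / f"convergence_{analysis.label}.csv"
    analysis.convergence.table.to_csv(conv_path)
    files.append(conv_path)
    return files


def render_sensitivity_report(result: SensitivityResult, out_dir) -> list:
    """Write the full sensitivity file set.

    Emits: the per-parameter comparison table (estimate, SD, HPD bounds,
    original estimate, percent deviation, zero-in-HPD flags), a per-analysis
    convergence table, density-grid and trace-series data files per analysis,
    and a plain-text narrative skeleton listing which parameters' substantive
    conclusions changed.
    """
    out_dir = _ensure_dir(out_dir)
    files = []

    comparison_path = out_dir / "comparison.csv"
    result.comparison.to_csv(comparison_path, index=False)
    files.append(comparison_path)

    conv_rows = []
    for label, analysis in result.analyses.items():
        table = analysis.convergence.table.reset_index()
        table.insert(0, "analysis", label)
        table.insert(1, "seed", analysis.seed)
        conv_rows.append(table)
    conv_path = out_dir / "convergence.csv"
    pd.concat(conv_rows, ignore_index=True).to_csv(conv_path, index=False)
    files.append(conv_path)

    for label, analysis in result.analyses.items():
        dens_rows = []
        for parameter, grid in analysis.densities.items():
            dens_rows.append(
                pd.DataFrame(
                    {
                        "parameter": parameter,
                        "value": grid.grid,
                        "density": grid.density,
                        "degenerate": grid.degenerate,
                    }
                )
            )
        dens_path = out_dir / f"density_{label}.csv"
        pd.concat(dens_rows, ignore_index=True).to_csv(dens_path, index=False)
        files.append(dens_path)
        trace_path = out_dir / f"trace_{label}.csv"
        analysis.chain.to_frame().to_csv(trace_path, index=False)
        files.append(trace_path)

    narrative_path = out_dir / "narrative.txt"
    narrative_path.write_text(_narrative(result), encoding="utf-8")
    files.append(narrative_path)
    return files


def _narrative(result: SensitivityResult) -> str:
    lines = [
        "Understanding the impact of the priors",
        "=" * 38,
        "",
        f"Analyses run: {', '.join(result.analyses)}",
        f"HPD level: {result.level:.2f}",
        "",
    ]
    comp = result.comparison
    alt = comp[comp["analysis"] != "original"]
    changed = alt[alt["conclusion_changed"]]
    if changed.empty:
        lines.append(
            "No parameter's substantive conclusion (zero inside/outside the HPD "
            "interval) changed under any alternative prior set."
        )
    else:
        lines.append("Conclusion changes (zero enters or leaves the HPD interval):")
        for _, row in changed.iterrows():
            lines.append(
                f"  - {row['parameter']} under '{row['analysis']}': "
                f"zero_in_hpd {not row['zero_in_hpd']} -> {row['zero_in_hpd']}"
            )
    lines.append("")
    not_conv = [
        label
        for label, analysis in result.analyses.items()
        if not analysis.convergence.converged
    ]
    if not_conv:
        lines.append(
            "WARNING: non-converged analyses (possible evidence against these "
            f"priors): {', '.join(not_conv)}"
        )
    else:
        lines.append("All analyses converged (R-hat and ESS thresholds met).")
    lines.append("")
    lines.append("Largest percent deviations from the original posterior means:")
    top = alt.reindex(alt["percent_deviation"].abs().sort_values(ascending=False).index)
    for _, row in top.head(5).iterrows():
        lines.append(
            f"  - {row['parameter']} under '{row['analysis']}': "
            f"{row['percent_deviation']:+.3f}%"
        )
    return "\n".join(lines) + "\n"


def render_study_table(results: list, out_dir) -> list:
    """Write the study results: a long-format CSV plus a formatted text
    rendering with 'bias (MSE)' cells, flagging |bias| > 10% with '*'."""
    out_dir = _ensure_dir(out_dir)
    files = []
    frame = study_frame(results)
    csv_path = out_dir / "study_results.csv"
    frame.to_csv(csv_path, index=False)
    files.append(csv_path)

    lines = ["Model parameter estimate percent bias (MSE)", ""]
    params = list(results[0].percent_bias)
    header = "condition\t" + "\t".join(params)
    for n in sorted({c.sample_size for c in results}):
        lines.append(f"n = {n}")
        lines.append(header)
        for cell in [c for c in results if c.sample_size == n]:
            cells = []
            for p in params:
                mark = "*" if cell.flagged(p) else ""
                cells.append(f"{mark}{cell.percent_bias[p]:.2f} ({cell.mse[p]:.4f})")
            lines.append(f"{cell.condition_index}\t" + "\t".join(cells))
        lines.append("")
    lines.append(f"* |percent bias| > {BIAS_FLAG_THRESHOLD:.0f}%")
    txt_path = out_dir / "study_table.txt"
    txt_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    files.append(txt_path)
    return files


def parse_study_table(path) -> pd.DataFrame:
    """Parse the long-format study CSV back (round-trip check support)."""
    return pd.read_csv(path)
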