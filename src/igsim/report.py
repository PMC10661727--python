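"""Stratified summaries, ratio tables, threshold attainment, ribbon plots."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exposure import threshold_fraction

__all__ = ["GroupSummary", "summarize_groups", "percentile_ribbon",
           "write_report", "summaries_to_frame"]


@dataclass(frozen=True)
class GroupSummary:
    """Mean (SD) exposure per stratum, trough ratio vs the reference stratum,
    and the percentage of subjects holding the 7 g/L trough threshold."""

    stratum: str
    n: int
    auc_ss_mean: float
    auc_ss_sd: float
    cmax_mean: float
    cmax_sd: float
    cmin_mean: float
    cmin_sd: float
    cave_mean: float
    cave_sd: float
    cmin_ratio: float
    pct_above_threshold: float


def _label(subject, stratify_by: str) -> str:
    return subject.bmi_group if stratify_by == "bmi" else subject.age_group


def summarize_groups(result, stratify_by: str, reference_label: str,
                     threshold: float = 7.0) -> list[GroupSummary]:
    """Per-stratum mean/SD (sample SD, n-1) of each exposure metric.

    ``cmin_ratio`` is the quotient of the stratum's mean trough over the
    reference stratum's; the reference reports exactly 1.0.
    """
    groups: dict[str, list] = {}
    for subj, m in zip(result.subjects, result.metrics):
        groups.setdefault(_label(subj, stratify_by), []).append(m)
    if reference_label not in groups:
        raise ValueError(f"reference stratum {reference_label!r} absent from results")
    ref_mean = float(np.mean([m.cmin_ss for m in groups[reference_label]]))
    out = []
    for label, ms in groups.items():
        arr = {k: np.array([getattr(m, k) for m in ms])
               for k in ("auc_ss", "cmax_ss", "cmin_ss", "cave_ss")}
        cmin_mean = float(arr["cmin_ss"].mean())
        out.append(GroupSummary(
            stratum=label,
            n=len(ms),
            auc_ss_mean=float(arr["auc_ss"].mean()),
            auc_ss_sd=float(arr["auc_ss"].std(ddof=1)) if len(ms) > 1 else 0.0,
            cmax_mean=float(arr["cmax_ss"].mean()),
            cmax_sd=float(arr["cmax_ss"].std(ddof=1)) if len(ms) > 1 else 0.0,
            cmin_mean=cmin_mean,
            cmin_sd=float(arr["cmin_ss"].std(ddof=1)) if len(ms) > 1 else 0.0,
            cave_mean=float(arr["cave_ss"].mean()),
            cave_sd=float(arr["cave_ss"].std(ddof=1)) if len(ms) > 1 else 0.0,
            cmin_ratio=1.0 if label == reference_label else cmin_mean / ref_mean,
            pct_above_threshold=threshold_fraction(ms, threshold),
        ))
    return out


def percentile_ribbon(profiles, percentiles=(5, 50, 95)) -> pd.DataFrame:
    """Pointwise empirical percentiles of total IgG across subjects.

    All profiles must share one time grid; quantiles use the linear-
    interpolation definition.  Returns columns time, p<q> per percentile.
    """
    if not profiles:
        raise ValueError("no profiles given")
    t0 = np.asarray(profiles[0].times)
    for p in profiles[1:]:
        if p.times.shape != t0.shape or not np.allclose(p.times, t0):
            raise ValueError("profiles do not share one time grid")
    conc = np.vstack([p.conc_total for p in profiles])
    qs = np.percentile(conc, percentiles, axis=0, method="linear")
    data = {"time": t0}
    for pct, row in zip(percentiles, qs):
        data[f"p{pct:g}"] = row
    return pd.DataFrame(data)


def summaries_to_frame(summaries, regimen_label: str | None = None) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "stratum": s.stratum, "n": s.n,
            "auc_ss_mean": s.auc_ss_mean, "auc_ss_sd": s.auc_ss_sd,
            "cmax_mean": s.cmax_mean, "cmax_sd": s.cmax_sd,
            "cmin_mean": s.cmin_mean, "cmin_sd": s.cmin_sd,
            "cave_mean": s.cave_mean, "cave_sd": s.cave_sd,
            "cmin_ratio": s.cmin_ratio,
            "pct_cmin_ge_7": s.pct_above_threshold,
        }
        if regimen_label is not None:
            row = {"regimen": regimen_label, **row}
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(summaries, ribbons, out_dir, regimen_label=None,
                 threshold: float = 7.0) -> dict:
    """Write summary.csv, ribbons.csv and the two standard figures.

    ``ribbons`` maps stratum label -> ribbon frame (may be empty).  Full
    precision is kept in the CSVs; rounding is applied only in figures.
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    df = summaries_to_frame(summaries, regimen_label)
    summary_path = out_dir / "summary.csv"
    df.to_csv(summary_path, index=False)
    written["summary"] = summary_path

    if ribbons:
        frames = []
        for label, rib in ribbons.items():
            rib = rib.copy()
            rib.insert(0, "stratum", label)
            frames.append(rib)
        ribbon_path = out_dir / "ribbons.csv"
        pd.concat(frames, ignore_index=True).to_csv(ribbon_path, index=False)
        written["ribbons"] = ribbon_path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ribbons:
        fig, ax = plt.subplots(figsize=(8, 5))
        for label, rib in ribbons.items():
            ax.fill_between(rib["time"], rib["p5"], rib["p95"], alpha=0.2)
            ax.plot(rib["time"], rib["p50"], label=label)
        ax.axhline(threshold, ls="--", color="grey")
        ax.set_xlabel("Time (days)")
        ax.set_ylabel("Serum total IgG (g/L)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out_dir / "profiles_ribbon.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written["ribbon_plot"] = path

    fig, ax = plt.subplots(figsize=(7, 4.5))
    x = np.arange(len(summaries))
    ax.bar(x, [s.cmin_mean for s in summaries],
           yerr=[s.cmin_sd for s in summaries], capsize=4)
    ax.axhline(threshold, ls="--", color="k",
               label=f"{threshold:g} g/L threshold")
    ax.set_xticks(x)
    ax.set_xticklabels([s.stratum for s in summaries], rotation=20, ha="right")
    ax.set_ylabel("Mean C$_{min,ss}$ (g/L)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = out_dir / "cmin_bars.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written["cmin_plot"] = path

    return written
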