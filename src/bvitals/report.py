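"""Human-readable study report: audit, correlation screen, feature screen
and per-participant trajectory figures (PHQ-8 overlaid on a weekly feature
deviation)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .aggregate import CORR_FLAG_THRESHOLD, summary_key
from .model import format_screen
from . import io as _io

#: deviations overlaid on PHQ-8 in the trajectory figures
DEFAULT_PLOT_FEATURES = (
    ("norm_location_entropy", "mean"),
    ("step_count_k", "mean"),
)


def plot_participant_trajectory(
    triples: pd.DataFrame,
    phq: pd.DataFrame,
    participant_id,
    feature: str,
    statistic: str,
    path: Path,
) -> Path | None:
    """PHQ-8 scores and one weekly feature deviation for one participant."""
    tri = triples[
        (triples["participant_id"] == participant_id)
        & (triples["feature"] == feature)
        & (triples["statistic"] == statistic)
    ].sort_values("week")
    p = phq[phq["participant_id"] == participant_id].sort_values("week")
    if len(tri) == 0 or len(p) == 0:
        return None
    fig, ax1 = plt.subplots(figsize=(6, 3.5))
    ax1.plot(p["week"], p["phq8"], "o-", color="tab:red", label="PHQ-8")
    ax1.set_xlabel("week")
    ax1.set_ylabel("PHQ-8", color="tab:red")
    ax1.set_ylim(-1, 25)
    ax2 = ax1.twinx()
    ax2.plot(tri["week"], tri["x_dev"], "s--", color="tab:blue", label="weekly deviation")
    ax2.axhline(0.0, color="tab:blue", lw=0.6, alpha=0.5)
    ax2.set_ylabel(f"Δ {feature} ({statistic})", color="tab:blue")
    ax1.set_title(f"participant {participant_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def generate_report(
    screen: pd.DataFrame,
    audit_cohort: dict,
    corr_summary: dict,
    flagged: pd.DataFrame,
    outdir,
    triples: pd.DataFrame | None = None,
    phq: pd.DataFrame | None = None,
    plot_features=DEFAULT_PLOT_FEATURES,
    n_plot_participants: int = 2,
    meta: dict | None = None,
) -> Path:
    """Write ``report.md`` (plus PNG figures) summarizing one pipeline run."""
    outdir = _io.ensure_dir(outdir)
    lines = ["# Behavioral vital-signs screen", ""]
    for k, v in (meta or {}).items():
        lines.append(f"- {k}: {v}")
    lines += ["", "## Cohort audit", ""]
    for k, v in audit_cohort.items():
        lines.append(f"- {k}: {v:.3f}" if isinstance(v, float) else f"- {k}: {v}")

    lines += ["", "## Global-feature correlation screen", ""]
    if corr_summary.get("n_pairs", 0):
        lines.append(
            f"- median |r| = {corr_summary['median_abs_r']:.2f} "
            f"(Q1 = {corr_summary['q1_abs_r']:.2f}, Q3 = {corr_summary['q3_abs_r']:.2f})"
        )
    if len(flagged):
        lines.append(f"- pairs with |r| >= {CORR_FLAG_THRESHOLD:.2f}:")
        for _, row in flagged.iterrows():
            lines.append(f"  - {row['feature_a']} vs {row['feature_b']}: r = {row['r']:.2f}")
    else:
        lines.append(f"- no feature pairs with |r| >= {CORR_FLAG_THRESHOLD:.2f}")

    lines += ["", "## Between/within-person feature screen", ""]
    if len(screen) == 0:
        lines.append("**Warning: empty screen — no models could be fit.**")
    else:
        fmt = format_screen(screen)
        lines.append("| feature | term | B [95% CI] | ΔR² | n obs | n part. | ok |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, r in fmt.iterrows():
            ci = f"{r['estimate']:.2f} [{r['ci_low']:.2f}, {r['ci_high']:.2f}]"
            lines.append(
                f"| {r['summary']} | {r['term']} | {ci} | {r['delta_r2']:.3f} "
                f"| {r['n_obs']} | {r['n_participants']} | {'y' if r['converged'] else 'NO'} |"
            )

    figs = []
    if triples is not None and phq is not None and len(phq):
        pids = sorted(phq["participant_id"].unique())[:n_plot_participants]
        for pid in pids:
            for feature, stat in plot_features:
                fname = outdir / f"participant_{pid}_{feature}_{stat}.png"
                if plot_participant_trajectory(triples, phq, pid, feature, stat, fname):
                    figs.append(fname.name)
    if figs:
        lines += ["", "## Participant trajectories", ""]
        lines += [f"![{f}]({f})" for f in figs]

    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
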