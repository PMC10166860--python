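"""Human-readable report of a pipeline run: figures plus a JSON summary."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["write_report"]


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(result: dict, outdir) -> Path:
    """Write summary JSON and diagnostic figures for one pipeline result.

    Figures: alpha-sorted trace raster with overlaid phase, phase vs heading
    overlay, bump profile, and (when present) triggered averages.  Optional
    sections absent from the result tree are skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "summary": result.get("summary", {}),
        "config": result.get("config", {}),
        "inputs_digest": result.get("inputs_digest"),
    }
    (outdir / "summary.json").write_text(json.dumps(_json_safe(summary), indent=2))

    phase = result.get("phase")
    if phase is not None and "embedding" in result.get("embedding", {}):
        emb = result["embedding"]["embedding"]
        traces = result.get("traces")
        if traces is not None:
            index = {rid: k for k, rid in enumerate(traces.roi_ids)}
            rows = [index[r] for r in emb.roi_ids if r in index]
            order = np.argsort(emb.alpha)
            sorted_rows = np.asarray(rows)[order]
            fig, ax = plt.subplots(figsize=(8, 4))
            ax.imshow(
                traces.values[sorted_rows],
                aspect="auto",
                cmap="gray_r",
                extent=(0, traces.duration_s, len(sorted_rows), 0),
            )
            n = len(sorted_rows)
            ax.plot(
                phase.times,
                (np.pi - phase.wrapped) / (2 * np.pi) * n,
                color="tab:green", lw=0.8, label="phase",
            )
            ax.set(xlabel="time (s)", ylabel="ROI (sorted by alpha)")
            fig.savefig(outdir / "raster.png", dpi=120)
            plt.close(fig)

    if phase is not None and result.get("heading") is not None:
        heading = result["heading"]
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(phase.times, phase.unwrapped, color="tab:green", label="phase")
        ax2 = ax.twinx()
        ax2.plot(heading.times, heading.heading, color="goldenrod", label="heading")
        ax2.invert_yaxis()
        ax.set(xlabel="time (s)", ylabel="unwrapped phase (rad)")
        ax2.set_ylabel("estimated heading (rad, inverted)")
        fig.savefig(outdir / "phase_heading.png", dpi=120)
        plt.close(fig)

    profile = result.get("profile")
    if profile is not None:
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(profile.bins, profile.mean, color="tab:blue")
        ax.fill_between(
            profile.bins,
            profile.mean - profile.sd,
            profile.mean + profile.sd,
            alpha=0.3,
        )
        ax.set(xlabel="ring angle (rad)", ylabel="activity (z)",
               title=f"bump profile, FWHM = {profile.fwhm:.2f} rad")
        fig.savefig(outdir / "bump_profile.png", dpi=120)
        plt.close(fig)

    triggered = result.get("triggered")
    if triggered:
        fig, ax = plt.subplots(figsize=(5, 3))
        colors = {"left": "tab:blue", "right": "tab:red", "forward": "gray"}
        for cls, ta in triggered.items():
            ax.plot(ta.lags, ta.mean, label=f"{cls} (n={ta.n_events})",
                    color=colors.get(cls))
        ax.axvline(0, color="k", lw=0.5)
        ax.set(xlabel="time from swim (s)", ylabel="delta phase (rad)")
        ax.legend(frameon=False)
        fig.savefig(outdir / "triggered_average.png", dpi=120)
        plt.close(fig)
    return outdir / "summary.json"
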