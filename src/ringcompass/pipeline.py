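"""End-to-end orchestration: raw bundle -> decoded phase and statistics.

Stage order mirrors the analysis: preprocessing, swim extraction, ring
detection, circular embedding, phase decoding, heading integration, coupling
statistics and (optionally) regressor analyses.  Every intermediate is kept
in the result tree and the configuration (plus seed) is echoed for
provenance; runs are deterministic given the config.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np
import pandas as pd

from . import behavior, headnav, phasedyn, ringdetect, rpcspace, traceprep
from .bundleio import PipelineConfig, SessionBundle

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and an input digest."""

    def __init__(self, stage: str, digest: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed (inputs {digest}): {cause}")
        self.stage = stage
        self.digest = digest
        self.cause = cause


def _digest(*arrays) -> str:
    h = hashlib.sha1()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:10]


def run_pipeline(bundle: SessionBundle, config: PipelineConfig = None) -> dict:
    """Run the full analysis on one session bundle.

    Returns a result tree with the preprocessed traces, swim events, ring
    selection, embedding, phase, heading, coupling and a flat ``summary``
    of headline statistics.
    """
    if config is None:
        config = PipelineConfig()
    digest = _digest(bundle.raw.values, bundle.tail.angle)
    rng = np.random.default_rng(config.seed)
    result = {"config": config.to_dict(), "inputs_digest": digest}

    def stage(name, fn):
        try:
            result[name] = fn()
            return result[name]
        except Exception as exc:  # re-raise with stage context
            raise PipelineError(name, digest, exc) from exc

    traces = stage(
        "traces",
        lambda: traceprep.preprocess(
            bundle.raw,
            baseline_window_s=config.baseline_window_s,
            median_kernel_frames=config.median_kernel_frames,
            baseline_statistic=config.baseline_statistic,
        ),
    )
    # phase decoding weighs ROIs by dF/F (no per-ROI mean removal, which
    # would bias the population vector toward the most-occupied phase)
    dff_traces = stage(
        "dff_traces",
        lambda: traceprep.preprocess_dff(
            bundle.raw,
            baseline_window_s=config.baseline_window_s,
            median_kernel_frames=config.median_kernel_frames,
            baseline_statistic=config.baseline_statistic,
        ),
    )

    def _swims():
        events = behavior.detect_swims(
            bundle.tail,
            threshold=config.swim_threshold,
            min_gap_ms=config.min_gap_ms,
            vigor_window_ms=config.vigor_window_ms,
        )
        if len(events) >= 30:
            try:
                fit = behavior.fit_trimodal(
                    [ev.laterality for ev in events], n_bins=config.trimodal_bins
                )
                threshold = fit.threshold
            except RuntimeError as exc:
                warnings.warn(f"trimodal fit failed ({exc}); using fallback")
                threshold = config.fallback_class_threshold
        else:
            threshold = config.fallback_class_threshold
        behavior.classify_swims(events, threshold)
        return {"events": events, "class_threshold": threshold}

    swims = stage("swims", _swims)

    def _ring():
        provisional = ringdetect.select_anticorrelated(
            traces, threshold=config.ring_threshold, scan=config.ring_scan
        )
        if provisional.selected_ids.size < 8:
            return {"selection": provisional, "final": provisional}
        sub = traces.subset(provisional.selected_ids)
        coords, _ = rpcspace.pca_neuron_embedding(sub)
        alpha_prov = np.arctan2(coords[:, 1], coords[:, 0])
        final = ringdetect.exclude_by_sorted_matrix(
            traces, provisional, alpha_prov,
            template_min_corr=config.template_min_corr,
        )
        return {"selection": provisional, "final": final}

    ring = stage("ring", _ring)
    ring_ids = ring["final"].selected_ids
    if ring_ids.size < 8:
        result["summary"] = {"n_ring": int(ring_ids.size), "detected": False}
        return result
    ring_traces = traces.subset(ring_ids)
    ring_rois = (
        bundle.rois.set_index("roi_id").loc[ring_ids].reset_index()
    )

    def _embedding():
        coords, evr_neuron = rpcspace.pca_neuron_embedding(ring_traces)
        embedding = rpcspace.align_embedding(coords, ring_rois)
        _, evr_state = rpcspace.pca_state_space(ring_traces, k=2)
        stats = rpcspace.anatomy_stats(
            embedding, ring_rois, n_shuffles=200, rng=rng
        )
        return {
            "embedding": embedding,
            "evr_neuron": evr_neuron,
            "evr_state": evr_state,
            "anatomy": stats,
        }

    emb = stage("embedding", _embedding)
    embedding = emb["embedding"]

    phase = stage(
        "phase",
        lambda: phasedyn.compute_phase(
            dff_traces.subset(ring_ids), embedding,
            clip_percentiles=config.clip_percentiles, clip_mode=config.clip_mode,
        ),
    )
    profile = stage(
        "profile",
        lambda: phasedyn.phase_zeroed_profile(
            ring_traces, embedding, phase, n_bins=config.profile_bins
        ),
    )
    tuning = stage(
        "tuning", lambda: phasedyn.tuning_curves(ring_traces, phase)
    )

    events = swims["events"]
    heading = stage(
        "heading",
        lambda: headnav.integrate_heading(
            events, bundle.tail.rate, bundle.tail.angle.size / bundle.tail.rate
        ),
    )
    coupling = stage(
        "coupling",
        lambda: headnav.phase_heading_coupling(
            phase, heading,
            window_s=config.coupling_window_s,
            window_step_s=config.coupling_step_s,
            rng=rng,
        ),
    )

    def _delta():
        try:
            return headnav.window_delta_regression(
                phase, heading, events, window_s=config.delta_window_s
            )
        except ValueError as exc:
            warnings.warn(f"delta regression unavailable: {exc}")
            return None

    delta = stage("delta_regression", _delta)
    stage(
        "triggered",
        lambda: headnav.triggered_average(phase, events),
    )

    fwhms = np.array([c.fwhm for c in tuning])
    summary = {
        "detected": True,
        "n_ring": int(ring_ids.size),
        "n_swims": len(events),
        "state_pc_variance_2": float(np.sum(emb["evr_state"][:2])),
        "neuron_pc_variance_2": float(np.sum(emb["evr_neuron"][:2])),
        "rho_t": float(emb["anatomy"].rho_t),
        "profile_fwhm": float(profile.fwhm),
        "median_tuning_fwhm": float(np.nanmedian(fwhms)),
        "coupling_median_r": float(np.median(coupling.window_correlations)),
        "coupling_p": float(coupling.p_value),
        "delta_slope": None if delta is None else delta["slope"],
    }
    result["summary"] = summary
    return result


def summary_table(results: dict) -> pd.DataFrame:
    """Stack per-session pipeline summaries into one table."""
    rows = []
    for name, res in results.items():
        row = {"session": name}
        row.update(res["summary"])
        rows.append(row)
    return pd.DataFrame(rows)
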