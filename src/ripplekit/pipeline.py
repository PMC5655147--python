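"""Session-level orchestration: staging -> detection -> summaries ->
coupling, with JSON reports and pre/post-session comparison.

Reports are pydantic models so their JSON is schema-validated; the
published schema lives in ``ripplekit/schema/session_report.schema.json``.
Every NREM-dependent quantity that cannot be computed is null, with the
reason recorded in ``null_reasons``.  Reports carry no timestamps, so a
re-run with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from . import io as rio
from .core import (
    ACC_LFP,
    CA1_LFP,
    NREM,
    Hypnogram,
    InsufficientDataError,
    Recording,
)
from .coupling import (
    DEFAULT_HALF_WINDOW_S,
    DEFAULT_PEAK_SEARCH_S,
    DEFAULT_STEP_S,
    JOINT_WINDOW_S,
    N_SHUFFLES,
    SHIFT_RANGE_S,
    TS_BIN_S,
    joint_occurrence_rate,
    normalize_to_baseline,
    ripple_delta_xcorr,
    shuffle_null_test,
    timestamp_xcorr,
)
from .detect import (
    DELTA_PARAMS,
    RIPPLE_PARAMS,
    SPINDLE_PARAMS,
    detect_deltas,
    detect_ripples,
    detect_spindles,
    event_amplitude_summary,
    event_incidence,
)
from .spectral import band_power_fractions, bandpass_filter, hilbert_envelope, welch_psd
from .staging import score_sleep, sleep_architecture


class CouplingSettings(BaseModel):
    half_window_s: float = DEFAULT_HALF_WINDOW_S
    step_s: float = DEFAULT_STEP_S
    ts_bin_s: float = TS_BIN_S
    joint_window_s: float = JOINT_WINDOW_S
    n_shuffles: int = N_SHUFFLES
    shift_range_s: tuple[float, float | None] = SHIFT_RANGE_S
    shuffle_mode: str = "global"
    peak_search_s: float | None = DEFAULT_PEAK_SEARCH_S


class AnalysisConfig(BaseModel):
    """Every knob the pipeline uses; embedded verbatim in reports."""

    ripple: dict = Field(default_factory=lambda: asdict(RIPPLE_PARAMS))
    spindle: dict = Field(default_factory=lambda: asdict(SPINDLE_PARAMS))
    delta: dict = Field(default_factory=lambda: asdict(DELTA_PARAMS))
    staging_lfp_role: str = CA1_LFP
    coupling: CouplingSettings = Field(default_factory=CouplingSettings)
    seed: int = 0

    def detection_params(self, kind: str):
        from .core import DetectionParams

        return DetectionParams(**getattr(self, kind))


class ArchitectureModel(BaseModel):
    total_nrem_s: float
    mean_nrem_epoch_s: float
    n_nrem_epochs: int
    total_rem_s: float
    total_wake_s: float


class EventSummary(BaseModel):
    count: int
    incidence_per_min_nrem: float | None = None
    mean_peak_amp: float | None = None


class CorrelogramSummary(BaseModel):
    peak_coef: float
    peak_lag_s: float
    n_windows: int
    n_skipped: int = 0


class CouplingSummary(BaseModel):
    amp_xcorr: CorrelogramSummary | None = None
    amp_null_pct99: float | None = None
    is_significant: bool | None = None
    ts_xcorr: CorrelogramSummary | None = None
    joint_rate: float | None = None
    ripple_delta_xcorr: CorrelogramSummary | None = None


class SessionReport(BaseModel):
    recording_id: str
    seed: int
    params: AnalysisConfig
    architecture: ArchitectureModel | None = None
    ripple: EventSummary | None = None
    spindle: EventSummary | None = None
    delta: EventSummary | None = None
    band_power: dict[str, dict[str, float]] = Field(default_factory=dict)
    coupling: CouplingSummary = Field(default_factory=CouplingSummary)
    null_reasons: dict[str, str] = Field(default_factory=dict)
    warnings: list[str] = Field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, indent=1)


class ComparisonReport(BaseModel):
    pre: SessionReport
    post: SessionReport
    normalized_amp_xcorr_peak: float | None = None
    normalized_ts_xcorr_peak: float | None = None
    normalized_joint_rate: float | None = None
    null_reasons: dict[str, str] = Field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, indent=1)


def _xcg_summary(xcg) -> CorrelogramSummary:
    return CorrelogramSummary(
        peak_coef=float(xcg.peak_coef), peak_lag_s=float(xcg.peak_lag_s),
        n_windows=int(xcg.n_windows), n_skipped=int(xcg.n_skipped),
    )


def run_session(
    rec: Recording | str | Path,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
    recording_id: str = "session",
    hypnogram: Hypnogram | None = None,
    format: str = "rawbin",
) -> SessionReport:
    """Analyse one session end to end.

    Scores sleep (unless a hypnogram is supplied), detects ripples,
    spindles and delta waves during NREM, summarizes incidence and
    amplitude, computes band-power fractions per LFP channel, and runs
    all three coupling measures plus the shuffle-significance test.
    Artifacts (hypnogram, event tables, correlogram CSV, report JSON)
    are written to ``out_dir`` when given.
    """
    config = config or AnalysisConfig()
    if not isinstance(rec, Recording):
        rec = rio.read_recording(rec, format=format)
    report = SessionReport(recording_id=recording_id, seed=config.seed,
                           params=config)

    hyp = hypnogram or score_sleep(rec, lfp_role=config.staging_lfp_role)
    if "warning" in hyp.meta:
        report.warnings.append(str(hyp.meta["warning"]))
    arch = sleep_architecture(hyp)
    report.architecture = ArchitectureModel(**asdict(arch))

    # band power per LFP channel over the whole recording
    for role in (CA1_LFP, ACC_LFP):
        if role in rec.channels:
            psd = welch_psd(rec.channel(role), rec.fs)
            report.band_power[role] = band_power_fractions(psd).fractions

    nrem = hyp.intervals_for(NREM)
    if not nrem:
        for key in ("ripple", "spindle", "delta", "coupling.amp_xcorr",
                    "coupling.ts_xcorr", "coupling.joint_rate",
                    "coupling.ripple_delta_xcorr"):
            report.null_reasons[key] = "no NREM"
        _write_artifacts(report, rec, hyp, {}, None, out_dir)
        return report

    events = {
        "ripple": detect_ripples(rec, hyp, config.detection_params("ripple")),
        "spindle": detect_spindles(rec, hyp, config.detection_params("spindle")),
        "delta": detect_deltas(rec, hyp, config.detection_params("delta")),
    }
    for kind, es in events.items():
        summary = EventSummary(count=len(es))
        summary.incidence_per_min_nrem = event_incidence(es, hyp)
        if len(es):
            summary.mean_peak_amp = event_amplitude_summary(es)
        else:
            report.null_reasons[f"{kind}.mean_peak_amp"] = "no events"
        setattr(report, kind, summary)

    cs = config.coupling
    rip_env = hilbert_envelope(
        bandpass_filter(rec.channel(CA1_LFP), rec.fs,
                        config.ripple["band_low_hz"], config.ripple["band_high_hz"])
    )
    spi_env = hilbert_envelope(
        bandpass_filter(rec.channel(ACC_LFP), rec.fs,
                        config.spindle["band_low_hz"], config.spindle["band_high_hz"])
    )
    amp_xcg = None
    if len(events["spindle"]) == 0:
        report.null_reasons["coupling.amp_xcorr"] = "no spindles"
        report.null_reasons["coupling.joint_rate"] = "no spindles"
        report.null_reasons["coupling.ts_xcorr"] = "no spindles"
    else:
        try:
            amp_xcg, null = shuffle_null_test(
                rip_env, spi_env, events["spindle"].centers(), rec.fs,
                half_window_s=cs.half_window_s, step_s=cs.step_s, nrem=nrem,
                n_shuffles=cs.n_shuffles, shift_range_s=cs.shift_range_s,
                seed=config.seed, shuffle_mode=cs.shuffle_mode,
                peak_search_s=cs.peak_search_s,
            )
            report.coupling.amp_xcorr = _xcg_summary(amp_xcg)
            report.coupling.amp_null_pct99 = float(null.pct99)
            report.coupling.is_significant = bool(null.is_significant)
        except InsufficientDataError as e:
            report.null_reasons["coupling.amp_xcorr"] = str(e)
        report.coupling.joint_rate = joint_occurrence_rate(
            events["ripple"], events["spindle"], window_s=cs.joint_window_s
        )
        if len(events["ripple"]) == 0:
            report.null_reasons["coupling.ts_xcorr"] = "no ripples"
        else:
            try:
                ts = timestamp_xcorr(
                    events["ripple"], events["spindle"],
                    half_window_s=cs.half_window_s, bin_s=cs.ts_bin_s, nrem=nrem,
                )
                report.coupling.ts_xcorr = _xcg_summary(ts)
            except InsufficientDataError as e:
                report.null_reasons["coupling.ts_xcorr"] = str(e)

    if len(events["delta"]) == 0:
        report.null_reasons["coupling.ripple_delta_xcorr"] = "no delta waves"
    else:
        del_env = hilbert_envelope(
            bandpass_filter(rec.channel(ACC_LFP), rec.fs,
                            config.delta["band_low_hz"], config.delta["band_high_hz"])
        )
        try:
            rd = ripple_delta_xcorr(rip_env, del_env, events["delta"], rec.fs,
                                    nrem, step_s=cs.step_s)
            report.coupling.ripple_delta_xcorr = _xcg_summary(rd)
        except InsufficientDataError as e:
            report.null_reasons["coupling.ripple_delta_xcorr"] = str(e)

    _write_artifacts(report, rec, hyp, events, amp_xcg, out_dir)
    return report


def _write_artifacts(report, rec, hyp, events, amp_xcg, out_dir) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_hypnogram(hyp, out / "hypnogram.csv")
    for kind, es in events.items():
        rio.write_event_table(es, out / f"events_{kind}.csv")
    if amp_xcg is not None:
        with open(out / "amp_xcorr.csv", "w") as fh:
            fh.write("lag_s,coef\n")
            for lag, c in zip(amp_xcg.lags_s, amp_xcg.coefs):
                fh.write(f"{lag:.17g},{c:.17g}\n")
    (out / "report.json").write_text(report.to_json())


def compare_sessions(pre: SessionReport, post: SessionReport) -> ComparisonReport:
    """Pre-training-normalized coupling: post/pre ratios of the amplitude
    correlogram peak, timestamp correlogram peak and joint rate."""
    cmp = ComparisonReport(pre=pre, post=post)

    def ratio(field: str, get) -> float | None:
        pv, qv = get(pre), get(post)
        if pv is None or qv is None:
            cmp.null_reasons[field] = "missing in pre or post"
            return None
        if pv == 0:
            cmp.null_reasons[field] = "pre value is zero"
            return None
        return normalize_to_baseline(qv, pv)

    cmp.normalized_amp_xcorr_peak = ratio(
        "normalized_amp_xcorr_peak",
        lambda r: r.coupling.amp_xcorr.peak_coef if r.coupling.amp_xcorr else None,
    )
    cmp.normalized_ts_xcorr_peak = ratio(
        "normalized_ts_xcorr_peak",
        lambda r: r.coupling.ts_xcorr.peak_coef if r.coupling.ts_xcorr else None,
    )
    cmp.normalized_joint_rate = ratio(
        "normalized_joint_rate",
        lambda r: r.coupling.joint_rate,
    )
    return cmp


def report_schema() -> dict:
    """JSON schema of SessionReport (as published in the package)."""
    return SessionReport.model_json_schema()
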