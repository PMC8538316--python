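"""End-to-end composition: raw chewing signal -> smoothing -> chew count."""

from __future__ import annotations

from .config import PipelineConfig
from .peaks import ChewResult, PeakSet, count_chews
from .processing import DwdSpec, dwd_decompose, lowpass_filter, reconstruct_approximation, select_dwd_levels
from .signal import ChewSignal, build_chew_signal
from .landmarks import LandmarkTrack


def process_signal(sig: ChewSignal, method: str, speed: str,
                   config: PipelineConfig | None = None) -> tuple[ChewSignal, float]:
    """Smooth a raw chewing signal with the requested branch.

    Returns the series peaks are counted on and its sampling rate.  For the
    DWD branch this is, by default, the decimated final-level approximation
    coefficient series; ``config.dwd_count_on = "reconstruction"`` switches
    to the full-rate reconstruction of the approximation instead.
    """
    config = config or PipelineConfig()
    method = method.upper()
    if method == "LPF":
        out = lowpass_filter(sig, config.lpf)
        return out, out.fps
    if method == "DWD":
        levels = select_dwd_levels(sig.fps, speed, config.speed_bands_hz)
        result = dwd_decompose(sig, DwdSpec(wavelet=config.wavelet, levels=levels))
        if config.dwd_count_on == "coefficients":
            rate = result.effective_rate_hz
            return ChewSignal(values=result.approximation, fps=rate), rate
        recon = reconstruct_approximation(result)
        return sig.with_values(recon), sig.fps
    raise ValueError(f"unknown method {method!r}; expected 'LPF' or 'DWD'")


def count_chews_in_signal(sig: ChewSignal, method: str, speed: str,
                          config: PipelineConfig | None = None) -> tuple[ChewResult, PeakSet]:
    """Smooth then count; the main entry point of the counting pipeline."""
    config = config or PipelineConfig()
    processed, _rate = process_signal(sig, method, speed, config)
    result, peaks = count_chews(
        processed, method=method, speed=speed,
        bite_policy=config.bite_policy(),
        baseline_window_s=config.baseline_window_s,
        include_bites_in_mph=config.include_bites_in_mph,
    )
    result.parameters["config_hash"] = config.config_hash()
    return result, peaks


def count_chews_in_track(track: LandmarkTrack, method: str, speed: str,
                         config: PipelineConfig | None = None) -> tuple[ChewResult, PeakSet]:
    """Landmark track -> chewing signal -> chew count."""
    config = config or PipelineConfig()
    sig = build_chew_signal(track, gap_policy=config.gap_policy)
    return count_chews_in_signal(sig, method, speed, config)
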