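"""PAM chlorophyll-fluorescence quenching analysis.

A quenching recording follows a fixed temporal protocol: measuring flashes
alone for an initial dark window (F0), a first saturation pulse closing all
PSII centres (FM), dark relaxation, then actinic illumination driving
photosynthesis with repeated saturation pulses.  The steady-state signal
just before the last actinic pulse gives F(t) and the pulse itself FM′.
From the four measured levels the light-adapted minimal fluorescence is
estimated as

    F0' = F0 / ((FM - F0)/FM + F0/FM')

and the six PSII quantum-yield / quenching parameters follow:

    Φ_Po   = (FM - F0)/FM            maximal yield, dark-adapted (Fv/Fm)
    Φ_P    = (FM' - F(t))/FM'        actual yield in light
    Φ_PSII = (FM' - F0')/FM'         maximal yield in light
    q_P    = (FM' - F(t))/(FM' - F0')  fraction of open centres
    Φ_f,D  = F(t)/FM                 constitutive dissipation
    Φ_NPQ  = F(t)/FM' - F(t)/FM      regulatory heat dissipation

The partition Φ_P + Φ_f,D + Φ_NPQ = 1 and the factorization
Φ_P = q_P · Φ_PSII hold identically and are useful numerical checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProtocolTiming",
    "FluorLevels",
    "QuantumYields",
    "extract_levels",
    "f0_prime",
    "quantum_yields",
    "parameter_image",
    "render_false_colour",
    "demodulate",
]


@dataclass(frozen=True)
class ProtocolTiming:
    """Temporal layout of the quenching measurement, in seconds.

    Defaults: 5 s F0 window, a first 800 ms saturation pulse, 17 s dark
    relaxation, then 70 s of actinic light with saturation pulses at
    8, 18, 28, 48 and 68 s after actinic onset.  F(t) is averaged over
    ``ft_window_s`` immediately before the last pulse (set to one sample
    period for a point estimate).
    """

    f0_window: tuple[float, float] = (0.0, 5.0)
    sp1_start_s: float = 5.0
    sp_duration_s: float = 0.8
    relax_s: float = 17.0
    actinic_duration_s: float = 70.0
    sp_offsets_s: tuple[float, ...] = (8.0, 18.0, 28.0, 48.0, 68.0)
    ft_window_s: float = 1.0

    def __post_init__(self) -> None:
        if self.f0_window[1] <= self.f0_window[0]:
            raise ValueError("empty F0 window")
        if self.f0_window[1] > self.sp1_start_s:
            raise ValueError("F0 window must end before the first pulse")
        if not self.sp_offsets_s:
            raise ValueError("need at least one actinic-phase pulse")
        if sorted(self.sp_offsets_s) != list(self.sp_offsets_s):
            raise ValueError("pulse offsets must be increasing")
        if self.sp_offsets_s[-1] + self.sp_duration_s > self.actinic_duration_s:
            raise ValueError("last pulse must end within the actinic phase")

    @property
    def actinic_start_s(self) -> float:
        return self.sp1_start_s + self.sp_duration_s + self.relax_s

    @property
    def last_pulse_start_s(self) -> float:
        return self.actinic_start_s + self.sp_offsets_s[-1]

    @property
    def total_s(self) -> float:
        return self.actinic_start_s + self.actinic_duration_s


@dataclass(frozen=True)
class FluorLevels:
    """The four measured fluorescence levels (instrument units)."""

    f0: float
    fm: float
    ft: float
    fmp: float

    def __post_init__(self) -> None:
        if not (self.fm >= self.f0 > 0):
            raise ValueError("levels must satisfy FM >= F0 > 0")
        if self.fmp <= 0:
            raise ValueError("FM' must be positive")

    @property
    def fv(self) -> float:
        return self.fm - self.f0


@dataclass(frozen=True)
class QuantumYields:
    phi_po: float
    phi_p: float
    phi_psii: float
    q_p: float
    phi_fd: float
    phi_npq: float
    f0p: float = field(default=float("nan"))


def demodulate(before_flash: np.ndarray, during_flash: np.ndarray) -> np.ndarray:
    """Pass-through hook for raw paired samples.

    PAM instruments sample the signal just before each measuring flash and
    during it, and subtract the pair so actinic light cancels.  Recordings
    are normally delivered already demodulated; this hook accepts the raw
    pairs when they are not.
    """
    return np.asarray(during_flash, dtype=float) - np.asarray(
        before_flash, dtype=float
    )


def _window_mask(times: np.ndarray, start: float, stop: float, name: str) -> np.ndarray:
    m = (times >= start) & (times < stop)
    if not m.any():
        raise ValueError(f"no samples in the {name} window [{start}, {stop}) s")
    return m


def extract_levels(
    times_s: np.ndarray,
    signal: np.ndarray,
    timing: ProtocolTiming | None = None,
    pulse_mode: str = "max",
) -> FluorLevels:
    """Extract F0, FM, F(t) and FM′ from a timed quenching trace.

    F0 is the mean over the initial dark window; FM comes from the first
    (dark-adapted) saturation pulse and FM′ from the last actinic-phase
    pulse; F(t) is the mean over ``ft_window_s`` immediately preceding that
    pulse.  ``pulse_mode`` selects how a pulse window is reduced: ``"max"``
    (the default), ``"mean"``, or ``"top_quartile_mean"`` — a noise-robust
    plateau estimate.  Pulses during the dark relaxation are ignored.
    """
    timing = timing or ProtocolTiming()
    times = np.asarray(times_s, dtype=float)
    sig = np.asarray(signal, dtype=float)
    if times.ndim != 1 or times.shape[0] != sig.shape[0]:
        raise ValueError("times and signal must align on the first axis")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be strictly increasing")

    def reduce_pulse(win: np.ndarray) -> float:
        if pulse_mode == "max":
            return float(win.max())
        if pulse_mode == "mean":
            return float(win.mean())
        if pulse_mode == "top_quartile_mean":
            q3 = np.quantile(win, 0.75)
            return float(win[win >= q3].mean())
        raise ValueError(f"unknown pulse_mode {pulse_mode!r}")

    f0 = float(sig[_window_mask(times, *timing.f0_window, "F0")].mean())
    fm = reduce_pulse(
        sig[
            _window_mask(
                times,
                timing.sp1_start_s,
                timing.sp1_start_s + timing.sp_duration_s,
                "FM pulse",
            )
        ]
    )
    last = timing.last_pulse_start_s
    fmp = reduce_pulse(
        sig[_window_mask(times, last, last + timing.sp_duration_s, "FM' pulse")]
    )
    ft = float(sig[_window_mask(times, last - timing.ft_window_s, last, "Ft")].mean())
    return FluorLevels(f0=f0, fm=fm, ft=ft, fmp=fmp)


def f0_prime(levels: FluorLevels) -> float:
    """Estimated minimal fluorescence of the light-adapted state.

    Evaluates F0/((FM−F0)/FM + F0/FM′) in the single-division form
    F0·FM·FM′ / (FM′·(FM−F0) + F0·FM) for numerical accuracy.  When
    FM′ = FM the expression reduces algebraically to F0 and is returned as
    such, keeping the no-quenching limit exact in floating point.
    """
    if levels.fmp == levels.fm:
        return levels.f0
    denom = levels.fmp * (levels.fm - levels.f0) + levels.f0 * levels.fm
    if denom <= 0:
        raise ValueError("degenerate quenching state: F0' denominator <= 0")
    return levels.f0 * levels.fm * levels.fmp / denom


def quantum_yields(levels: FluorLevels) -> QuantumYields:
    """The six PSII quantum-yield / quenching parameters from four levels."""
    f0p = f0_prime(levels)
    phi_po = (levels.fm - levels.f0) / levels.fm
    phi_p = (levels.fmp - levels.ft) / levels.fmp
    phi_psii = (levels.fmp - f0p) / levels.fmp
    if levels.fmp == f0p:
        raise ValueError("q_P undefined: FM' equals F0'")
    q_p = (levels.fmp - levels.ft) / (levels.fmp - f0p)
    phi_fd = levels.ft / levels.fm
    phi_npq = levels.ft / levels.fmp - levels.ft / levels.fm
    return QuantumYields(
        phi_po=phi_po,
        phi_p=phi_p,
        phi_psii=phi_psii,
        q_p=q_p,
        phi_fd=phi_fd,
        phi_npq=phi_npq,
        f0p=f0p,
    )


def timing_from_mapping(cfg: dict[str, object]) -> ProtocolTiming:
    """Build :class:`ProtocolTiming` from flat config keys.

    Recognized keys (with or without a ``timing.`` prefix): ``f0_start``,
    ``f0_end``, ``sp1_start_s``, ``sp_duration_s``, ``relax_s``,
    ``actinic_duration_s``, ``sp_offsets_s`` (comma-separated),
    ``ft_window_s``.  Unset keys keep the default protocol.
    """
    flat: dict[str, str] = {}
    for key, val in cfg.items():
        name = key.split(".", 1)[1] if key.startswith("timing.") else key
        flat[name] = str(val)
    kwargs: dict = {}
    if "f0_start" in flat or "f0_end" in flat:
        kwargs["f0_window"] = (
            float(flat.get("f0_start", 0.0)), float(flat.get("f0_end", 5.0))
        )
    for name in ("sp1_start_s", "sp_duration_s", "relax_s",
                 "actinic_duration_s", "ft_window_s"):
        if name in flat:
            kwargs[name] = float(flat[name])
    if "sp_offsets_s" in flat:
        kwargs["sp_offsets_s"] = tuple(
            float(x) for x in flat["sp_offsets_s"].split(",")
        )
    return ProtocolTiming(**kwargs)


_PARAM_NAMES = ("F0", "FM", "Ft", "FMp", "F0p", "phi_Po", "phi_P", "phi_PSII",
                "q_P", "phi_fD", "phi_NPQ")


def parameter_image(
    stack: np.ndarray,
    times_s: np.ndarray,
    timing: ProtocolTiming | None = None,
    mask: np.ndarray | None = None,
    noise_floor: float = 1e-6,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Pixel-wise fluorescence levels and quantum yields for an image stack.

    ``stack`` has shape (T, H, W) with frame times ``times_s``.  Levels use
    the window means/maxima of :func:`extract_levels`, vectorized over
    pixels.  Yields are computed only inside ``mask`` and where F0 exceeds
    ``noise_floor`` (background pixels would divide by ~0); everywhere else
    the maps hold NaN.  Returns the maps and a summary table of the region
    median and lower/upper quartiles per parameter.
    """
    timing = timing or ProtocolTiming()
    stack = np.asarray(stack, dtype=float)
    times = np.asarray(times_s, dtype=float)
    if stack.ndim != 3 or times.shape[0] != stack.shape[0]:
        raise ValueError("stack must be (T, H, W) with matching frame times")
    if mask is None:
        mask = np.ones(stack.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape[1:]:
        raise ValueError("mask and stack must share spatial shape")
    if not mask.any():
        raise ValueError("empty mask")

    f0_map = stack[_window_mask(times, *timing.f0_window, "F0")].mean(axis=0)
    fm_map = stack[
        _window_mask(
            times, timing.sp1_start_s, timing.sp1_start_s + timing.sp_duration_s,
            "FM pulse",
        )
    ].max(axis=0)
    last = timing.last_pulse_start_s
    fmp_map = stack[
        _window_mask(times, last, last + timing.sp_duration_s, "FM' pulse")
    ].max(axis=0)
    ft_map = stack[_window_mask(times, last - timing.ft_window_s, last, "Ft")].mean(
        axis=0
    )

    valid = mask & (f0_map > noise_floor) & (fm_map > 0) & (fmp_map > 0)
    maps = {name: np.full(mask.shape, np.nan) for name in _PARAM_NAMES}
    with np.errstate(divide="ignore", invalid="ignore"):
        f0p = f0_map * fm_map * fmp_map / (
            fmp_map * (fm_map - f0_map) + f0_map * fm_map
        )
        maps["F0"][valid] = f0_map[valid]
        maps["FM"][valid] = fm_map[valid]
        maps["Ft"][valid] = ft_map[valid]
        maps["FMp"][valid] = fmp_map[valid]
        maps["F0p"][valid] = f0p[valid]
        maps["phi_Po"][valid] = ((fm_map - f0_map) / fm_map)[valid]
        maps["phi_P"][valid] = ((fmp_map - ft_map) / fmp_map)[valid]
        maps["phi_PSII"][valid] = ((fmp_map - f0p) / fmp_map)[valid]
        maps["q_P"][valid] = ((fmp_map - ft_map) / (fmp_map - f0p))[valid]
        maps["phi_fD"][valid] = (ft_map / fm_map)[valid]
        maps["phi_NPQ"][valid] = (ft_map / fmp_map - ft_map / fm_map)[valid]

    rows = []
    for name in _PARAM_NAMES:
        vals = maps[name][valid]
        vals = vals[np.isfinite(vals)]
        q1, med, q3 = (
            np.quantile(vals, [0.25, 0.5, 0.75]) if vals.size else (np.nan,) * 3
        )
        rows.append(
            {"parameter": name, "q1": q1, "median": med, "q3": q3, "n_px": vals.size}
        )
    return maps, pd.DataFrame(rows)


def render_false_colour(
    param_map: np.ndarray,
    scale: tuple[float, float],
    cmap: str = "viridis",
) -> np.ndarray:
    """Linear false-colour rendering of a parameter map as an 8-bit RGB image.

    Values are clipped to ``scale``; NaN pixels render black.
    """
    import matplotlib

    vmin, vmax = scale
    if not (np.isfinite(vmin) and np.isfinite(vmax) and vmin < vmax):
        raise ValueError("scale must be finite with min < max")
    arr = np.asarray(param_map, dtype=float)
    norm = np.clip((arr - vmin) / (vmax - vmin), 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](norm)
    rgba[~np.isfinite(arr)] = 0.0
    return (rgba[..., :3] * 255).round().astype(np.uint8)
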