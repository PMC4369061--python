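"""Ground-truthed synthetic inputs: plants, growth series, quenching traces.

The plant generator renders a branching shoot skeleton — stem, branches and
curly 1–2 px tendrils — in plant-green hue over a flat or soil-textured
background, and returns the exact rasterized ground-truth mask alongside
the image.  The thin tendrils are the point: they reproduce the failure
mode where a single-pixel hue miss disconnects a whole offshoot, which is
what the edge-fusion step of the segmentation exists to fix.

Growth series follow exponential growth with per-observation lognormal
noise; quenching traces are piecewise plateaus laid out by a
:class:`~phenoshoot.fluorescence.ProtocolTiming`, so the generative
F0/FM/F(t)/FM′ are recovered exactly in the noiseless case.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color

from .fluorescence import ProtocolTiming
from .segmentation import VIEWS

_BG_HUE_DEG = 30.0  # soil brown


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one rendered plant view."""

    height: int = 192
    width: int = 144
    stem_length_px: int = 90
    n_branches: int = 4
    n_tendrils: int = 5
    tendril_width_px: int = 1
    tendril_length_px: int = 26
    hue_deg: float = 120.0
    hue_jitter_deg: float = 8.0
    background: str = "flat"  # or "soil_texture"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tendril_width_px < 1:
            raise ValueError("tendril_width_px must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background not in ("flat", "soil_texture"):
            raise ValueError("background must be 'flat' or 'soil_texture'")


@dataclass(frozen=True)
class TraceSpec:
    """Generative levels and sampling of a synthetic quenching trace."""

    f0: float = 200.0
    fm: float = 1000.0
    ft: float = 400.0
    fmp: float = 700.0
    timing: ProtocolTiming = field(default_factory=ProtocolTiming)
    sample_rate_hz: float = 25.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fm >= self.f0 > 0):
            raise ValueError("need FM >= F0 > 0")
        if not (0 < self.fmp <= self.fm):
            raise ValueError("need 0 < FM' <= FM")
        if self.sample_rate_hz <= 0 or self.noise_sd < 0:
            raise ValueError("invalid sampling parameters")


class ViewRender(NamedTuple):
    """One rendered view: image, exact mask, and the tendril-only submask."""

    rgb: np.ndarray
    mask: np.ndarray
    tendril_mask: np.ndarray


def _stamp(mask: np.ndarray, r: int, c: int, width: int) -> None:
    h, w = mask.shape
    if width <= 1:
        offsets = ((0, 0),)
    elif width == 2:
        offsets = ((0, 0), (0, 1), (1, 0), (1, 1))
    else:
        rad = width // 2
        yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
        offsets = tuple(zip(yy[yy**2 + xx**2 <= rad**2], xx[yy**2 + xx**2 <= rad**2]))
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w:
            mask[rr, cc] = True


def _walk(
    rng: np.random.Generator,
    start: tuple[float, float],
    angle_deg: float,
    length: int,
    jitter_deg: float,
    curl_deg: float = 0.0,
) -> list[tuple[int, int]]:
    """Unit-step random walk with angular jitter; returns integer pixels."""
    r, c = start
    ang = np.deg2rad(angle_deg)
    pts = []
    for _ in range(length):
        pts.append((int(round(r)), int(round(c))))
        r += -np.cos(ang)  # angle 0 points up the image
        c += np.sin(ang)
        ang += np.deg2rad(curl_deg + rng.normal(0.0, jitter_deg))
    return pts


def _render_skeleton(
    spec: PlantSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize stem + branches + tendrils; returns (mask, tendril_mask)."""
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    tendrils = np.zeros_like(mask)

    base = (spec.height - 8.0, spec.width / 2.0 + rng.uniform(-6, 6))
    stem = _walk(rng, base, rng.uniform(-6, 6), spec.stem_length_px, 1.5)
    for r, c in stem:
        _stamp(mask, r, c, 3)

    anchors = [stem[-1]]
    lo = int(0.3 * len(stem))
    for _ in range(spec.n_branches):
        idx = int(rng.integers(lo, len(stem)))
        side = rng.choice((-1.0, 1.0))
        branch = _walk(
            rng,
            stem[idx],
            side * rng.uniform(25, 55),
            int(spec.stem_length_px * rng.uniform(0.25, 0.45)),
            3.0,
        )
        for r, c in branch:
            _stamp(mask, r, c, 2)
        anchors.append(branch[-1])

    for i in range(spec.n_tendrils):
        start = anchors[int(rng.integers(0, len(anchors)))]
        tendril = _walk(
            rng,
            start,
            rng.uniform(-80, 80),
            int(spec.tendril_length_px * rng.uniform(0.8, 1.3)),
            9.0,
            curl_deg=rng.choice((-1.0, 1.0)) * rng.uniform(4, 9),
        )
        tmask = np.zeros_like(mask)
        for r, c in tendril:
            _stamp(tmask, r, c, spec.tendril_width_px)
        tendrils |= tmask & ~mask
        mask |= tmask

    return mask, tendrils


def _render_view(spec: PlantSpec, rng: np.random.Generator) -> ViewRender:
    mask, tendrils = _render_skeleton(spec, rng)

    hsv = np.empty((spec.height, spec.width, 3))
    hsv[..., 0] = _BG_HUE_DEG / 360.0
    hsv[..., 1] = 0.5
    if spec.background == "flat":
        hsv[..., 2] = 0.38
    else:
        # soil: low-frequency brightness undulation plus pixel speckle
        lowfreq = ndimage.gaussian_filter(
            rng.normal(size=(spec.height, spec.width)), sigma=12
        )
        lowfreq = lowfreq / (np.abs(lowfreq).max() + 1e-9)
        speckle = rng.normal(scale=0.02, size=(spec.height, spec.width))
        hsv[..., 2] = np.clip(0.38 + 0.08 * lowfreq + speckle, 0.15, 0.6)
        hsv[..., 0] += rng.normal(scale=4.0 / 360.0, size=(spec.height, spec.width))

    jitter = rng.normal(scale=spec.hue_jitter_deg, size=mask.sum())
    hsv[..., 0][mask] = (spec.hue_deg + jitter) / 360.0
    hsv[..., 1][mask] = 0.65
    hsv[..., 2][mask] = 0.62
    hsv[..., 0] %= 1.0

    rgb = color.hsv2rgb(hsv) * 255.0
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(scale=spec.noise_sd, size=rgb.shape)
    return ViewRender(
        rgb=np.clip(np.round(rgb), 0, 255).astype(np.uint8),
        mask=mask,
        tendril_mask=tendrils,
    )


def make_plant_views(spec: PlantSpec) -> dict[str, ViewRender]:
    """Render the three views of one plant with exact ground-truth masks.

    The views are independent renders (view-specific silhouettes) seeded
    from ``spec.seed``, so the same spec always yields bit-identical output.
    """
    out = {}
    for i, view in enumerate(VIEWS):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        out[view] = _render_view(spec, rng)
    return out


def erase_tendril_hue(render: ViewRender) -> tuple[ViewRender, np.ndarray]:
    """Shift the hue of one whole tendril to soil brown, keeping V and S.

    Emulates the chromatic noise that makes hue thresholding drop an entire
    thin offshoot while the brightness structure — what edge detection
    sees — stays intact.  The erased tendril is the one reaching furthest
    into free background (an offshoot lying on top of the silhouette has no
    brightness edge and models a different, unrecoverable failure).
    Returns the corrupted render and the erased tendril's pixel mask.
    """
    labels, n = ndimage.label(render.tendril_mask, structure=np.ones((3, 3)))
    if n == 0:
        raise ValueError("render has no tendrils to erase")
    rest = render.mask & ~render.tendril_mask
    # isolation: fraction of the tendril further than 2 px from other plant parts
    near_rest = ndimage.binary_dilation(rest, np.ones((3, 3)), iterations=2)
    best, target = (-1.0, -1), 1
    for comp in range(1, n + 1):
        px = labels == comp
        size = int(px.sum())
        isolation = float((px & ~near_rest).sum()) / size
        if (isolation, size) > best:
            best, target = (isolation, size), comp
    erased = labels == target

    hsv = color.rgb2hsv(render.rgb.astype(np.float64) / 255.0)
    hsv[..., 0][erased] = _BG_HUE_DEG / 360.0
    rgb = np.clip(np.round(color.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    return ViewRender(rgb=rgb, mask=render.mask, tendril_mask=render.tendril_mask), erased


def make_growth_series(
    r_per_day: float = 0.0626,
    w0: float = 400.0,
    days: tuple[int, ...] = (1, 5, 8, 12, 15, 19, 21),
    n_plants: int = 15,
    lognormal_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential growth series with multiplicative lognormal noise.

    ``W_i(d) = w0 * exp(r_per_day * d) * eps`` with ``ln eps ~ N(0, sd^2)``
    independently per plant and day.  The default rate gives a ~3.5-fold
    area increase between days 1 and 21 (the fast-growing regime); a rate
    of ``ln(2.5)/20 ~ 0.0458`` gives the ~2.5-fold slow regime.  Returns a
    long table (plant_id, day, area_mm2).
    """
    if w0 <= 0:
        raise ValueError("w0 must be positive")
    if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for plant in range(n_plants):
        for day in days:
            eps = np.exp(rng.normal(0.0, lognormal_sd)) if lognormal_sd > 0 else 1.0
            rows.append(
                {
                    "plant_id": f"plant{plant:02d}",
                    "day": day,
                    "area_mm2": w0 * np.exp(r_per_day * day) * eps,
                }
            )
    return pd.DataFrame(rows)


def _trace_value(t: np.ndarray, spec: TraceSpec) -> np.ndarray:
    """Noiseless piecewise trace value at times ``t`` (vectorized)."""
    tm = spec.timing
    out = np.full(t.shape, spec.f0, dtype=float)

    # dark relaxation: exponential return from FM toward F0, truncated to
    # exactly F0 after 10 s so plateaus stay exact
    relax_start = tm.sp1_start_s + tm.sp_duration_s
    in_relax = (t >= relax_start) & (t < tm.actinic_start_s)
    dt = t[in_relax] - relax_start
    decay = np.where(dt < 10.0, (spec.fm - spec.f0) * np.exp(-dt / 1.5), 0.0)
    out[in_relax] = spec.f0 + decay

    # actinic phase: fast transient to the steady state, truncated after 6 s
    in_act = t >= tm.actinic_start_s
    dta = t[in_act] - tm.actinic_start_s
    peak = spec.ft + 0.3 * (spec.fmp - spec.ft)
    trans = np.where(dta < 6.0, (peak - spec.ft) * np.exp(-dta / 1.2), 0.0)
    out[in_act] = spec.ft + trans

    # saturation pulses override everything
    pulses = [tm.sp1_start_s] + [tm.actinic_start_s + o for o in tm.sp_offsets_s]
    levels = [spec.fm] + [spec.fmp] * len(tm.sp_offsets_s)
    for onset, level in zip(pulses, levels):
        out[(t >= onset) & (t < onset + tm.sp_duration_s)] = level
    return out


def make_trace(spec: TraceSpec) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic quenching trace ``(times_s, signal)`` under the protocol.

    Plateaus are exact, so with ``noise_sd = 0`` the extraction recovers the
    generative levels bit-for-bit.
    """
    tm = spec.timing
    n = int(np.floor(tm.total_s * spec.sample_rate_hz))
    times = np.arange(n) / spec.sample_rate_hz
    signal = _trace_value(times, spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
    return times, signal


def make_trace_stack(
    level_maps: dict[str, np.ndarray],
    timing: ProtocolTiming | None = None,
    sample_rate_hz: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel quenching stack from maps of generative levels.

    ``level_maps`` holds 2-D arrays ``f0, fm, ft, fmp`` of a common shape.
    Returns ``(times_s, stack)`` with stack shape (T, H, W).
    """
    timing = timing or ProtocolTiming()
    f0, fm, ft, fmp = (np.asarray(level_maps[k], float) for k in ("f0", "fm", "ft", "fmp"))
    n = int(np.floor(timing.total_s * sample_rate_hz))
    times = np.arange(n) / sample_rate_hz
    stack = np.empty((n, *f0.shape))
    base = TraceSpec(timing=timing, sample_rate_hz=sample_rate_hz)
    levels_flat = np.stack([f0.ravel(), fm.ravel(), ft.ravel(), fmp.ravel()])
    flat = stack.reshape(n, -1)
    for j in range(levels_flat.shape[1]):
        spec = replace(
            base,
            f0=float(levels_flat[0, j]),
            fm=float(levels_flat[1, j]),
            ft=float(levels_flat[2, j]),
            fmp=float(levels_flat[3, j]),
        )
        flat[:, j] = _trace_value(times, spec)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    return times, stack


def write_demo_dataset(
    outdir: str,
    seed: int = 0,
    n_trays: int = 4,
    days: tuple[int, ...] = (1, 5, 8, 12, 15, 19, 21),
    image_noise_sd: float = 4.0,
    trace_noise_sd: float = 3.0,
    r_fast: float = 0.0626,
    r_slow: float = 0.0458,
) -> dict[str, object]:
    """Write a complete ground-truthed demo dataset for the CLI pipeline.

    Layout under ``outdir``: tray images ``images/tray{T}_day{D}_{view}.png``
    (two plants per tray, side by side), exact per-plant masks under
    ``truth/``, quenching traces ``traces/plant{P}_day{D}.csv``, plus
    ``calibration.csv``, ``groups.csv`` and final-day ``fw.csv`` (a fresh
    weight proportional to true green area with lognormal scatter).

    The first half of the trays grows at ``r_fast`` (~3.5-fold area gain
    over days 1–21, stable photochemistry), the second half at ``r_slow``
    (~2.5-fold, with FM declining over the cold treatment so the
    dark-adapted PSII yield Φ_Po falls).
    """
    from pathlib import Path

    from . import io as pio

    out = Path(outdir)
    n_plants = 2 * n_trays
    mm2_per_px = 0.25

    groups, fw_rows, truth_px = [], [], {}
    for tray in range(n_trays):
        fast = tray < (n_trays + 1) // 2
        for pos in range(2):
            plant = 2 * tray + pos
            groups.append(
                {"plant_id": f"plant{plant:02d}", "group": "fast" if fast else "slow"}
            )

    for tray in range(n_trays):
        fast = tray < (n_trays + 1) // 2
        rate = r_fast if fast else r_slow
        for day in days:
            views_rgb = {v: [] for v in VIEWS}
            for pos in range(2):
                plant = 2 * tray + pos
                base_rng = np.random.default_rng(
                    np.random.SeedSequence([seed, plant])
                )
                base_len = 36 + base_rng.uniform(-4, 4)
                spec = PlantSpec(
                    stem_length_px=min(150, int(base_len * np.exp(rate * (day - 1)))),
                    n_branches=2 + day // 6,
                    n_tendrils=3 + day // 5,
                    background="soil_texture",
                    noise_sd=image_noise_sd,
                    seed=int(
                        np.random.default_rng(
                            np.random.SeedSequence([seed, plant, day])
                        ).integers(2**31)
                    ),
                )
                renders = make_plant_views(spec)
                for view in VIEWS:
                    views_rgb[view].append(renders[view].rgb)
                    pio.write_mask(
                        out / "truth" / f"plant{plant:02d}_day{day:02d}_{view}.png",
                        renders[view].mask,
                    )
                truth_px[(plant, day)] = {
                    view: int(renders[view].mask.sum()) for view in VIEWS
                }
                # quenching trace: slow group's FM declines under cold
                fm = 1000.0 if fast else 1000.0 - 14.0 * (day - 1)
                tspec = TraceSpec(
                    f0=200.0,
                    fm=fm,
                    ft=0.4 * fm,
                    fmp=0.7 * fm,
                    noise_sd=trace_noise_sd,
                    seed=int(
                        np.random.default_rng(
                            np.random.SeedSequence([seed, plant, day, 7])
                        ).integers(2**31)
                    ),
                )
                times, sig = make_trace(tspec)
                pio.write_table(
                    pd.DataFrame({"time_s": times, "signal": sig}),
                    out / "traces" / f"plant{plant:02d}_day{day:02d}.csv",
                )
            for view in VIEWS:
                pio.write_image(
                    out / "images" / f"tray{tray:02d}_day{day:02d}_{view}.png",
                    np.hstack(views_rgb[view]),
                )

    fw_rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    last = max(days)
    for plant in range(n_plants):
        px = truth_px[(plant, last)]
        a_total = float(np.sqrt(sum((px[v] * mm2_per_px) ** 2 for v in VIEWS)))
        fw_rows.append(
            {
                "plant_id": f"plant{plant:02d}",
                "fw_g": 2e-3 * a_total * np.exp(fw_rng.normal(0.0, 0.05)),
            }
        )

    pio.write_table(
        pd.DataFrame(
            [
                {"view": v, "px_count": 400, "known_mm2": 400 * mm2_per_px}
                for v in VIEWS
            ]
        ),
        out / "calibration.csv",
    )
    pio.write_table(pd.DataFrame(groups), out / "groups.csv")
    pio.write_table(pd.DataFrame(fw_rows), out / "fw.csv")
    return {"n_plants": n_plants, "days": days, "mm2_per_px": mm2_per_px}
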