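"""Small I/O helpers: flat key=value config files and stamped CSV tables."""

from __future__ import annotations

import hashlib
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__


def load_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``section.key=value`` config file.

    Blank lines and ``#`` comments are ignored; later keys override earlier
    ones.  CLI flags override config keys.
    """
    cfg: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = line.split("=", 1)
        cfg[key.strip()] = val.strip()
    return cfg


def config_hash(cfg: dict[str, str]) -> str:
    blob = "\n".join(f"{k}={cfg[k]}" for k in sorted(cfg))
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, cfg: dict[str, str] | None = None) -> None:
    """Write a CSV with a header comment naming version and config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# phenoshoot {__version__} config={config_hash(cfg or {})}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[-1] == 4:
        img = img[..., :3]
    return img


def write_image(path: str | Path, img: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(img))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    write_image(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 127


def read_fluor_stack(
    tiff_path: str | Path, frame_times_csv: str | Path
) -> tuple[np.ndarray, np.ndarray]:
    """Read a quenching image stack: multi-page TIFF plus frame-time CSV.

    The CSV needs a ``time_s`` column with one row per TIFF page.  Returns
    ``(times_s, stack)`` with stack shape (T, H, W).
    """
    stack = np.asarray(tifffile.imread(tiff_path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    times = read_table(frame_times_csv)["time_s"].to_numpy(dtype=float)
    if times.shape[0] != stack.shape[0]:
        raise ValueError(
            f"{stack.shape[0]} TIFF pages but {times.shape[0]} frame times"
        )
    return times, stack


def write_fluor_stack(
    tiff_path: str | Path, frame_times_csv: str | Path,
    times: np.ndarray, stack: np.ndarray,
) -> None:
    Path(tiff_path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(tiff_path, np.asarray(stack, dtype=np.float32))
    write_table(pd.DataFrame({"time_s": np.asarray(times)}), frame_times_csv)


def write_param_map_tiff(
    path: str | Path, param_map: np.ndarray, scale: tuple[float, float]
) -> None:
    """Write a parameter map as a 16-bit TIFF, linearly scaled to ``scale``.

    NaN (masked-out) pixels are written as 0.
    """
    lo, hi = scale
    if not hi > lo:
        raise ValueError("scale must satisfy max > min")
    arr = np.asarray(param_map, dtype=float)
    q = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
    out = np.where(np.isfinite(arr), np.round(q * 65535), 0).astype(np.uint16)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, out)
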