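"""File formats, run configuration and provenance plumbing.

Images travel as TIFF/PNG, tables as comma-separated UTF-8 CSV with a header
row and '.' decimals, fit results and summaries as JSON, configuration as
YAML validated against a strict schema (unknown keys rejected).  Column
names carry units (``r0_um``, ``K_D_uM``) to prevent silent unit errors.
Every run directory receives the resolved configuration and a plain-text
log so results remain reproducible.
"""

from __future__ import annotations

import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "RunConfig", "load_config", "read_image", "write_image",
    "write_table", "read_table", "write_json", "read_series",
    "write_sidecar", "RunLogger",
]

MEASUREMENT_COLUMNS = [
    "droplet_id", "r0_um", "eps_um", "I_in", "I_peri",
    "sd_I_in", "sd_I_peri", "S_tot_uM", "T_tot_uM",
]


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    pixel_size_um: float = Field(0.5, gt=0)
    s_tot_um: float = Field(1.66, ge=0)
    t_tot_um: float = Field(1.25, ge=0)
    concentration_reference: str = Field("bulk", pattern="^(bulk|layer)$")
    eps_source: str = Field("estimated", pattern="^(fixed|estimated)$")
    eps_um: float | None = Field(None, gt=0)
    d_min_um: float = Field(40.0, gt=0)
    d_max_um: float = Field(50.0, gt=0)
    kd_um: float = Field(0.5, ge=0)
    psf_sigma_um: float = Field(0.5, ge=0)
    noise_model: str = Field("gaussian", pattern="^(none|gaussian|poisson)$")
    noise_sd_frac: float = Field(0.02, ge=0)
    fit_weighted: bool = True
    fit_orientation: str = Field("falling", pattern="^(falling|rising)$")
    n_droplets: int = Field(25, ge=1)
    outdir: str = "results"


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def read_image(path: str | Path, pixel_size: float):
    """Read a TIFF or PNG grayscale image into a DropletImage."""
    from .quantify import DropletImage

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px, dtype=float)
    if px.ndim == 3:
        px = px.mean(axis=-1) if px.shape[-1] in (3, 4) else px[0]
    return DropletImage(pixels=px, pixel_size=pixel_size)


def write_image(path: str | Path, image) -> None:
    """Write a DropletImage; TIFF keeps float32, PNG rescales to 16-bit."""
    path = Path(path)
    px = image.pixels
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px.astype(np.float32))
    else:
        lo, hi = float(px.min()), float(px.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        iio.imwrite(path, ((px - lo) * scale).astype(np.uint16))


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path: str | Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


def write_sidecar(data_path: str | Path, params: dict) -> Path:
    """Write the generating parameter set as a JSON sidecar next to a file."""
    side = Path(str(data_path) + ".params.json")
    write_json(side, params)
    return side


def read_series(path: str | Path) -> np.ndarray:
    """Read a scalar series from single-column CSV or whitespace text.

    The common two-column time/value trajectory dialect is auto-detected
    (the second column is taken as the value).
    """
    arr = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",",
                     comments=("#", "@"), ndmin=2)
    if arr.shape[1] == 1:
        return arr[:, 0]
    if arr.shape[1] == 2:
        return arr[:, 1]
    raise ValueError(
        f"expected 1 or 2 columns in {path}, found {arr.shape[1]}")


def _is_whitespace(path: str | Path) -> bool:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "@")):
                continue
            return "," not in line
    return True


class RunLogger:
    """Minimal provenance: resolved config + timestamped log in the outdir."""

    def __init__(self, outdir: str | Path, config: RunConfig | None = None):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._fh = open(self.outdir / "run.log", "a", encoding="utf-8")
        if config is not None:
            with open(self.outdir / "config.resolved.yaml", "w",
                      encoding="utf-8") as fh:
                yaml.safe_dump(config.model_dump(), fh, sort_keys=True)
        self.info(f"python {sys.version.split()[0]}")

    def info(self, msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        self._fh.write(f"{stamp} {msg}\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()
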