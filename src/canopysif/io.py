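"""Text I/O: spectra, retrieval-window tables, run configuration.

Spectra travel as two-column comma-delimited text with a
``wavelength_nm,value`` header; ``#`` lines are comments and carry
provenance (unit, seed).  Window tables use the same comma-delimited
layout as the bundled ``data/windows.csv``.  Configuration files are
flat YAML key/value mappings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .retrieval import RetrievalWindow
from .spectra import Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "load_windows",
    "load_config",
    "write_manifest",
]


def read_spectrum(path, unit: str = "radiance") -> Spectrum:
    """Read a two-column wavelength/value text file.

    The unit comes from the caller (CLI flag or sidecar); a ``# unit:``
    comment in the file takes precedence.  Parse failures report the
    offending line number.
    """
    path = Path(path)
    wl, values = [], []
    with path.open() as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("unit:"):
                    unit = body.split(":", 1)[1].strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != "wavelength_nm,value":
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'wavelength_nm,value', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            if not (np.isfinite(w) and np.isfinite(v)):
                raise ValueError(f"{path}:{lineno}: non-finite value")
            wl.append(w)
            values.append(v)
    if not wl:
        raise ValueError(f"{path}: no data rows")
    if np.any(np.diff(wl) <= 0):
        raise ValueError(f"{path}: wavelengths must be strictly increasing")
    return Spectrum(np.array(wl), np.array(values), unit)


def write_spectrum(spectrum: Spectrum, path, seed: int | None = None) -> None:
    """Write a spectrum with deterministic formatting and provenance comments."""
    if len(spectrum) == 0:
        raise ValueError("refusing to write an empty spectrum")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# unit: {spectrum.unit}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        fh.write("wavelength_nm,value\n")
        for w, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{w:.6f},{v:.12e}\n")


def load_windows(path) -> list[RetrievalWindow]:
    """Load retrieval windows from a delimited table.

    Columns: band, algorithm, lambda_in, lambda_left, lambda_right,
    degree_r, degree_f (and optionally label).  Validation errors name
    the offending row.
    """
    df = pd.read_csv(path, comment="#")
    windows = []
    for i, row in df.iterrows():
        try:
            windows.append(
                RetrievalWindow(
                    algorithm=str(row["algorithm"]),
                    band=str(row["band"]),
                    lambda_in=float(row["lambda_in"]),
                    lambda_left=float(row["lambda_left"]),
                    lambda_right=None
                    if pd.isna(row.get("lambda_right"))
                    else float(row["lambda_right"]),
                    degree_r=None if pd.isna(row.get("degree_r")) else int(row["degree_r"]),
                    degree_f=None if pd.isna(row.get("degree_f")) else int(row["degree_f"]),
                    label=str(row.get("label", "")) if not pd.isna(row.get("label")) else "",
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: invalid window in row {i + 1}: {exc}") from exc
    return windows


def load_config(path) -> dict:
    """Flat key/value configuration (YAML)."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def write_manifest(path, config: dict, seed: int, version: str) -> None:
    """Echo the run configuration so outputs are byte-reproducible."""
    manifest = {"version": version, "seed": seed, "config": config}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
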