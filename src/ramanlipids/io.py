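"""Text file formats: spectra, hypercubes, band images.

All formats are plain delimited text for diffability.  Numeric values are
written with 12 significant digits, so a write/read round trip reproduces
values bit-for-bit at that precision.

* Spectrum: two columns (wavenumber_cm1, intensity) with ``#``-prefixed
  ``key: value`` header lines; ``excitation_nm`` is mandatory.
* Hypercube: long-format table (x_idx, y_idx, wavenumber_cm1, intensity)
  plus a sidecar ``key: value`` metadata file (nx, ny, step_um, origin,
  excitation_nm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError
from .hypermap import Hypercube
from .spectrum import Spectrum

__all__ = ["read_spectrum", "write_spectrum", "read_hypercube",
           "write_hypercube"]

_FMT = "%.12g"


def write_spectrum(path, s: Spectrum) -> None:
    """Write a spectrum as two-column text with '#'-prefixed header."""
    with open(path, "w") as fh:
        fh.write(f"# excitation_nm: {s.excitation_nm}\n")
        for k, v in s.meta.items():
            if k == "excitation_nm":
                continue
            fh.write(f"# {k}: {v}\n")
        for w, y in zip(s.wavenumbers, s.intensities):
            fh.write(f"{w:.12g}\t{y:.12g}\n")


def read_spectrum(path) -> Spectrum:
    """Parse a two-column spectrum file.

    Raises
    ------
    FormatError
        Naming the offending line for ragged rows, unparsable numbers or a
        non-increasing axis; or when the excitation_nm header is missing.
    """
    meta: dict[str, str] = {}
    ws: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, sep, val = line.lstrip("#").partition(":")
                if sep:
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                w, y = float(parts[0]), float(parts[1])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: unparsable number")
            if ws and w <= ws[-1]:
                raise FormatError(
                    f"{path}: line {lineno}: wavenumber axis not strictly "
                    f"increasing ({w} after {ws[-1]})")
            ws.append(w)
            ys.append(y)
    if "excitation_nm" not in meta:
        raise FormatError(f"{path}: missing required header 'excitation_nm'")
    try:
        ex = int(meta["excitation_nm"])
    except ValueError:
        raise FormatError(f"{path}: bad excitation_nm {meta['excitation_nm']!r}")
    if not ws:
        raise FormatError(f"{path}: no data rows")
    return Spectrum(np.array(ws), np.array(ys), ex, meta)


def write_hypercube(path, sidecar, h: Hypercube) -> None:
    """Write a hypercube as a long-format table plus a sidecar metadata file."""
    with open(sidecar, "w") as fh:
        fh.write(f"nx: {h.nx}\nny: {h.ny}\n")
        fh.write(f"step_um: {h.step:.12g}\n")
        fh.write(f"origin_x_um: {h.origin[0]:.12g}\n")
        fh.write(f"origin_y_um: {h.origin[1]:.12g}\n")
        fh.write(f"excitation_nm: {h.excitation_nm}\n")
    with open(path, "w") as fh:
        fh.write("x_idx\ty_idx\twavenumber_cm1\tintensity\n")
        for iy in range(h.ny):
            for ix in range(h.nx):
                for w, y in zip(h.wavenumbers, h.intensities[iy, ix]):
                    fh.write(f"{ix}\t{iy}\t{w:.12g}\t{y:.12g}\n")


def _read_sidecar(sidecar) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(sidecar) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, sep, v = line.partition(":")
            if not sep:
                raise FormatError(f"{sidecar}: bad sidecar line {line!r}")
            out[k.strip()] = v.strip()
    return out


def read_hypercube(path, sidecar) -> Hypercube:
    """Read a long-format hypercube and its sidecar.

    Raises
    ------
    FormatError
        Listing missing or duplicated pixels, and on any shape mismatch
        between table and sidecar.
    """
    sc = _read_sidecar(sidecar)
    try:
        nx, ny = int(sc["nx"]), int(sc["ny"])
        step = float(sc["step_um"])
        origin = (float(sc.get("origin_x_um", 0.0)),
                  float(sc.get("origin_y_um", 0.0)))
        ex = int(sc["excitation_nm"])
    except KeyError as exc:
        raise FormatError(f"{sidecar}: missing sidecar key {exc}")
    except ValueError as exc:
        raise FormatError(f"{sidecar}: bad sidecar value: {exc}")

    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable table: {exc}")
    need = {"x_idx", "y_idx", "wavenumber_cm1", "intensity"}
    if set(df.columns) != need:
        raise FormatError(f"{path}: expected columns {sorted(need)}, "
                          f"got {list(df.columns)}")
    wavenumbers = np.sort(df["wavenumber_cm1"].unique())
    nw = wavenumbers.size

    counts = df.groupby(["x_idx", "y_idx"]).size()
    expected = {(ix, iy) for ix in range(nx) for iy in range(ny)}
    present = set(counts.index)
    missing = sorted(expected - present)
    extra = sorted(present - expected)
    if missing or extra:
        msg = []
        if missing:
            msg.append(f"missing pixels {missing[:5]}")
        if extra:
            msg.append(f"unexpected pixels {extra[:5]}")
        raise FormatError(f"{path}: {'; '.join(msg)} (sidecar says {nx}x{ny})")
    bad = counts[counts != nw]
    if len(bad):
        raise FormatError(
            f"{path}: pixels with duplicate/missing wavenumber rows: "
            f"{list(bad.index[:5])}")

    df = df.sort_values(["y_idx", "x_idx", "wavenumber_cm1"])
    cube = df["intensity"].to_numpy().reshape(ny, nx, nw)
    return Hypercube(intensities=cube, wavenumbers=wavenumbers,
                     excitation_nm=ex, step=step, origin=origin)
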