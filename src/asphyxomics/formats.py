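"""Spectrum serialization: tabular text and a JCAMP-DX-style dialect.

Two plain-text dialects carry the same information:

* ``tabular``: a commented header (material, sample id, metadata) followed
  by whitespace-separated columns ``ppm  real  imaginary``.
* ``jcamp``: a JCAMP-DX-flavoured single-spectrum file using ``##KEY=``
  labelled-data records and an ``##XYPOINTS=(XY..XY)`` block with
  ``x, yreal[, yimag]`` rows.  This is a self-contained dialect, not a
  full JCAMP-DX implementation (vendor raw formats are out of scope).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .spectrum import Spectrum

__all__ = ["write_spectrum", "read_spectrum"]


def write_spectrum(s: Spectrum, path: str | Path, dialect: str = "tabular") -> None:
    path = Path(path)
    imag = np.imag(s.intensity) if s.is_complex else np.zeros_like(s.real)
    if dialect == "tabular":
        with open(path, "w") as fh:
            fh.write(f"# material: {s.material}\n")
            fh.write(f"# sample_id: {s.sample_id}\n")
            fh.write(f"# meta: {json.dumps(_jsonable(s.meta))}\n")
            if s.qc:
                fh.write(f"# qc: {json.dumps(_jsonable(s.qc))}\n")
            fh.write("# ppm\treal\timag\n")
            for x, yr, yi in zip(s.ppm, s.real, imag):
                fh.write(f"{x:.10g}\t{yr:.10g}\t{yi:.10g}\n")
    elif dialect == "jcamp":
        with open(path, "w") as fh:
            fh.write(f"##TITLE={s.sample_id or 'spectrum'}\n")
            fh.write("##JCAMP-DX=5.01 (asphyxomics dialect)\n")
            fh.write("##DATA TYPE=NMR SPECTRUM\n")
            fh.write(f"##.MATERIAL={s.material}\n")
            fh.write(f"##.META={json.dumps(_jsonable(s.meta))}\n")
            if s.qc:
                fh.write(f"##.QC={json.dumps(_jsonable(s.qc))}\n")
            fh.write("##XUNITS=PPM\n")
            fh.write(f"##NPOINTS={s.ppm.size}\n")
            fh.write(f"##FIRSTX={s.ppm[0]:.10g}\n")
            fh.write(f"##LASTX={s.ppm[-1]:.10g}\n")
            fh.write("##XYPOINTS=(XY..XY)\n")
            for x, yr, yi in zip(s.ppm, s.real, imag):
                fh.write(f"{x:.10g}, {yr:.10g}, {yi:.10g}\n")
            fh.write("##END=\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        if isinstance(v, dict):
            v = _jsonable(v)
        out[k] = v
    return out


def _parse_rows(rows, path):
    ppm, re_, im_ = [], [], []
    for lineno, text in rows:
        parts = text.replace(",", " ").split()
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{lineno}: expected 2-3 columns, got {text!r}")
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric value in {text!r}") from None
        if any(np.isnan(v) for v in vals):
            raise ValueError(f"{path}:{lineno}: NaN intensity")
        ppm.append(vals[0])
        re_.append(vals[1])
        im_.append(vals[2] if len(vals) == 3 else 0.0)
    return np.array(ppm), np.array(re_), np.array(im_)


def read_spectrum(path: str | Path, dialect: str | None = None) -> Spectrum:
    """Read either dialect (auto-detected from the first line by default).

    Raises ``ValueError`` with the offending line number for malformed or
    NaN rows and for a non-monotone axis.  The returned spectrum has an
    empty processing history.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect is None:
        dialect = "jcamp" if lines and lines[0].startswith("##") else "tabular"

    material, sample_id, meta = "plasma", "", {}
    qc: dict = {}
    rows = []
    if dialect == "tabular":
        for lineno, line in enumerate(lines, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text.lstrip("# ")
                if body.startswith("material:"):
                    material = body.split(":", 1)[1].strip()
                elif body.startswith("sample_id:"):
                    sample_id = body.split(":", 1)[1].strip()
                elif body.startswith("meta:"):
                    meta = json.loads(body.split(":", 1)[1])
                elif body.startswith("qc:"):
                    qc = json.loads(body.split(":", 1)[1])
                continue
            rows.append((lineno, text))
    elif dialect == "jcamp":
        in_data = False
        for lineno, line in enumerate(lines, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("##"):
                key, _, val = text[2:].partition("=")
                key = key.strip().upper()
                if key == "XYPOINTS":
                    in_data = True
                elif key == "END":
                    in_data = False
                elif key == ".MATERIAL":
                    material = val.strip()
                elif key == ".META":
                    meta = json.loads(val)
                elif key == ".QC":
                    qc = json.loads(val)
                elif key == "TITLE":
                    sample_id = val.strip()
                continue
            if in_data:
                rows.append((lineno, text))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not rows:
        raise ValueError(f"{path}: no data rows found")
    ppm, re_, im_ = _parse_rows(rows, path)
    if not np.all(np.diff(ppm) > 0):
        raise ValueError(f"{path}: ppm axis is not strictly increasing")
    intensity = re_ + 1j * im_ if np.any(im_ != 0) else re_
    if sample_id == "spectrum":
        sample_id = ""
    return Spectrum(ppm=ppm, intensity=intensity, material=material,
                    sample_id=sample_id, meta=meta, qc=qc)
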