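"""TSP-referenced metabolite quantification from preprocessed spectra.

Signal areas are trapezoidal integrals over per-metabolite ppm windows and
are converted to mM by proportionality with the TSP reference:

    c = (area / protons) / (tsp_area / 9) * tsp_conc

Windows are the panel position +- (multiplet half-span + 2x the expected
linewidth), truncated at the midpoint towards any neighbouring panel
signal.  Because both the metabolite windows and the TSP integration
window capture only part of a Lorentzian's tails, each integral is
divided by the analytic capture fraction of its window (the Lorentzian
CDF share between the window edges), which puts metabolite and reference
areas on equal footing; narrow windows then minimize noise and
neighbour bleed without biasing the ratio.  Overlapping multiplets (e.g.
succinate 2.40 vs pyruvate 2.37 ppm in plasma) are integrated on the
truncated windows without deconvolution, which limits their individual
accuracy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import MetabolitePanel
from .conctable import ConcentrationTable
from .render import AcquisitionParams, multiplet_lines
from .spectrum import Spectrum

__all__ = [
    "integrate_signal",
    "area_to_concentration",
    "integration_windows",
    "capture_fraction",
    "peak_mask_windows",
    "quantify_spectrum",
    "quantify_cohort",
    "creatinine_normalize",
]


def integrate_signal(s: Spectrum, window: tuple[float, float]) -> float:
    """Trapezoidal integral of the real intensity over a ppm window.

    Negative totals are floored at 0 with a warning.  A window containing
    no retained points (fully excised) raises ``ValueError``.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window must be ordered, got {window}")
    mask = s.window(lo, hi)
    if not mask.any():
        raise ValueError(f"integration window {window} is fully excised")
    area = float(np.trapezoid(s.real[mask], s.ppm[mask]))
    # fractional edge trapezoids so the integral covers [lo, hi] exactly
    # (narrow windows would otherwise be biased by up to a grid step)
    idx = np.flatnonzero(mask)
    i0, i1 = idx[0], idx[-1]
    step = s.step
    if i0 > 0 and s.ppm[i0] - s.ppm[i0 - 1] < 1.5 * step and s.ppm[i0] > lo:
        y_lo = float(np.interp(lo, s.ppm[i0 - 1:i0 + 1], s.real[i0 - 1:i0 + 1]))
        area += 0.5 * (y_lo + s.real[i0]) * (s.ppm[i0] - lo)
    if i1 < s.ppm.size - 1 and s.ppm[i1 + 1] - s.ppm[i1] < 1.5 * step \
            and s.ppm[i1] < hi:
        y_hi = float(np.interp(hi, s.ppm[i1:i1 + 2], s.real[i1:i1 + 2]))
        area += 0.5 * (s.real[i1] + y_hi) * (hi - s.ppm[i1])
    if area < 0:
        warnings.warn(f"negative integral {area:.3g} in window {window}; floored at 0")
        return 0.0
    return area


def area_to_concentration(area: float, protons: int, tsp_area: float,
                          tsp_conc: float) -> float:
    """Convert a signal area to mM relative to the 9-proton TSP singlet."""
    if tsp_area <= 0:
        raise ValueError(f"TSP area must be positive, got {tsp_area}")
    if protons < 1:
        raise ValueError("protons must be >= 1")
    return (area / protons) / (tsp_area / 9.0) * tsp_conc


def integration_windows(
    panel: MetabolitePanel,
    acq: AcquisitionParams = AcquisitionParams(),
    margin_fwhm: float = 2.0,
) -> dict[str, tuple[float, float]]:
    """Per-signal integration windows, truncated at neighbour midpoints."""
    spans = {}
    for spec in panel.signals:
        offs = [off for off, _w in multiplet_lines(spec.multiplicity, acq)]
        spans[spec.name] = (min(offs), max(offs))
    order = sorted(panel.signals, key=lambda sp: sp.ppm)
    windows: dict[str, tuple[float, float]] = {}
    margin = margin_fwhm * acq.linewidth
    for i, spec in enumerate(order):
        lo = spec.ppm + spans[spec.name][0] - margin
        hi = spec.ppm + spans[spec.name][1] + margin
        if i > 0:
            lo = max(lo, 0.5 * (order[i - 1].ppm + spec.ppm))
        if i < len(order) - 1:
            hi = min(hi, 0.5 * (spec.ppm + order[i + 1].ppm))
        windows[spec.name] = (lo, hi)
    return windows


#: default half-margin (in FWHM multiples) of the known-signal windows the
#: adaptive baseline bridges; the capture correction assumes the baseline
#: anchors on the multiplet's own wings at this distance
DEFAULT_MASK_MARGIN_FWHM = 6.0


def capture_fraction(spec, window: tuple[float, float],
                     acq: AcquisitionParams,
                     baseline_margin_fwhm: float | None = DEFAULT_MASK_MARGIN_FWHM,
                     ) -> float:
    """Effective share of a multiplet's area measured inside a ppm window.

    The first term is the Lorentzian CDF share between the window edges.
    When ``baseline_margin_fwhm`` is given, the adaptive baseline is
    assumed to have removed a flat floor at the multiplet's own wing
    height ``baseline_margin_fwhm`` FWHM outside its outermost lines (where
    the baseline anchors), and the corresponding area share is deducted.
    """
    gamma = acq.linewidth / 2.0
    lo, hi = window
    lines = multiplet_lines(spec.multiplicity, acq)
    cap = 0.0
    for off, weight in lines:
        pos = spec.ppm + off
        cap += weight * (np.arctan((hi - pos) / gamma)
                         + np.arctan((pos - lo) / gamma)) / np.pi
    if baseline_margin_fwhm is not None:
        margin = baseline_margin_fwhm * acq.linewidth
        anchors = (spec.ppm + min(o for o, _ in lines) - margin,
                   spec.ppm + max(o for o, _ in lines) + margin)
        level = np.mean([
            sum(w * gamma / (np.pi * ((a - (spec.ppm + o)) ** 2 + gamma ** 2))
                for o, w in lines)
            for a in anchors
        ])
        cap -= (hi - lo) * float(level)
    return float(cap)


def peak_mask_windows(
    panel: MetabolitePanel,
    acq: AcquisitionParams = AcquisitionParams(),
    margin_fwhm: float = DEFAULT_MASK_MARGIN_FWHM,
    with_tsp: bool = True,
) -> tuple[tuple[float, float], ...]:
    """ppm intervals known to hold signals, for baseline bridging."""
    out = []
    for spec in panel.signals:
        offs = [off for off, _w in multiplet_lines(spec.multiplicity, acq)]
        out.append((spec.ppm + min(offs) - margin_fwhm * acq.linewidth,
                    spec.ppm + max(offs) + margin_fwhm * acq.linewidth))
    if with_tsp:
        out.append((-0.05, 0.05))
    return tuple(out)


def quantify_spectrum(
    s: Spectrum,
    panel: MetabolitePanel,
    tsp_conc: float,
    acq: AcquisitionParams = AcquisitionParams(),
    windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Quantify every panel signal in one preprocessed spectrum.

    Uses ``qc['tsp_area']`` (1 after normalization) as the reference area;
    unidentified signals get the same formula but their values are
    arbitrary units.
    """
    tsp_area = s.qc.get("tsp_area")
    if tsp_area is None:
        raise ValueError(
            "spectrum has no TSP area on record; run normalize_to_tsp first")
    tsp_full = tsp_area / s.qc.get("tsp_capture", 1.0)
    if windows is None:
        windows = integration_windows(panel, acq)
    floors = _local_floors(s, panel, windows, acq)
    out = {}
    for spec in panel.signals:
        win = windows[spec.name]
        lo, hi = win
        floor, anchor_fwhm = floors[spec.name]
        area = integrate_signal(s, win) - floor * (hi - lo)
        area = max(area, 0.0)
        area /= capture_fraction(spec, win, acq,
                                 baseline_margin_fwhm=anchor_fwhm)
        out[spec.name] = area_to_concentration(area, spec.protons, tsp_full,
                                               tsp_conc)
    return out


#: collar placement (in FWHM multiples outside the window edge) for the
#: local-floor estimate under each integration window
_COLLAR_IN, _COLLAR_OUT = 1.0, 4.0


def _local_floors(s: Spectrum, panel, windows, acq):
    """Median residual level in collars flanking each integration window.

    Any smooth background the adaptive baseline left behind (e.g. lipid
    band residue) shows up in the collars and is subtracted as a flat
    floor.  A collar is used only where it does not intrude into another
    signal's window; windows truncated on both sides keep no local floor
    and fall back to the default bridge-anchor capture correction.
    Returns name -> (floor level, effective capture anchor distance).
    """
    all_wins = sorted(windows.values())
    out = {}
    fw = acq.linewidth
    for spec in panel.signals:
        lo, hi = windows[spec.name]
        levels = []
        for side_lo, side_hi in (
            (lo - _COLLAR_OUT * fw, lo - _COLLAR_IN * fw),
            (hi + _COLLAR_IN * fw, hi + _COLLAR_OUT * fw),
        ):
            if any(side_lo < w_hi and side_hi > w_lo
                   for w_lo, w_hi in all_wins
                   if (w_lo, w_hi) != (lo, hi)):
                continue
            mask = s.window(side_lo, side_hi)
            if mask.sum() >= 3:
                levels.append(float(np.median(s.real[mask])))
        if levels:
            # collar center sits (window margin + collar middle) FWHM
            # beyond the outermost line; the own-wing share subtracted
            # with the floor is deducted at that distance
            anchor = 2.0 + 0.5 * (_COLLAR_IN + _COLLAR_OUT)
            out[spec.name] = (float(np.mean(levels)), anchor)
        else:
            out[spec.name] = (0.0, DEFAULT_MASK_MARGIN_FWHM)
    return out


def quantify_cohort(
    spectra,
    panel: MetabolitePanel,
    tsp_conc: float,
    acq: AcquisitionParams = AcquisitionParams(),
    meta: pd.DataFrame | None = None,
) -> ConcentrationTable:
    """Quantify a list of preprocessed spectra into a concentration table
    (plus per-sample QC columns in the metadata)."""
    windows = integration_windows(panel, acq)
    rows, qc_rows, skipped = [], [], []
    for s in spectra:
        if s.qc.get("tsp_area") is None:
            skipped.append(s.sample_id)
            continue
        vals = quantify_spectrum(s, panel, tsp_conc, acq, windows)
        rows.append({"sample_id": s.sample_id, **vals})
        qc_rows.append({
            "sample_id": s.sample_id,
            "tsp_area": s.qc.get("tsp_area_raw", np.nan),
            "tsp_fwhm_ppm": s.qc.get("tsp_fwhm_ppm", np.nan),
            "phase_deg": s.qc.get("phase_deg", np.nan),
            "ppm_shift": s.qc.get("ppm_shift", np.nan),
        })
    if skipped:
        warnings.warn(
            f"{len(skipped)} spectrum/spectra without a usable TSP reference "
            f"skipped: {skipped[:5]}")
    if not rows:
        raise ValueError("no spectrum had a usable TSP reference")
    values = pd.DataFrame(rows).set_index("sample_id")
    qc = pd.DataFrame(qc_rows).set_index("sample_id")
    if meta is not None:
        qc = meta.join(qc, how="right")
    units = {sp.name: ("mM" if sp.identified else "a.u.") for sp in panel.signals}
    return ConcentrationTable(values=values, units=units, meta=qc,
                              flags={"no_tsp_reference": skipped})


def creatinine_normalize(
    table: ConcentrationTable, creatinine: str = "Creatinine"
) -> ConcentrationTable:
    """Divide each urine metabolite by the same-sample creatinine.

    Samples with zero or missing creatinine are excluded and listed in
    ``flags['creatinine_excluded']`` rather than silently dropped.
    """
    if creatinine not in table.values.columns:
        raise KeyError(f"column {creatinine!r} missing from the table")
    cre = table.values[creatinine]
    bad = cre.index[(cre <= 0) | cre.isna()].tolist()
    keep = [i for i in table.values.index if i not in set(bad)]
    if bad:
        warnings.warn(
            f"{len(bad)} sample(s) excluded from creatinine normalization: {bad}")
    values = table.values.loc[keep].div(cre.loc[keep], axis=0)
    units = {m: (u if u == "a.u." else "mM/mM creatinine")
             for m, u in table.units.items()}
    units[creatinine] = "ratio"
    meta = table.meta.loc[keep] if table.meta is not None else None
    out = ConcentrationTable(values=values, units=units, meta=meta,
                             creatinine_normalized=True,
                             flags={**table.flags, "creatinine_excluded": bad})
    return out
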