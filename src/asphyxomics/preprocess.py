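"""Spectral preprocessing chain for TSP-referenced 1H-NMR spectra.

The standard order, applied by :func:`preprocess_pipeline`, is

    1. zero-order phase correction on the TSP signal
    2. separate linear baselines up- and downfield of the water artifact
    3. chemical-shift referencing (plasma: glucose doublet near 5.23 ppm;
       urine: TSP at 0.0 ppm)
    4. clipping to the -0.5 ... 9.0 ppm range
    5. normalization to the area under the TSP signal
    6. TSP full-width-at-half-maximum measurement (lipoprotein proxy)
    7. adaptive nonlinear baseline subtraction (asymmetric penalized
       smoothing, removing broad lipid/protein or urea backgrounds)
    8. excision of the water, TSP and (urine) urea regions

Every operation appends one history entry and records its quality-control
scalars (phase angle, ppm shift, TSP area and FWHM) on ``Spectrum.qc``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded

from .spectrum import RegionSet, Spectrum, default_regions

__all__ = [
    "PreprocessConfig",
    "phase_correct_zero_order",
    "subtract_linear_baselines",
    "reference_axis",
    "clip",
    "clip_and_excise",
    "normalize_to_tsp",
    "measure_tsp_fwhm",
    "adaptive_baseline",
    "preprocess_pipeline",
]

#: default search window for the TSP signal
TSP_WINDOW = (-0.2, 0.2)

#: default referencing anchors: (search window, target ppm).  The plasma
#: anchor targets the low-field line of the glucose anomeric doublet
#: (doublet printed at 5.24 ppm, default J 0.012 ppm -> line at 5.234).
PLASMA_ANCHOR = ((5.14, 5.34), 5.234)
URINE_ANCHOR = ((-0.2, 0.2), 0.0)


@dataclass(frozen=True)
class PreprocessConfig:
    material: str = "plasma"
    regions: RegionSet | None = None
    tsp_window: tuple[float, float] = TSP_WINDOW
    anchor: tuple[tuple[float, float], float] | None = None
    #: TSP integration half-width as a multiple of the measured TSP FWHM
    tsp_integration_fwhm: float = 10.0
    #: adaptive baseline: smoothness (index units), asymmetry, iterations,
    #: noise-band half-width (in noise sd), and known-signal ppm windows
    #: that the baseline bridges rather than climbs into
    baseline_lam: float = 3e4
    baseline_p: float = 3e-4
    baseline_iter: int = 15
    baseline_czone: float = 1.0
    peak_windows: tuple = ()

    def resolved_regions(self) -> RegionSet:
        return self.regions if self.regions is not None else default_regions(self.material)

    def resolved_anchor(self):
        if self.anchor is not None:
            return self.anchor
        return PLASMA_ANCHOR if self.material == "plasma" else URINE_ANCHOR


# --------------------------------------------------------------------------
# peak helpers

def _refine_peak(ppm: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid peak position/height by parabolic interpolation around i."""
    if 0 < i < y.size - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            step = ppm[min(i + 1, ppm.size - 1)] - ppm[i] if i + 1 < ppm.size \
                else ppm[i] - ppm[i - 1]
            height = y1 - 0.25 * (y0 - y2) * delta
            return float(ppm[i] + delta * step), float(height)
    return float(ppm[i]), float(y[i])


def _find_peak(s: Spectrum, window: tuple[float, float]):
    mask = s.window(*window)
    if not mask.any():
        raise ValueError(f"no spectral points in window {window}")
    idx = np.flatnonzero(mask)
    y = np.abs(s.intensity[idx]) if s.is_complex else s.real[idx]
    j = int(np.argmax(y))
    return idx[j], y


# --------------------------------------------------------------------------
# operations

def phase_correct_zero_order(
    s: Spectrum, tsp_window: tuple[float, float] = TSP_WINDOW
) -> Spectrum:
    """Rotate a complex spectrum by the angle that maximizes the real-part
    height of the TSP peak.

    Real-only input passes through unchanged with a warning.  The applied
    angle (degrees) is recorded in ``qc['phase_deg']``.
    """
    if not s.is_complex:
        warnings.warn("phase correction skipped: real-valued spectrum")
        out = s.evolve("phase_correct_zero_order", {"skipped": True})
        out.qc.setdefault("phase_deg", 0.0)
        return out
    mask = s.window(*tsp_window)
    if not mask.any():
        raise ValueError(f"TSP window {tsp_window} contains no points")
    win = s.intensity[mask]
    if np.max(np.abs(win)) == 0:
        raise ValueError("TSP window is empty (zero intensity)")

    # The magnitude spectrum is phase-invariant, so the TSP apex can be
    # located first; the rotation maximizing the real-part height is then
    # the argument of the complex signal integrated over a window
    # symmetric about the apex (the antisymmetric dispersion cancels).
    # A local complex baseline, estimated from a collar around the window,
    # removes slowly varying tails of remote signals (e.g. water).
    idx = np.flatnonzero(mask)
    mag = np.abs(s.intensity)
    center, _h = _refine_peak(s.ppm, mag, idx[int(np.argmax(mag[idx]))])
    half = 0.03
    core = s.window(center - half, center + half)
    collar = s.window(center - 3 * half, center + 3 * half) & ~core
    if not core.any():
        raise ValueError("TSP window is empty around the detected apex")
    base = s.intensity[collar].mean() if collar.any() else 0.0
    integral = np.trapezoid(s.intensity[core] - base, s.ppm[core])
    phi = float(np.rad2deg(np.angle(integral)))

    out_int = s.intensity * np.exp(-1j * np.deg2rad(phi))
    out = s.evolve("phase_correct_zero_order", {"phase_deg": -phi},
                   intensity=out_int)
    out.qc["phase_deg"] = out.qc.get("phase_deg", 0.0) - phi
    return out


def _support_line(ppm: np.ndarray, y: np.ndarray, n_chunks: int = 50,
                  tau: float = 0.25):
    """Robust baseline line through per-chunk low-decile support points.

    Support points are the lowest-decile intensities of consecutive
    chunks (robust to peaks); the line is a quantile regression at level
    ``tau`` through them, so broad humps elevating a minority of chunks
    cannot drag the line off the true baseline level.
    """
    n = ppm.size
    n_chunks = max(4, min(n_chunks, n // 4))
    bounds = np.linspace(0, n, n_chunks + 1).astype(int)
    xs, ys = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 1:
            continue
        chunk = y[a:b]
        k = max(1, int(0.1 * (b - a)))
        sel = np.argsort(chunk)[:k]
        xs.append(ppm[a:b][sel])
        ys.append(chunk[sel])
    x = np.concatenate(xs)
    v = np.concatenate(ys)
    if np.allclose(v, v[0]):
        return np.array([0.0, v[0]])
    try:
        from statsmodels.regression.quantile_regression import QuantReg
        X = np.column_stack([x, np.ones_like(x)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = QuantReg(v, X).fit(q=tau)
        return np.asarray(res.params)
    except Exception:
        return np.polyfit(x, v, 1)


def subtract_linear_baselines(
    s: Spectrum, water: tuple[float, float] = (4.5, 5.0)
) -> Spectrum:
    """Subtract independent straight lines from the regions up- and
    downfield of the water artifact.

    Support points are the lowest-decile intensities of consecutive chunks
    on each side, which makes the fit robust to peaks.  Operates on the
    real part; the chain is real-valued from here on.
    """
    lo_mask = s.ppm < water[0]
    hi_mask = s.ppm >= water[1]
    if not lo_mask.any() or not hi_mask.any():
        raise ValueError("water interval covers an entire side of the spectrum")
    y = s.real.astype(float).copy()
    params = {}
    for name, mask in (("downfield", lo_mask), ("upfield", hi_mask)):
        coef = _support_line(s.ppm[mask], y[mask])
        y[mask] -= np.polyval(coef, s.ppm[mask])
        params[name] = [float(c) for c in coef]
    return s.evolve("subtract_linear_baselines", {"water": water, **params},
                    intensity=y)


def reference_axis(
    s: Spectrum, anchor: tuple[tuple[float, float], float],
    doublet_j: float | None = 0.012,
) -> Spectrum:
    """Shift the ppm axis so the detected anchor peak lands on its target.

    The anchor peak is the highest local maximum in the search window.
    If the two strongest maxima are separated by roughly ``doublet_j``
    (an anchor that is itself a doublet, such as the glucose anomeric
    doublet), the low-ppm line is used; other near-ties are broken by
    proximity to the target ppm.  The applied shift is recorded in
    ``qc['ppm_shift']``.
    """
    (win, target) = anchor
    mask = s.window(*win)
    if not mask.any():
        raise ValueError(f"anchor window {win} contains no points")
    idx = np.flatnonzero(mask)
    y = s.real[idx]
    noise = 1.4826 * np.median(np.abs(y - np.median(y)))
    ymax = float(y.max())
    if ymax <= np.median(y) + 5 * noise or ymax <= 0:
        raise ValueError(
            f"no peak above noise floor in anchor window {win} "
            f"(target {target} ppm)")
    # candidate local maxima within 50% of the top
    cand = []
    for j in range(1, y.size - 1):
        if y[j] >= y[j - 1] and y[j] >= y[j + 1] and y[j] >= 0.5 * ymax:
            cand.append(j)
    if not cand:
        cand = [int(np.argmax(y))]
    # doublet anchors (e.g. the glucose anomeric doublet): if the two
    # strongest candidates sit one J-spacing apart, the low-ppm line is
    # the anchor regardless of any global referencing offset; otherwise
    # near-ties are broken by proximity to the target
    cand.sort(key=lambda j: -y[j])
    best = None
    if len(cand) >= 2 and doublet_j is not None:
        a, b = sorted(cand[:2], key=lambda j: s.ppm[idx[j]])
        sep = s.ppm[idx[b]] - s.ppm[idx[a]]
        if 0.6 * doublet_j <= sep <= 1.4 * doublet_j:
            best = a
    if best is None:
        near = [j for j in cand if y[j] >= 0.8 * y[cand[0]]]
        best = min(near, key=lambda j: abs(s.ppm[idx[j]] - target))
    pos, _h = _refine_peak(s.ppm, s.real, idx[best])
    shift = float(target - pos)
    out = s.evolve("reference_axis", {"window": win, "target": target,
                                      "shift": shift}, ppm=s.ppm + shift)
    out.qc["ppm_shift"] = out.qc.get("ppm_shift", 0.0) + shift
    return out


def clip(s: Spectrum, bounds: tuple[float, float] = (-0.5, 9.0)) -> Spectrum:
    """Restrict the axis to the half-open interval [lo, hi)."""
    mask = s.window(*bounds)
    if not mask.any():
        raise ValueError("clipping removed every point")
    return s.evolve("clip", {"bounds": bounds},
                    ppm=s.ppm[mask], intensity=s.intensity[mask])


def clip_and_excise(s: Spectrum, regions: RegionSet) -> Spectrum:
    """Clip to the retained range and delete the named regions
    (water, TSP and, for urine, the urea band)."""
    regions.validate()
    keep = s.window(*regions.clip)
    for _name, (a, b) in regions.excised():
        keep &= ~s.window(a, b)
    if not keep.any():
        raise ValueError("clip/excision removed every point")
    return s.evolve(
        "clip_and_excise",
        {"clip": regions.clip,
         "excised": {n: list(iv) for n, iv in regions.excised()}},
        ppm=s.ppm[keep], intensity=s.intensity[keep])


def _tsp_peak_and_fwhm(s: Spectrum, tsp_window: tuple[float, float]):
    i, _ = _find_peak(s, tsp_window)
    y = s.real
    pos, height = _refine_peak(s.ppm, y, i)
    if height <= 0:
        raise ValueError("TSP peak has non-positive height")
    half = height / 2.0
    # walk outwards to the half-height crossings, linear interpolation
    left = right = None
    j = i
    while j > 0 and y[j] > half:
        j -= 1
    if y[j] <= half and j < i:
        f = (half - y[j]) / (y[j + 1] - y[j])
        left = s.ppm[j] + f * (s.ppm[j + 1] - s.ppm[j])
    k = i
    while k < y.size - 1 and y[k] > half:
        k += 1
    if y[k] <= half and k > i:
        f = (half - y[k]) / (y[k - 1] - y[k])
        right = s.ppm[k] - f * (s.ppm[k] - s.ppm[k - 1])
    if left is None or right is None:
        raise ValueError("TSP peak not resolved above noise (no half-height crossings)")
    return pos, float(right - left)


def measure_tsp_fwhm(
    s: Spectrum, tsp_window: tuple[float, float] = TSP_WINDOW
) -> float:
    """TSP full width at half maximum (ppm) via linearly interpolated
    half-height crossings."""
    _pos, fwhm = _tsp_peak_and_fwhm(s, tsp_window)
    return fwhm


def normalize_to_tsp(
    s: Spectrum,
    tsp_window: tuple[float, float] = TSP_WINDOW,
    integration_fwhm: float = 10.0,
) -> Spectrum:
    """Divide the spectrum by the trapezoidal area under the TSP signal.

    The integration window is the detected TSP center +- ``integration_fwhm``
    times the measured FWHM.  The pre-normalization area is stored in
    ``qc['tsp_area_raw']``; after the operation the TSP area is 1 by
    construction.
    """
    pos, fwhm = _tsp_peak_and_fwhm(s, tsp_window)
    # cap the window so heavily broadened TSP peaks do not integrate into
    # curved background territory far from 0 ppm
    half = min(integration_fwhm * fwhm, 0.1)
    k_eff = half / fwhm
    mask = s.window(pos - half, pos + half)
    # integrate above the local floor (smooth backgrounds such as the
    # macromolecule hump are not yet subtracted at this stage); the floor
    # balances the median collar level on each side of the window
    floors = []
    for lo, hi in ((pos - 2 * half, pos - 1.2 * half),
                   (pos + 1.2 * half, pos + 2 * half)):
        cm = s.window(lo, hi)
        if cm.any():
            floors.append(float(np.median(s.real[cm])))
    floor = float(np.mean(floors)) if floors else 0.0
    area = float(np.trapezoid(s.real[mask] - floor, s.ppm[mask]))
    if area <= 0:
        raise ValueError(f"non-positive TSP area {area}")
    out = s.evolve("normalize_to_tsp",
                   {"tsp_area": area, "center": pos, "fwhm": fwhm,
                    "integration_fwhm": integration_fwhm},
                   intensity=s.intensity / area)
    out.qc["tsp_area_raw"] = area
    out.qc["tsp_area"] = 1.0
    out.qc["tsp_center"] = pos
    # share of a Lorentzian's area inside +- integration_fwhm half-widths,
    # minus the share removed with the collar floor (the peak's own wing
    # level at ~1.5x the window half-width); used downstream to put the
    # TSP and metabolite windows on equal footing
    gamma = fwhm / 2.0
    d_collar = 1.5 * half
    own_wing = 2 * half * gamma / (np.pi * (d_collar ** 2 + gamma ** 2))
    out.qc["tsp_capture"] = float(
        2.0 / np.pi * np.arctan(2.0 * k_eff) - own_wing)
    return out


def asls_baseline(y: np.ndarray, lam: float = 3e4, p: float = 3e-4,
                  niter: int = 15, czone: float = 1.0,
                  peak_mask: np.ndarray | None = None) -> np.ndarray:
    """Adaptive penalized-smoothing baseline with noise-aware asymmetry.

    Minimizes ``sum w_i (y_i - z_i)^2 + lam * sum (d2 z)^2`` with weights
    reassigned each iteration from the residual ``d = y - z`` relative to
    the noise scale ``sigma`` (root mean square of the negative residuals):
    ``p`` above ``czone * sigma`` (peaks are ignored), ``1 - p`` below
    ``-czone * sigma`` (the baseline never dives under the data), and a
    symmetric ``1/2`` inside the noise band so the estimate runs through
    the middle of the noise rather than its lower envelope, keeping
    integrals unbiased.  ``peak_mask`` marks stretches known to hold
    signals (e.g. panel positions): there the baseline is only pulled from
    below, so broad backgrounds are bridged smoothly under crowded
    multiplet regions.
    """
    n = y.size
    if n < 4:
        return np.zeros_like(y)
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    d2 = np.ones(n - 2)
    w = np.ones(n)
    ab = np.zeros((3, n))
    z = np.zeros_like(y)
    for _ in range(niter):
        ab[0, 2:] = lam * d2
        ab[1, 1:] = lam * d1
        ab[2, :] = w + lam * d0
        z = solveh_banded(ab, w * y, lower=False)
        d = y - z
        neg = d[d < 0]
        sigma = float(np.sqrt((neg ** 2).mean())) if neg.size > 10 else 1e-12
        w = np.where(d > czone * sigma, p,
                     np.where(d < -czone * sigma, 1.0 - p, 0.5))
        if peak_mask is not None:
            # known-signal stretches get only the weak peak-side weight,
            # so the baseline bridges them rather than climbing into them
            w = np.where(peak_mask & (d > -czone * sigma), p, w)
    return z


def adaptive_baseline(
    s: Spectrum, lam: float = 3e4, p: float = 3e-4, niter: int = 15,
    czone: float = 1.0,
    peak_windows=None,
) -> Spectrum:
    """Estimate and subtract a smooth, slowly varying background.

    Tracks broad components (plasma lipid/protein envelope, urinary urea
    band) while leaving narrow metabolite peaks intact.  ``peak_windows``
    is an optional list of ppm intervals known to contain signals (the
    metabolite panel); the baseline bridges them instead of climbing into
    multiplet clusters.  Flat input passes through essentially unchanged.
    """
    mask = None
    if peak_windows:
        mask = np.zeros(s.ppm.size, dtype=bool)
        for lo, hi in peak_windows:
            mask |= s.window(lo, hi)
    z = asls_baseline(s.real.astype(float), lam=lam, p=p, niter=niter,
                      czone=czone, peak_mask=mask)
    return s.evolve("adaptive_baseline",
                    {"lam": lam, "p": p, "niter": niter, "czone": czone,
                     "n_peak_windows": len(peak_windows or [])},
                    intensity=s.real - z)


# --------------------------------------------------------------------------
# pipeline

def preprocess_pipeline(
    s: Spectrum, config: PreprocessConfig | None = None, excise: bool = True
) -> Spectrum:
    """Apply the standard chain (phase -> linear baselines -> referencing ->
    clip -> TSP normalization -> TSP FWHM -> adaptive baseline -> excision).

    Steps whose landmark is already absent (e.g. the TSP signal when the
    chain is re-run on its own excised output) are skipped with a warning
    instead of failing, which makes the chain idempotent in practice.
    ``excise=False`` stops before the final region deletion: quantification
    consumes that pre-excision spectrum (signals inside the deleted water
    or urea regions would otherwise be lost), while the multivariate layer
    uses the fully excised output.
    """
    cfg = config or PreprocessConfig(material=s.material)
    regions = cfg.resolved_regions()

    out = phase_correct_zero_order(s, cfg.tsp_window) if s.is_complex else s
    out = subtract_linear_baselines(out, regions.water)
    try:
        out = reference_axis(out, cfg.resolved_anchor())
    except ValueError as exc:
        warnings.warn(f"referencing skipped: {exc}")
    out = clip(out, regions.clip)
    try:
        out = normalize_to_tsp(out, cfg.tsp_window, cfg.tsp_integration_fwhm)
        out.qc["tsp_fwhm_ppm"] = measure_tsp_fwhm(out, cfg.tsp_window)
    except ValueError as exc:
        warnings.warn(f"TSP normalization skipped: {exc}")
    out = adaptive_baseline(out, cfg.baseline_lam, cfg.baseline_p,
                            cfg.baseline_iter, cfg.baseline_czone,
                            peak_windows=cfg.peak_windows or None)
    if excise:
        out = clip_and_excise(out, regions)
    return out
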