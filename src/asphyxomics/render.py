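"""Forward model: render metabolite concentrations into 1D 1H-NMR spectra.

Each panel signal is a Lorentzian multiplet whose total integrated area is
``k * concentration * protons`` with one global constant ``k`` shared with
the TSP reference (9 protons at the configured concentration), so that
TSP-referenced quantification is exact in the noiseless limit.  On top of
the metabolite signals the renderer adds, per material, the instrumental
and biological nuisances the preprocessing chain is designed to remove:

* a zero-order phase error (complex rotation) and a global ppm
  referencing offset, both recorded in the spectrum metadata,
* a residual water signal near 4.7 ppm,
* plasma: broad lipid bands (CH3 ~0.9, CH2 ~1.3 ppm) and a macromolecule
  hump scaling with the animal's TSP-broadening factor (lipoprotein
  proxy); urine: a broad urea band near 5.8 ppm,
* a global receiver gain factor, a linear baseline tilt, and complex
  white noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import MetabolitePanel
from .spectrum import Spectrum

__all__ = ["AcquisitionParams", "render_spectrum", "render_cohort", "multiplet_lines"]


@dataclass(frozen=True)
class AcquisitionParams:
    ppm_min: float = -1.0
    ppm_max: float = 10.0
    n_points: int = 16384
    #: TSP reference concentration in mM (only ratios matter downstream)
    tsp_conc: float = 0.5
    tsp_protons: int = 9
    #: natural linewidth (FWHM, ppm) of metabolite signals and of the
    #: unbroadened TSP singlet
    linewidth: float = 0.003
    tsp_linewidth: float = 0.003
    #: J-spacings in ppm per multiplicity
    j_doublet: float = 0.012
    j_triplet: float = 0.011
    j_multiplet: float = 0.006
    #: complex white-noise sd (intensity units where area = conc * protons)
    noise_sd: float = 0.2
    #: zero-order phase error sd in degrees
    phase_sd_deg: float = 10.0
    #: global ppm referencing offset sd
    shift_sd: float = 0.005
    #: log-sd of the per-sample global receiver gain
    gain_log_sd: float = 0.3
    #: linear baseline tilt: intensity units per ppm (sd)
    tilt_sd: float = 5.0
    #: residual water signal (presaturated): center, FWHM, area
    water: tuple[float, float, float] = (4.70, 0.08, 10.0)
    #: broad Gaussian backgrounds (center, sigma, area); plasma areas are
    #: additionally scaled by the animal's TSP-broadening factor.  The
    #: lipoprotein CH3/CH2 envelopes are composite bands a few tenths of a
    #: ppm wide; the macromolecule hump spans the whole aliphatic region.
    plasma_background: tuple = ((0.89, 0.08, 20.0), (1.28, 0.08, 30.0),
                                (2.20, 1.00, 60.0))
    urine_background: tuple = ((5.80, 0.15, 50.0),)
    include_backgrounds: bool = True

    def grid(self) -> np.ndarray:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        return np.linspace(self.ppm_min, self.ppm_max, self.n_points)


def multiplet_lines(multiplicity: str, acq: AcquisitionParams):
    """Relative line offsets (ppm) and weights for a multiplicity code."""
    if multiplicity == "s":
        return [(0.0, 1.0)]
    if multiplicity == "d":
        j = acq.j_doublet
        return [(-j / 2, 0.5), (j / 2, 0.5)]
    if multiplicity == "t":
        j = acq.j_triplet
        return [(-j, 0.25), (0.0, 0.5), (j, 0.25)]
    if multiplicity == "m":
        j = acq.j_multiplet
        w = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        w /= w.sum()
        return [((k - 2) * j, wk) for k, wk in enumerate(w)]
    raise ValueError(f"unknown multiplicity {multiplicity!r}")


def _lorentzian_complex(ppm: np.ndarray, center: float, gamma: float,
                        area: float) -> np.ndarray:
    """Complex Lorentzian with absorptive real part of integral ``area``."""
    d = ppm - center
    return (area / np.pi) * (gamma - 1j * d) / (d * d + gamma * gamma)


def _gaussian(ppm: np.ndarray, center: float, sigma: float,
              area: float) -> np.ndarray:
    d = ppm - center
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * (d / sigma) ** 2)


def render_spectrum(
    concentrations,
    panel: MetabolitePanel,
    acq: AcquisitionParams = AcquisitionParams(),
    seed: int | None = 0,
    tsp_broadening: float = 1.0,
    dilution: float = 1.0,
    sample_id: str = "",
    noiseless: bool = False,
    with_water: bool = True,
) -> Spectrum:
    """Render one spectrum from a name -> concentration mapping.

    ``noiseless`` switches off noise, phase error, ppm offset, gain,
    baseline tilt and the broad backgrounds at once (ground-truth
    rendering); the residual water signal is controlled separately by
    ``with_water`` since it is present in any acquisition.  The individual
    nuisances can also be suppressed through ``acq``.
    Raises ``KeyError`` for concentrations of signals absent from the panel.
    """
    for name in concentrations:
        try:
            panel[name]
        except KeyError:
            raise KeyError(
                f"concentration given for {name!r} which is not in the "
                f"{panel.material} panel") from None

    rng = np.random.default_rng(seed)
    phase_deg = 0.0 if noiseless else float(rng.normal(0.0, acq.phase_sd_deg))
    offset = 0.0 if noiseless else float(rng.normal(0.0, acq.shift_sd))
    gain = 1.0 if noiseless else float(np.exp(rng.normal(0.0, acq.gain_log_sd)))
    tilt = 0.0 if noiseless else float(rng.normal(0.0, acq.tilt_sd))

    ppm = acq.grid()
    signal = np.zeros_like(ppm, dtype=complex)

    gamma_met = acq.linewidth / 2.0
    for name, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        spec = panel[name]
        area = conc * dilution * spec.protons
        if area == 0.0:
            continue
        for off, weight in multiplet_lines(spec.multiplicity, acq):
            signal += _lorentzian_complex(
                ppm, spec.ppm + off + offset, gamma_met, area * weight)

    # TSP reference singlet at 0 ppm, broadened per animal
    gamma_tsp = acq.tsp_linewidth * tsp_broadening / 2.0
    tsp_area = acq.tsp_conc * acq.tsp_protons
    signal += _lorentzian_complex(ppm, 0.0 + offset, gamma_tsp, tsp_area)

    background = np.zeros_like(ppm)
    wc, wf, wa = acq.water
    if with_water:
        signal += _lorentzian_complex(ppm, wc + offset, wf / 2.0, wa)
    if not noiseless:
        if acq.include_backgrounds:
            comps = (acq.plasma_background if panel.material == "plasma"
                     else acq.urine_background)
            scale = tsp_broadening if panel.material == "plasma" else 1.0
            for center, sigma, area in comps:
                background += _gaussian(ppm, center + offset, sigma, area * scale)
        background += tilt * (ppm - ppm.mean())

    total = signal + background
    total = total * gain * np.exp(1j * np.deg2rad(phase_deg))
    if not noiseless and acq.noise_sd > 0:
        noise = rng.normal(0.0, acq.noise_sd, size=(2, ppm.size))
        total = total + gain * (noise[0] + 1j * noise[1])

    meta = {
        "true_phase_deg": phase_deg,
        "true_ppm_offset": offset,
        "true_gain": gain,
        "tsp_broadening": tsp_broadening,
        "dilution": dilution,
        "tsp_conc": acq.tsp_conc,
        "true_concentrations": dict(concentrations),
    }
    return Spectrum(ppm=ppm, intensity=total, material=panel.material,
                    sample_id=sample_id, meta=meta)


def render_cohort(
    table,
    panel: MetabolitePanel,
    acq: AcquisitionParams = AcquisitionParams(),
    nuisance=None,
    seed: int = 0,
    noiseless: bool = False,
    with_water: bool = True,
) -> list[Spectrum]:
    """Render every sample of a ground-truth concentration table.

    Per-sample seeds are spawned deterministically from ``seed``.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(table.values.index))
    spectra = []
    for child, (sample_id, row) in zip(seeds, table.values.iterrows()):
        broadening, dilution = 1.0, 1.0
        if nuisance is not None and sample_id in nuisance.index:
            broadening = float(nuisance.loc[sample_id, "tsp_broadening"])
            dilution = float(nuisance.loc[sample_id, "dilution"])
        spectra.append(render_spectrum(
            row.to_dict(), panel, acq,
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
            tsp_broadening=broadening, dilution=dilution,
            sample_id=sample_id, noiseless=noiseless, with_water=with_water))
    return spectra
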