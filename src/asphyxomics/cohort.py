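"""Synthetic study-cohort generator.

Emulates the design of the asphyxia/resuscitation experiment: six
resuscitation-protocol groups of newborn pigs, plasma and urine samples at
baseline (t1) and 2 h / 4 h after return of spontaneous circulation
(t2 / t3), with per-group sample availability, survival, times to asystole
and ROSC, and per-metabolite concentration trajectories.

Concentrations follow a log-normal model: the t1 marginal of each
metabolite is moment-matched to the published median/IQR; later time
points are built multiplicatively within animal,
``c(t+1) = c(t) * ratio(FC) * exp(noise)``, where ``ratio`` converts the
signed fold-change convention (-2 means a factor 1/2) and the log-scale
noise sd defaults to 0.25.  Optional structure: intra-material correlation
clusters (Gaussian copula), correlations of baseline metabolites with the
duration of hypoxia, a per-animal TSP-broadening factor (plasma
lipoprotein proxy) and a per-sample urinary dilution factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .conctable import ConcentrationTable
from .reference import fit_lognormal_from_median_iqr

__all__ = [
    "GroupSpec",
    "StudyDesign",
    "SignalSpec",
    "MetabolitePanel",
    "MetaboliteModel",
    "ConcentrationModel",
    "default_design",
    "simple_design",
    "default_panel",
    "default_concentration_model",
    "sample_cohort",
    "sample_concentrations",
    "signed_fc_to_ratio",
    "ratio_to_signed_fc",
]


# --------------------------------------------------------------------------
# fold-change sign convention

def signed_fc_to_ratio(fc: float) -> float:
    """Signed fold change -> multiplicative ratio (e.g. -2 -> 0.5)."""
    if fc == 0:
        raise ValueError("signed fold change cannot be 0")
    return fc if fc >= 1 else (-1.0 / fc if fc <= -1 else fc)


def ratio_to_signed_fc(ratio: float) -> float:
    """Multiplicative ratio -> signed fold change (e.g. 0.5 -> -2)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1 else -1.0 / ratio


# --------------------------------------------------------------------------
# study design

@dataclass(frozen=True)
class GroupSpec:
    group: int
    n: int
    initial_ventilation_s: float
    fio2: float
    cv_ratio: str
    asystole_median_iqr: tuple[float, float, float]  # median, q1, q3
    rosc_median_iqr: tuple[float, float, float]      # seconds


@dataclass(frozen=True)
class StudyDesign:
    groups: tuple[GroupSpec, ...]
    timepoints: tuple[str, ...] = ("t1", "t2", "t3")
    materials: tuple[str, ...] = ("plasma", "urine")
    #: availability rate in [0, 1] per (group id, material, timepoint)
    availability: dict = field(default_factory=dict)
    #: unit stored for time-to-asystole values; the published table prints
    #: values consistent with minutes for the asphyxiation protocol while
    #: its footnote says seconds, so the unit travels with the data
    asystole_unit: str = "min"
    survival_prob: float = 0.85

    def __post_init__(self) -> None:
        if any(g.n <= 0 for g in self.groups):
            raise ValueError("group sizes must be positive")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly ordered and unique")
        for key, rate in self.availability.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"availability rate out of [0,1] for {key}: {rate}")

    def rate(self, group: int, material: str, timepoint: str) -> float:
        return self.availability.get((group, material, timepoint), 1.0)

    @property
    def n_animals(self) -> int:
        return sum(g.n for g in self.groups)


def default_design(survival_prob: float = 0.85) -> StudyDesign:
    """The six-protocol pooled design with published group sizes and
    per-group sample availability."""
    groups = tuple(
        GroupSpec(g, n, vent, fio2, cv, asys, rosc)
        for g, n, vent, fio2, cv, asys, rosc in reference.RESUSCITATION_GROUPS
    )
    availability = {}
    for g, n, *_ in reference.RESUSCITATION_GROUPS:
        for (material, tp), n_avail in reference.SAMPLE_AVAILABILITY[g].items():
            availability[(g, material, tp)] = min(1.0, n_avail / n)
    return StudyDesign(groups=groups, availability=availability,
                       survival_prob=survival_prob)


def simple_design(
    n: int,
    timepoints: tuple[str, ...] = ("t1", "t2", "t3"),
    materials: tuple[str, ...] = ("plasma",),
    survival_prob: float = 1.0,
) -> StudyDesign:
    """Single-group design with full sample availability (desk-scale runs)."""
    g = GroupSpec(1, n, 30, 0.21, "3:1", (32.5, 27.8, 35.5), (146.0, 125.0, 173.0))
    return StudyDesign(groups=(g,), timepoints=timepoints, materials=materials,
                       survival_prob=survival_prob)


# --------------------------------------------------------------------------
# metabolite panel

@dataclass(frozen=True)
class SignalSpec:
    name: str
    ppm: float
    multiplicity: str  # s | d | t | m
    protons: int
    identified: bool = True


@dataclass(frozen=True)
class MetabolitePanel:
    material: str
    signals: tuple[SignalSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.signals]
        if len(names) != len(set(names)):
            raise ValueError("signal names must be unique within a material")
        for s in self.signals:
            if not -0.5 <= s.ppm <= 9.0:
                raise ValueError(f"{s.name}: ppm {s.ppm} outside [-0.5, 9.0]")
            if s.protons < 1:
                raise ValueError(f"{s.name}: protons must be >= 1")
            if s.multiplicity not in ("s", "d", "t", "m"):
                raise ValueError(f"{s.name}: unknown multiplicity {s.multiplicity!r}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signals]

    def __getitem__(self, name: str) -> SignalSpec:
        for s in self.signals:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset(self, names) -> "MetabolitePanel":
        keep = set(names)
        return MetabolitePanel(self.material,
                               tuple(s for s in self.signals if s.name in keep))


def default_panel(material: str) -> MetabolitePanel:
    signals = tuple(
        SignalSpec(name, ppm, mult, protons, identified)
        for name, ppm, mult, protons, identified, *_ in reference.panel_rows(material)
    )
    return MetabolitePanel(material, signals)


# --------------------------------------------------------------------------
# concentration model

@dataclass(frozen=True)
class MetaboliteModel:
    name: str
    #: per-timepoint log-normal (mu, sigma) moment-matched to median/IQR
    lognormal: dict
    #: signed fold change per transition, e.g. {("t1","t2"): 3.07}
    fold_changes: dict


@dataclass(frozen=True)
class ConcentrationModel:
    material: str
    metabolites: dict
    #: within-animal log-scale noise sd per time-point transition
    noise_sd: float = 0.25
    #: correlation clusters: list of (metabolite names, latent rho)
    clusters: tuple = ()
    #: Pearson r of log t1 concentration with the (log) time to asystole
    endpoint_correlations: dict = field(default_factory=dict)
    #: per-animal TSP broadening factor (plasma lipoprotein proxy):
    #: log-normal median and sigma, trajectory fold changes, and its
    #: correlation with time to asystole
    tsp_broadening_median: float = 1.0
    tsp_broadening_sigma: float = 0.0
    tsp_broadening_fc: dict = field(default_factory=dict)
    tsp_broadening_asystole_r: float = 0.0
    #: per-sample urinary dilution: log-normal sigma (urine only)
    dilution_sigma: float = 0.0

    def __getitem__(self, name: str) -> MetaboliteModel:
        return self.metabolites[name]


def default_concentration_model(
    material: str,
    noise_sd: float = 0.25,
    with_clusters: bool = True,
) -> ConcentrationModel:
    """Model parameterized from the published concentration tables.

    The default correlation structure puts the hypoxia-responsive
    metabolites (lactate, pyruvate, succinate, fumarate, alanine, glucose,
    hypoxanthine) in one intra-material cluster with latent rho 0.5, and
    ties baseline hypoxanthine (r = -0.23) and, for plasma, the TSP
    broadening factor (r = -0.26) to the duration of hypoxia.
    """
    rows = reference.panel_rows(material)
    mets = {}
    for name, _ppm, _mult, _protons, _ident, t1, t2, t3, fc12, fc23 in rows:
        lognormal = {
            tp: fit_lognormal_from_median_iqr(*vals)
            for tp, vals in zip(("t1", "t2", "t3"), (t1, t2, t3))
        }
        mets[name] = MetaboliteModel(
            name=name,
            lognormal=lognormal,
            fold_changes={("t1", "t2"): fc12, ("t2", "t3"): fc23},
        )

    clusters: tuple = ()
    if with_clusters:
        hypoxia = [n for n in ("Lactate", "Pyruvate", "Succinate", "Fumarate",
                               "Alanine", "Glucose", "Hypoxanthine") if n in mets]
        clusters = ((tuple(hypoxia), 0.5),)

    kwargs: dict = dict(
        material=material,
        metabolites=mets,
        noise_sd=noise_sd,
        clusters=clusters,
        endpoint_correlations={
            k: v for k, v in reference.ENDPOINT_CORRELATIONS.items() if k in mets
        },
    )
    if material == "plasma":
        med, q1, q3 = reference.PLASMA_TSP_FWHM["t1"]
        base = 0.003  # natural (unbroadened) TSP FWHM in ppm
        mu, sigma = fit_lognormal_from_median_iqr(med / base, q1 / base, q3 / base)
        kwargs.update(
            tsp_broadening_median=math.exp(mu),
            tsp_broadening_sigma=sigma,
            tsp_broadening_fc={
                ("t1", "t2"): reference.PLASMA_TSP_FWHM["fc_t1_t2"],
                ("t2", "t3"): reference.PLASMA_TSP_FWHM["fc_t2_t3"],
            },
            tsp_broadening_asystole_r=reference.TSP_BROADENING_ASYSTOLE_R,
        )
    else:
        kwargs.update(dilution_sigma=0.5)
    return ConcentrationModel(**kwargs)


# --------------------------------------------------------------------------
# sampling

def _lognormal_from_iqr_triplet(rng, med_iqr, z):
    med, q1, q3 = med_iqr
    mu, sigma = fit_lognormal_from_median_iqr(med, q1, q3)
    return np.exp(mu + sigma * z)


def sample_cohort(design: StudyDesign, seed: int):
    """Draw animals and a sample manifest from a study design.

    Returns ``(animals, manifest)`` data frames.  ``animals`` has one row
    per animal (group, time to asystole, time to ROSC in seconds, survival
    flag, and the latent standard-normal asystole score used for endpoint
    correlations); ``manifest`` has one row per *available* sample with
    ``sample_id = "<animal>_<material>_<timepoint>"``.  Non-survivors have
    no t2/t3 samples.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    animal_rows = []
    manifest_rows = []
    for g in design.groups:
        for i in range(g.n):
            animal_id = f"g{g.group}a{i + 1:03d}"
            z_asys = rng.standard_normal()
            asystole = _lognormal_from_iqr_triplet(rng, g.asystole_median_iqr, z_asys)
            rosc = _lognormal_from_iqr_triplet(
                rng, g.rosc_median_iqr, rng.standard_normal())
            survived = bool(rng.random() < design.survival_prob)
            animal_rows.append({
                "animal_id": animal_id,
                "group": g.group,
                "time_to_asystole": asystole,
                "asystole_unit": design.asystole_unit,
                "time_to_rosc_s": rosc,
                "survived": survived,
                "z_asystole": z_asys,
            })
            for material in design.materials:
                for tp in design.timepoints:
                    if tp != "t1" and not survived:
                        continue
                    if rng.random() >= design.rate(g.group, material, tp):
                        continue
                    manifest_rows.append({
                        "sample_id": f"{animal_id}_{material}_{tp}",
                        "animal_id": animal_id,
                        "group": g.group,
                        "material": material,
                        "timepoint": tp,
                    })
    animals = pd.DataFrame(animal_rows).set_index("animal_id")
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["sample_id", "animal_id", "group", "material", "timepoint"],
    ).set_index("sample_id")
    return animals, manifest


def _transition_chain(timepoints):
    return [(a, b) for a, b in zip(timepoints[:-1], timepoints[1:])]


def sample_concentrations(
    model: ConcentrationModel,
    animals: pd.DataFrame,
    manifest: pd.DataFrame,
    seed: int,
    panel: MetabolitePanel | None = None,
) -> tuple[ConcentrationTable, pd.DataFrame]:
    """Draw ground-truth concentration trajectories for one material.

    Returns the truth ``ConcentrationTable`` (one row per available sample
    of ``model.material``) and a per-sample nuisance frame with the TSP
    broadening and urinary dilution factors consumed by the spectral
    renderer.  t1 values are log-normal draws; t2/t3 follow the
    within-animal multiplicative fold-change construction.
    """
    rng = np.random.default_rng(seed)
    material = model.material
    sub = manifest[manifest["material"] == material]
    timepoints = sorted(sub["timepoint"].unique())
    names = panel.names if panel is not None else list(model.metabolites)
    for name in names:
        if name not in model.metabolites:
            raise KeyError(f"panel metabolite {name!r} has no model parameters")

    # metabolite -> cluster rho
    rho_of = {}
    for members, rho in model.clusters:
        for m in members:
            rho_of[m] = rho

    animal_ids = list(animals.index)
    n_animals = len(animal_ids)
    z_asys = animals["z_asystole"].to_numpy()
    n_clusters = len(model.clusters)
    z_cluster = rng.standard_normal((n_clusters, n_animals))
    cluster_idx = {members: k for k, (members, _rho) in enumerate(model.clusters)}

    # latent standard-normal scores at the first sampled time point
    # (its own marginal parameters), one per metabolite x animal
    tp0 = timepoints[0]
    conc = {}  # (timepoint) -> {name: array over animals}
    first_vals = {}
    for j, name in enumerate(names):
        mm = model.metabolites[name]
        if tp0 not in mm.lognormal:
            raise KeyError(f"metabolite {name!r} has no marginal for {tp0}")
        r_e = model.endpoint_correlations.get(name, 0.0)
        eps = rng.standard_normal(n_animals)
        base = eps
        for members, rho in model.clusters:
            if name in members:
                k = cluster_idx[members]
                base = math.sqrt(rho) * z_cluster[k] + math.sqrt(1 - rho) * eps
                break
        z = r_e * z_asys + math.sqrt(1 - r_e ** 2) * base
        mu, sigma = mm.lognormal[tp0]
        first_vals[name] = np.exp(mu + sigma * z)
    conc[tp0] = first_vals

    for (a, b) in _transition_chain(timepoints):
        step = {}
        for name in names:
            mm = model.metabolites[name]
            if (a, b) not in mm.fold_changes:
                raise KeyError(
                    f"metabolite {name!r} has no fold change for transition {a}->{b}")
            ratio = signed_fc_to_ratio(mm.fold_changes[(a, b)])
            noise = np.exp(model.noise_sd * rng.standard_normal(n_animals))
            step[name] = conc[a][name] * ratio * noise
        conc[b] = step

    # TSP broadening factor trajectory per animal
    r_b = model.tsp_broadening_asystole_r
    eps_b = rng.standard_normal(n_animals)
    z_b = r_b * z_asys + math.sqrt(1 - r_b ** 2) * eps_b
    broaden = {tp0: model.tsp_broadening_median
               * np.exp(model.tsp_broadening_sigma * z_b)}
    for (a, b) in _transition_chain(timepoints):
        fc = model.tsp_broadening_fc.get((a, b), 1.0)
        broaden[b] = broaden[a] * signed_fc_to_ratio(fc) \
            * np.exp(0.1 * rng.standard_normal(n_animals)
                     if model.tsp_broadening_sigma > 0 else 0.0)

    pos = {aid: i for i, aid in enumerate(animal_ids)}
    rows, nuis_rows = [], []
    for sample_id, rec in sub.iterrows():
        i = pos[rec["animal_id"]]
        tp = rec["timepoint"]
        rows.append({"sample_id": sample_id,
                     **{name: conc[tp][name][i] for name in names}})
        nuis_rows.append({
            "sample_id": sample_id,
            "tsp_broadening": float(broaden[tp][i]),
            "dilution": float(np.exp(model.dilution_sigma * rng.standard_normal()))
            if model.dilution_sigma > 0 else 1.0,
        })
    values = pd.DataFrame(rows).set_index("sample_id")
    nuisance = pd.DataFrame(nuis_rows).set_index("sample_id")

    units = {}
    if panel is not None:
        units = {s.name: ("mM" if s.identified else "a.u.") for s in panel.signals}
    else:
        for name, *_rest in reference.panel_rows(material):
            identified = _rest[3]
            if name in names:
                units[name] = "mM" if identified else "a.u."
    meta = sub.join(animals.drop(columns=["z_asystole", "group"]),
                    on="animal_id")
    table = ConcentrationTable(values=values, units=units, meta=meta)
    return table, nuisance
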