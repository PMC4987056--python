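"""End-to-end orchestration: simulate -> preprocess -> quantify ->
chemometrics -> unistats -> correlate, with a provenance manifest.

Every stage writes its outputs under ``out_dir/<stage>/`` and records, in
``out_dir/manifest.json``, the SHA-256 hashes of its input files, a hash
of the configuration parameters it depends on, its seed and the package
version.  A stage is skipped on re-run when its outputs exist and the
recorded hashes match, so deleting an intermediate file triggers only
downstream recomputation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import (backscale_loadings, cross_validate, dummy_code,
                           nmc_permutation_null, pca, pls_fit, select_ncomp,
                           uv_scale)
from .cohort import (default_concentration_model, default_design,
                     default_panel, sample_cohort, sample_concentrations,
                     simple_design)
from .conctable import ConcentrationTable
from .corrstruct import (all_pairs_pearson, cluster_order, combine_materials,
                         threshold_mask, to_newick)
from .formats import read_spectrum, write_spectrum
from .preprocess import PreprocessConfig, preprocess_pipeline
from .quantify import quantify_cohort
from .render import AcquisitionParams, render_cohort
from .unistats import (endpoint_correlation, group_anova, log_transform,
                       paired_fold_change, survival_comparison)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]

STAGES = ("simulate", "preprocess", "quantify", "chemometrics", "unistats",
          "correlate")


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 0
    #: "full" reproduces the pooled six-group design; "simple" is a single
    #: group of ``n_animals`` with full availability
    design: str = "full"
    n_animals: int = 20
    materials: tuple[str, ...] = ("plasma", "urine")
    timepoints: tuple[str, ...] = ("t1", "t2", "t3")
    survival_prob: float = 0.85
    noise_sd_log: float = 0.25
    #: overrides for AcquisitionParams fields
    acquisition: dict = field(default_factory=dict)
    #: PLS-DA contrast and CV settings
    contrast: tuple[str, str] = ("t1", "t2")
    folds: int = 7
    ncomp: int = 0  # 0 = select by maximal Q2
    reps: int = 100
    nperm: int = 100
    corr_cutoff: float = 0.5

    def acq(self) -> AcquisitionParams:
        return AcquisitionParams(**self.acquisition)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["materials"] = list(self.materials)
        d["timepoints"] = list(self.timepoints)
        d["contrast"] = list(self.contrast)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("materials", "timepoints", "contrast"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# manifest helpers

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {}
        if path.exists():
            self.data = json.loads(path.read_text())

    def up_to_date(self, stage: str, inputs: list[Path], params: dict,
                   outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        if rec is None:
            return False
        if not all(p.exists() for p in outputs):
            return False
        if rec.get("params_hash") != _params_hash(params):
            return False
        recorded = rec.get("inputs", {})
        for p in inputs:
            if not p.exists() or recorded.get(str(p)) != _sha256(p):
                return False
        return True

    def record(self, stage: str, inputs: list[Path], params: dict,
               outputs: list[Path], seed: int) -> None:
        self.data[stage] = {
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": sorted(str(p) for p in outputs),
            "params_hash": _params_hash(params),
            "seed": seed,
            "version": __version__,
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


# --------------------------------------------------------------------------
# stages

def _stage_seed(config: PipelineConfig, stage: str) -> int:
    ss = np.random.SeedSequence([config.seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _spectra_dir(out: Path, kind: str, material: str) -> Path:
    d = out / kind / material
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order; returns a stage -> outputs map.

    A stage failure raises with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    manifest = _Manifest(out / "manifest.json")
    results: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        func = globals()[f"_run_{stage}"]
        try:
            results[stage] = func(config, out, manifest)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def _run_simulate(config: PipelineConfig, out: Path, manifest: _Manifest):
    seed = _stage_seed(config, "simulate")
    params = {**config.to_dict(), "stage": "simulate"}
    sim = out / "simulate"
    animals_csv = sim / "animals.csv"
    manifest_csv = sim / "samples.csv"
    outputs = [animals_csv, manifest_csv]
    if manifest.up_to_date("simulate", [], params, outputs):
        return outputs
    sim.mkdir(parents=True, exist_ok=True)
    if config.design == "full":
        design = default_design(config.survival_prob)
        design = dataclasses.replace(design, materials=config.materials,
                                     timepoints=config.timepoints)
    else:
        design = simple_design(config.n_animals, config.timepoints,
                               config.materials, config.survival_prob)
    animals, samples = sample_cohort(design, seed)
    animals.to_csv(animals_csv)
    samples.to_csv(manifest_csv)
    acq = config.acq()
    for k, material in enumerate(config.materials):
        model = default_concentration_model(material,
                                            noise_sd=config.noise_sd_log)
        panel = default_panel(material)
        truth, nuisance = sample_concentrations(model, animals, samples,
                                                seed + 1 + k, panel)
        truth.to_csv(sim / f"truth_{material}.csv")
        nuisance.to_csv(sim / f"nuisance_{material}.csv")
        spectra = render_cohort(truth, panel, acq, nuisance, seed + 11 + k)
        d = _spectra_dir(out, "spectra_raw", material)
        for s in spectra:
            write_spectrum(s, d / f"{s.sample_id}.txt", dialect="tabular")
            outputs.append(d / f"{s.sample_id}.txt")
        outputs += [sim / f"truth_{material}.csv", sim / f"nuisance_{material}.csv"]
    manifest.record("simulate", [], params, outputs, seed)
    return outputs


def _run_preprocess(config: PipelineConfig, out: Path, manifest: _Manifest):
    params = {"stage": "preprocess", "acquisition": config.acquisition}
    inputs = sorted((out / "spectra_raw").rglob("*.txt"))
    qc_csv = out / "preprocess" / "qc.csv"
    proc_root = out / "spectra_processed"
    outputs = [qc_csv] + [
        proc_root / p.parent.name / p.name for p in inputs]
    if manifest.up_to_date("preprocess", inputs, params, outputs):
        return outputs
    (out / "preprocess").mkdir(parents=True, exist_ok=True)
    from .quantify import peak_mask_windows
    acq = config.acq()
    masks = {m: peak_mask_windows(default_panel(m), acq)
             for m in config.materials}
    qc_rows = []
    for p in inputs:
        s = read_spectrum(p)
        proc = preprocess_pipeline(
            s, PreprocessConfig(material=s.material,
                                peak_windows=masks.get(s.material, ())),
            excise=False)
        d = _spectra_dir(out, "spectra_processed", s.material)
        write_spectrum(proc, d / p.name, dialect="tabular")
        qc_rows.append({"sample_id": proc.sample_id,
                        "material": proc.material, **proc.qc})
    pd.DataFrame(qc_rows).set_index("sample_id").to_csv(qc_csv)
    manifest.record("preprocess", inputs, params, outputs,
                    _stage_seed(config, "preprocess"))
    return outputs


def _run_quantify(config: PipelineConfig, out: Path, manifest: _Manifest):
    params = {"stage": "quantify", "acquisition": config.acquisition}
    inputs = sorted((out / "spectra_processed").rglob("*.txt"))
    qdir = out / "quantify"
    outputs = [qdir / f"concentrations_{m}.csv" for m in config.materials]
    if manifest.up_to_date("quantify", inputs, params, outputs):
        return outputs
    qdir.mkdir(parents=True, exist_ok=True)
    acq = config.acq()
    samples = pd.read_csv(out / "simulate" / "samples.csv",
                          index_col="sample_id")
    for material in config.materials:
        spectra = [read_spectrum(p) for p in inputs
                   if p.parent.name == material]
        panel = default_panel(material)
        table = quantify_cohort(spectra, panel, acq.tsp_conc, acq,
                                meta=samples)
        table.to_csv(qdir / f"concentrations_{material}.csv")
    manifest.record("quantify", inputs, params, outputs,
                    _stage_seed(config, "quantify"))
    return outputs


def _load_material(out: Path, material: str) -> ConcentrationTable:
    return ConcentrationTable.read_csv(
        out / "quantify" / f"concentrations_{material}.csv")


def _run_chemometrics(config: PipelineConfig, out: Path, manifest: _Manifest):
    from .plots import plot_backscaled_loadings, plot_scores

    seed = _stage_seed(config, "chemometrics")
    params = {"stage": "chemometrics", "contrast": list(config.contrast),
              "folds": config.folds, "ncomp": config.ncomp,
              "reps": config.reps, "nperm": config.nperm}
    inputs = sorted((out / "quantify").glob("concentrations_*.csv"))
    cdir = out / "chemometrics"
    outputs = [cdir / f"plsda_{m}.json" for m in config.materials]
    if manifest.up_to_date("chemometrics", inputs, params, outputs):
        return outputs
    cdir.mkdir(parents=True, exist_ok=True)
    a, b = config.contrast
    for material in config.materials:
        table = _load_material(out, material)
        meta = table.meta
        sel = meta["timepoint"].isin([a, b])
        logc, _ = log_transform(table.values.loc[sel.index[sel]])
        labels = meta.loc[logc.index, "timepoint"].to_numpy()
        if len(set(labels.tolist())) < 2:
            continue
        X = logc.to_numpy()
        Y, _classes = dummy_code(labels)
        ncomp = config.ncomp
        cv = cross_validate(X, Y, folds=config.folds,
                            ncomp=max(ncomp, 2) if ncomp else 3,
                            order=np.random.default_rng(seed).permutation(len(X)),
                            labels=labels)
        if not ncomp:
            ncomp = select_ncomp(cv.q2)
        scaled = uv_scale(X)
        model = pls_fit(scaled.X, Y, ncomp=ncomp)
        res = nmc_permutation_null(X, labels, folds=config.folds, ncomp=ncomp,
                                   reps=config.reps, nperm=config.nperm,
                                   seed=seed)
        summary = {
            "material": material, "contrast": [a, b], "ncomp": ncomp,
            "r2": float(model.r2[ncomp - 1]), "q2": float(cv.q2[ncomp - 1]),
            "nmc_median": res.median, "nmc_ci": list(res.ci),
            "null_median": res.null_median, "null_ci": list(res.null_ci),
            "p_empirical": res.p_empirical, "p_ranksum": res.p_ranksum,
        }
        (cdir / f"plsda_{material}.json").write_text(
            json.dumps(summary, indent=2))
        bl = backscale_loadings(model, scaled.sds, X, Y[:, 0],
                                columns=list(logc.columns))
        bl.frame().to_csv(cdir / f"loadings_{material}.csv")
        plot_backscaled_loadings(bl, cdir / f"loadings_{material}.svg")
        pc = pca(scaled, k=min(2, len(X) - 1))
        plot_scores(pc, meta.loc[logc.index, "timepoint"],
                    cdir / f"pca_scores_{material}.svg",
                    title=f"PCA scores ({material})")
    manifest.record("chemometrics", inputs, params, outputs, seed)
    return outputs


def _run_unistats(config: PipelineConfig, out: Path, manifest: _Manifest):
    params = {"stage": "unistats", "timepoints": list(config.timepoints)}
    inputs = sorted((out / "quantify").glob("concentrations_*.csv"))
    udir = out / "unistats"
    outputs = [udir / f"fold_changes_{m}.csv" for m in config.materials]
    if manifest.up_to_date("unistats", inputs, params, outputs):
        return outputs
    udir.mkdir(parents=True, exist_ok=True)
    animals = pd.read_csv(out / "simulate" / "animals.csv",
                          index_col="animal_id")
    for material in config.materials:
        table = _load_material(out, material)
        meta = table.meta
        logc, _ = log_transform(table.values)
        frames = []
        tps = list(config.timepoints)
        for a, b in zip(tps[:-1], tps[1:]):
            ia = meta.index[meta["timepoint"] == a]
            ib = meta.index[meta["timepoint"] == b]
            if len(ia) == 0 or len(ib) == 0:
                continue
            fc = paired_fold_change(logc.loc[ia], logc.loc[ib],
                                    meta.loc[ia, "animal_id"],
                                    meta.loc[ib, "animal_id"])
            fc.insert(0, "transition", f"{a}->{b}")
            frames.append(fc)
        if frames:
            pd.concat(frames).to_csv(udir / f"fold_changes_{material}.csv",
                                     index_label="metabolite")
        # ANOVA across groups and endpoint correlations at baseline
        i1 = meta.index[meta["timepoint"] == tps[0]]
        base = logc.loc[i1]
        groups = meta.loc[i1, "group"]
        if groups.nunique() >= 2:
            group_anova(base, groups).to_csv(udir / f"anova_{material}.csv")
        ann = meta.loc[i1]
        corr_vars = base.copy()
        if "tsp_fwhm_ppm" in ann.columns:
            corr_vars["tsp_fwhm_ppm"] = ann["tsp_fwhm_ppm"]
        endpoint = animals.loc[ann["animal_id"], "time_to_asystole"].to_numpy()
        if len(corr_vars) >= 5:
            endpoint_correlation(corr_vars, np.log(endpoint)).to_csv(
                udir / f"asystole_correlation_{material}.csv")
        surv = animals.loc[ann["animal_id"], "survived"].to_numpy()
        sc = survival_comparison(base, surv)
        if len(sc):
            sc.to_csv(udir / f"survival_{material}.csv")
    manifest.record("unistats", inputs, params, outputs,
                    _stage_seed(config, "unistats"))
    return outputs


def _run_correlate(config: PipelineConfig, out: Path, manifest: _Manifest):
    from .plots import plot_correlation_heatmap
    from .quantify import creatinine_normalize

    params = {"stage": "correlate", "cutoff": config.corr_cutoff}
    inputs = sorted((out / "quantify").glob("concentrations_*.csv"))
    rdir = out / "correlate"
    outputs = [rdir / "correlation_matrix.csv"]
    if manifest.up_to_date("correlate", inputs, params, outputs):
        return outputs
    rdir.mkdir(parents=True, exist_ok=True)
    frames, materials = [], {}
    if "plasma" in config.materials and "urine" in config.materials:
        pt = _load_material(out, "plasma")
        ut = _load_material(out, "urine")
        if "Creatinine" in ut.values.columns:
            ut = creatinine_normalize(ut)
        pl, _ = log_transform(pt.values)
        ul, _ = log_transform(ut.values)
        pl.index = pt.meta.loc[pl.index, "animal_id"].astype(str) + "_" + \
            pt.meta.loc[pl.index, "timepoint"].astype(str)
        ul.index = ut.meta.loc[ul.index, "animal_id"].astype(str) + "_" + \
            ut.meta.loc[ul.index, "timepoint"].astype(str)
        joined, materials = combine_materials(pl, ul)
    else:
        material = config.materials[0]
        t = _load_material(out, material)
        joined, _ = log_transform(t.values)
        materials = {c: material for c in joined.columns}
    m = all_pairs_pearson(joined, materials)
    m = cluster_order(m, scope="all")
    m = threshold_mask(m, cutoff=config.corr_cutoff)
    m.ordered().to_csv(rdir / "correlation_matrix.csv")
    if m.linkage is not None:
        (rdir / "dendrogram.nwk").write_text(
            to_newick(m.linkage, list(m.r.columns)))
    plot_correlation_heatmap(m, rdir / "correlation_heatmap.svg")
    manifest.record("correlate", inputs, params, outputs,
                    _stage_seed(config, "correlate"))
    return outputs
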