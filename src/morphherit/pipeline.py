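"""Config-driven orchestration: TPS + pedigree in, heritability report out.

Runs the full analysis sequence — read landmarks and pedigree, GPA with
semilandmark sliding, object-symmetry averaging, PCA, optional
sexual-dimorphism permutation tests, animal-model REML, multivariate
heritability summaries — materializing every stage's output in the run
directory together with a manifest (config echo, seeds, package version,
file checksums) sufficient to re-run the analysis bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .animal_model import AnimalModel
from .morphometry import gpa, procrustes_anova, shape_pca, symmetric_component
from .pedigree import read_pedigree
from .scheme import LandmarkScheme, viper_head_scheme
from .tps import read_tps

__all__ = ["PipelineConfig", "PipelineStageError", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_NOT_CONVERGED = 3


class PipelineStageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run (see ``from_yaml``)."""

    tps: str
    pedigree: str
    output_dir: str
    scheme: str = "viper_head"  # builtin name or path to a scheme YAML
    n_pcs: int = 15
    slide: bool = True
    project: bool = True
    dimorphism: bool = True
    n_permutations: int = 1000
    seed: int = 0
    pinv_rtol: float = 1e-10
    reml: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def load_scheme(self) -> LandmarkScheme:
        if self.scheme == "viper_head":
            return viper_head_scheme()
        return LandmarkScheme.from_yaml(self.scheme)


@dataclass
class PipelineResult:
    """Outcome of a run: report dict, artifact paths, exit code."""

    report: dict
    paths: dict
    converged: bool

    @property
    def exit_code(self) -> int:
        return EXIT_OK if self.converged else EXIT_NOT_CONVERGED


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Raises :class:`PipelineStageError` on stage failure; a non-converged
    REML fit still writes the full report but is reflected in
    ``PipelineResult.converged`` (CLI exit code 3).
    """
    os.makedirs(config.output_dir, exist_ok=True)
    out = lambda name: os.path.join(config.output_dir, name)  # noqa: E731
    paths: dict[str, str] = {}

    @_stage("read")
    def stage_read():
        scheme = config.load_scheme()
        configs = read_tps(config.tps, scheme=scheme)
        ped = read_pedigree(config.pedigree)
        meta = pd.read_csv(config.pedigree, sep=None, engine="python", dtype=str)
        meta.columns = [c.lower().strip() for c in meta.columns]
        return scheme, configs, ped, meta

    scheme, configs, ped, meta = stage_read()

    @_stage("gpa")
    def stage_gpa():
        aligned = gpa(configs, scheme=scheme, slide=config.slide,
                      project=config.project)
        df = aligned.to_dataframe()
        df.to_csv(out("aligned.csv"), index=False)
        paths["aligned"] = out("aligned.csv")
        return aligned

    aligned = stage_gpa()

    @_stage("symmetry")
    def stage_sym():
        symm = symmetric_component(aligned, scheme, project=config.project)
        df = symm.to_dataframe()
        df.to_csv(out("symmetric.csv"), index=False)
        paths["symmetric"] = out("symmetric.csv")
        return symm

    symm = stage_sym()

    @_stage("pca")
    def stage_pca():
        space = shape_pca(symm, n_retained=config.n_pcs)
        space.to_dataframe().to_csv(out("pca_eigenvalues.csv"), index=False)
        scores = pd.DataFrame(
            space.scores,
            columns=[f"PC{i + 1}" for i in range(space.n_retained)],
        )
        scores.insert(0, "specimen_id", symm.specimen_ids)
        scores["log_cs"] = np.log(symm.centroid_sizes)
        scores.to_csv(out("scores.csv"), index=False)
        paths["pca_eigenvalues"] = out("pca_eigenvalues.csv")
        paths["scores"] = out("scores.csv")
        return space

    space = stage_pca()

    sex_of = {}
    if "sex" in meta.columns and "id" in meta.columns:
        sex_of = {
            str(r["id"]).strip(): str(r["sex"]).strip()
            for _, r in meta.iterrows()
            if str(r.get("sex", "")).strip() not in ("", "nan")
        }

    dimorphism: dict[str, dict] = {}
    if config.dimorphism and sex_of:

        @_stage("dimorphism")
        def stage_dim():
            res: dict[str, dict] = {}
            ids = symm.specimen_ids
            founders = ped.founders
            groups = {"adults": [i for i in ids if i in founders],
                      "offspring": [i for i in ids if i not in founders]}
            log_cs = np.log(symm.centroid_sizes)
            pos = {i: k for k, i in enumerate(ids)}
            for gname, members in groups.items():
                idx = [pos[i] for i in members if sex_of.get(i) in ("M", "F")]
                if len(idx) < 4:
                    continue
                labels = [sex_of[ids[k]] for k in idx]
                if len(set(labels)) < 2 or min(
                    labels.count(l) for l in set(labels)
                ) < 2:
                    continue
                shape_test = procrustes_anova(
                    space.scores[idx], labels,
                    n_perm=config.n_permutations, seed=config.seed,
                )
                size_test = procrustes_anova(
                    log_cs[idx], labels,
                    n_perm=config.n_permutations, seed=config.seed,
                )
                res[gname] = {
                    "shape": asdict(shape_test),
                    "log_cs": asdict(size_test),
                    "n": len(idx),
                }
            return res

        dimorphism = stage_dim()

    @_stage("reml")
    def stage_reml():
        ids = symm.specimen_ids
        dam, sire = [], []
        for i in ids:
            k = ped.index[i]
            dam.append(ped.ids[ped.dam_idx[k]] if ped.dam_idx[k] >= 0 else None)
            sire.append(ped.ids[ped.sire_idx[k]] if ped.sire_idx[k] >= 0 else None)
        model = AnimalModel(
            traits=space.scores,
            individual_ids=ids,
            pedigree=ped,
            covariate=np.log(symm.centroid_sizes),
            dam_ids=dam,
            sire_ids=sire,
        )
        results = model.fit(**config.reml)
        results.save_components(config.output_dir)
        for label in ("G", "Mat", "Pat", "R", "P"):
            paths[label] = out(f"{label}.csv")
        with open(out("fit_log.txt"), "w") as fh:
            fh.write(f"method: {results.method}\n")
            fh.write(f"iterations: {results.n_iter}\n")
            fh.write(f"converged: {results.converged}\n")
            fh.write("restricted logL trajectory:\n")
            for i, l in enumerate(results.logl_path):
                fh.write(f"  {i}: {l:.10f}\n")
        paths["fit_log"] = out("fit_log.txt")
        return results

    results = stage_reml()

    @_stage("heritability")
    def stage_herit():
        summary = results.heritability(pinv_rtol=config.pinv_rtol)
        # landmark displacement fields of the leading G / Mat eigenvectors
        for label, eig in (("G", summary.component_eigen["G"]),
                           ("Mat", summary.component_eigen["Mat"])):
            disp = space.back_project(eig.eigenvectors[:, 0])
            k = len(disp) // 2
            df = pd.DataFrame(disp.reshape(k, 2), columns=["dx", "dy"])
            df.insert(0, "landmark", np.arange(1, k + 1))
            df.to_csv(out(f"displacement_{label}1.csv"), index=False)
            paths[f"displacement_{label}1"] = out(f"displacement_{label}1.csv")
        return summary

    summary = stage_herit()

    report = {
        "n_specimens": symm.n_specimens,
        "n_landmarks": symm.n_landmarks,
        "n_pcs": space.n_retained,
        "pca_rank": space.rank,
        "cumulative_variance_retained": float(
            space.cumulative_variance[space.n_retained - 1]
        ),
        "dimorphism": dimorphism,
        "reml": {
            "converged": results.converged,
            "n_iter": results.n_iter,
            "loglike": results.loglike,
            "method": results.method,
        },
        "heritability": summary.to_dict(),
    }
    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    paths["report"] = out("report.json")

    manifest = {
        "package_version": _version,
        "config": asdict(config),
        "seed": config.seed,
        "checksums": {k: _sha256(v) for k, v in sorted(paths.items())},
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = out("manifest.json")

    return PipelineResult(report=report, paths=paths, converged=results.converged)
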