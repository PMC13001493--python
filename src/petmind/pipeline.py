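"""End-to-end runner: simulate-or-load -> MC -> MIND -> coupling -> nulls -> GLM.

One :class:`PipelineConfig` (loadable from YAML) drives the whole run.
Every stochastic stage derives its seed from the config seed via a named
:class:`numpy.random.SeedSequence` spawn, so any single stage can be
re-run from the manifest bit-identically. The manifest records a SHA-256
hash of every artifact, the configuration echo, derived seeds, and the
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coupling import (couple_matrices, fit_distance_decay, group_mean_matrix,
                       summarize_cohort)
from .errors import ConfigurationError
from .inference import bootstrap_ci, fit_glm, regional_age_effects
from .io import (read_cohort, read_geometry, read_tacs, read_vertex_features,
                 write_cohort, write_geometry, write_matrix, write_tacs,
                 write_truth, write_vertex_features)
from .mc import compute_mc, nodal_strength
from .mind import MINDConfig, compute_mind, standardize_features
from .nulls import spin_test, subject_mismatch_test
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

_STAGE_NAMES = ("simulate", "spin", "mismatch", "bootstrap")


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``simulate`` holds a :class:`SyntheticConfig` (synthetic run)
    or the four input paths must point at existing files (real-data run).
    """

    out_dir: str = "petmind_out"
    seed: int = 0
    simulate: SyntheticConfig | None = None
    cohort_path: str | None = None
    tac_dir: str | None = None
    feature_dir: str | None = None
    geometry_path: str | None = None
    mind: MINDConfig = field(default_factory=MINDConfig)
    dist_correct: bool = True
    run_spins: bool = True
    run_mismatch: bool = True
    n_spins: int = 1000
    n_perm: int = 1000
    n_boot: int = 1000
    fdr_q: float = 0.05

    def validate(self) -> "PipelineConfig":
        for name in ("n_spins", "n_perm", "n_boot"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ConfigurationError("fdr_q must lie in (0, 1)")
        if self.simulate is None:
            missing = [n for n in ("cohort_path", "tac_dir", "feature_dir", "geometry_path")
                       if getattr(self, n) is None]
            if missing:
                raise ConfigurationError(
                    f"without a simulate block, input paths are required; missing {missing}"
                )
        self.mind.validate()
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        mind = raw.pop("mind", None)
        cfg = cls(**raw)
        if sim is not None:
            sim = dict(sim)
            for key in ("n_vertices_per_region", "age_range", "distance_decay"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "frame_schedule" in sim:
                sim["frame_schedule"] = tuple(tuple(e) for e in sim["frame_schedule"])
            cfg.simulate = SyntheticConfig(**sim)
        if mind is not None:
            cfg.mind = MINDConfig(**mind)
        return cfg.validate()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(_STAGE_NAMES, children)}


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; return (and write) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"version": __version__, "seed": config.seed, "stage_seeds": seeds,
                      "config": _config_echo(config), "stages": {}, "files": {}}
    manifest_path = out / "manifest.json"

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        # ---- inputs -------------------------------------------------------
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=seeds["simulate"])
            logger.info("simulating cohort: %d subjects, %d regions",
                        sim.n_subjects, sim.n_regions)
            cohort, tacs, features, geom, truth = generate_cohort(sim)
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            write_cohort(cohort, inputs / "cohort.tsv")
            record("cohort", inputs / "cohort.tsv")
            write_geometry(geom, inputs / "geometry.tsv")
            record("geometry", inputs / "geometry.tsv")
            write_truth(truth, inputs / "truth.json")
            record("truth", inputs / "truth.json")
            for sid in cohort["subject_id"]:
                write_tacs(tacs[sid], inputs / f"{sid}_tacs.tsv")
                record(f"tacs/{sid}", inputs / f"{sid}_tacs.tsv")
                write_vertex_features(features[sid], inputs / f"{sid}_features.tsv")
                record(f"features/{sid}", inputs / f"{sid}_features.tsv")
        else:
            cohort = read_cohort(config.cohort_path)
            geom = read_geometry(config.geometry_path)
            tacs = {sid: read_tacs(Path(config.tac_dir) / f"{sid}_tacs.tsv", sid)
                    for sid in cohort["subject_id"]}
            features = {sid: read_vertex_features(
                Path(config.feature_dir) / f"{sid}_features.tsv", sid,
                region_order=list(geom.region_ids)) for sid in cohort["subject_id"]}
        manifest["stages"]["inputs"] = "ok"

        # ---- similarity matrices -----------------------------------------
        mat_dir = out / "matrices"
        mat_dir.mkdir(exist_ok=True)
        mc_by_subject, mind_by_subject = {}, {}
        for sid in cohort["subject_id"]:
            mc_m = compute_mc(tacs[sid])
            mind_m = compute_mind(standardize_features(features[sid]), config.mind)
            mc_by_subject[sid], mind_by_subject[sid] = mc_m, mind_m
            write_matrix(mc_m, mat_dir / f"{sid}_mc.tsv", sid)
            record(f"mc/{sid}", mat_dir / f"{sid}_mc.tsv")
            write_matrix(mind_m, mat_dir / f"{sid}_mind.tsv", sid)
            record(f"mind/{sid}", mat_dir / f"{sid}_mind.tsv")
        manifest["stages"]["matrices"] = "ok"

        # ---- coupling -----------------------------------------------------
        coup_dir = out / "coupling"
        coup_dir.mkdir(exist_ok=True)
        subject_ids = list(cohort["subject_id"])
        results = [couple_matrices(mc_by_subject[s], mind_by_subject[s], geom,
                                   dist_correct=config.dist_correct, subject_id=s)
                   for s in subject_ids]
        group_mc = group_mean_matrix([mc_by_subject[s] for s in subject_ids])
        group_mind = group_mean_matrix([mind_by_subject[s] for s in subject_ids])
        group_result = couple_matrices(group_mc, group_mind, geom,
                                       dist_correct=config.dist_correct)
        decay_mc = fit_distance_decay(group_mc, geom)
        decay_mind = fit_distance_decay(group_mind, geom)
        summary = summarize_cohort(results, geom)

        per_subject = pd.DataFrame({
            "subject_id": subject_ids,
            "global_rho": [r.global_rho for r in results],
            "global_p": [r.global_p for r in results],
            "global_rho_distcorr": [r.global_rho_distcorr for r in results],
            "strength_r": [r.strength_r for r in results],
        })
        per_subject.to_csv(coup_dir / "per_subject.tsv", sep="\t", index=False)
        record("coupling/per_subject", coup_dir / "per_subject.tsv")
        local = pd.DataFrame(np.vstack([r.local_rho for r in results]),
                             index=subject_ids, columns=group_mc.region_ids)
        local.to_csv(coup_dir / "local_rho.tsv", sep="\t", index_label="subject_id")
        record("coupling/local_rho", coup_dir / "local_rho.tsv")
        summary_df = pd.DataFrame({"region_id": summary.region_ids,
                                   "mean_local_rho": summary.mean_local_rho,
                                   "mad_local_rho": summary.mad_local_rho})
        summary_df.to_csv(coup_dir / "summary.tsv", sep="\t", index=False)
        record("coupling/summary", coup_dir / "summary.tsv")
        global_payload = {
            "group": {"global_rho": group_result.global_rho,
                      "global_p": group_result.global_p,
                      "global_rho_distcorr": group_result.global_rho_distcorr,
                      "strength_r": group_result.strength_r,
                      "strength_p": group_result.strength_p},
            "subject_mean": {"global_rho": float(per_subject["global_rho"].mean()),
                             "global_rho_sd": float(per_subject["global_rho"].std(ddof=1)),
                             "strength_r": float(per_subject["strength_r"].mean())},
            "decay_fit": {"mc": {"a": decay_mc.a, "b": decay_mc.b, "c": decay_mc.c,
                                 "converged": decay_mc.converged},
                          "mind": {"a": decay_mind.a, "b": decay_mind.b, "c": decay_mind.c,
                                   "converged": decay_mind.converged}},
            "class_means": summary.class_means,
        }
        (coup_dir / "global.json").write_text(json.dumps(global_payload, indent=1))
        record("coupling/global", coup_dir / "global.json")
        manifest["stages"]["coupling"] = "ok"

        # ---- nulls --------------------------------------------------------
        nulls_dir = out / "nulls"
        nulls_dir.mkdir(exist_ok=True)
        if config.run_spins:
            spin = spin_test(nodal_strength(group_mc), nodal_strength(group_mind), geom,
                             n_spins=config.n_spins, seed=seeds["spin"])
            payload = {"observed_r": spin.observed_stat, "p_value": spin.p_value,
                       "n_spins": spin.n_spins, "sidedness": spin.sidedness,
                       "seed": spin.seed, "duplication_rate": spin.duplication_rate,
                       "null_quantiles": {q: float(np.quantile(spin.null_stats, float(q)))
                                          for q in ("0.025", "0.5", "0.975")}}
            (nulls_dir / "spin_strength.json").write_text(json.dumps(payload, indent=1))
            record("nulls/spin_strength", nulls_dir / "spin_strength.json")
            manifest["stages"]["spins"] = "ok"
        else:
            manifest["stages"]["spins"] = "skipped"
        if config.run_mismatch:
            mm = subject_mismatch_test([mc_by_subject[s] for s in subject_ids],
                                       [mind_by_subject[s] for s in subject_ids],
                                       n_perm=config.n_perm, seed=seeds["mismatch"],
                                       dist_correct=config.dist_correct, geom=geom)
            payload = {"observed_mean": mm.observed_mean, "p_value": mm.p_value,
                       "n_perm": mm.n_perm, "seed": mm.seed,
                       "null_quantiles": {q: float(np.quantile(mm.null_means, float(q)))
                                          for q in ("0.025", "0.5", "0.975")}}
            (nulls_dir / "mismatch.json").write_text(json.dumps(payload, indent=1))
            record("nulls/mismatch", nulls_dir / "mismatch.json")
            manifest["stages"]["mismatch"] = "ok"
        else:
            manifest["stages"]["mismatch"] = "skipped"

        # ---- inference ----------------------------------------------------
        glm_dir = out / "glm"
        glm_dir.mkdir(exist_ok=True)
        y_global = per_subject["global_rho"].to_numpy()
        glm = fit_glm(y_global, cohort)
        ci = bootstrap_ci(y_global, cohort, n_boot=config.n_boot, seed=seeds["bootstrap"])
        global_glm = {"betas": glm.betas, "p_values": glm.p_values,
                      "partial_r": glm.partial_r, "bootstrap_ci": ci,
                      "n_boot": config.n_boot, "n_obs": glm.n_obs}
        (glm_dir / "global.json").write_text(json.dumps(global_glm, indent=1))
        record("glm/global", glm_dir / "global.json")
        regional = regional_age_effects(local, cohort, q=config.fdr_q)
        regional.to_csv(glm_dir / "regional.tsv", sep="\t", index=False)
        record("glm/regional", glm_dir / "regional.tsv")
        manifest["stages"]["glm"] = "ok"
    except Exception as exc:
        manifest["stages"]["error"] = f"{type(exc).__name__}: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=1))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    return json.loads(json.dumps(echo, default=str))
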