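"""End-to-end orchestration: simulate → geometry → statistics → reports.

A single :class:`RunConfig` drives all stages; every stage writes tidy
CSV/JSON artifacts into the output directory and registers them in a run
manifest (with SHA-256 checksums, the effective parameters and the seed),
so re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from organgeo import __version__
from organgeo.centreline import (parameterize, resample_equal,
                                 subset_by_landmarks, write_centreline)
from organgeo.diffgeo import (curvature_torsion, normalize_by_length,
                              radius_profile, tilt_angle)
from organgeo.functional_comparison import (distance_matrix, group_ellipsoid,
                                            location_test, mds_embed)
from organgeo.morphometrics import (gpa_align, pairwise_group_comparison,
                                    procrustes_anova_rrpp, shape_pca)
from organgeo.profiles import (align_and_bin, ar_null,
                               pairwise_profile_correlation, unit_normalize)
from organgeo.proximity import centreline_proximity, contact_call
from organgeo.synthetic import (CohortSpec, GeneratorParams, generate_cohort,
                                generate_intensity_trace, generate_organ_pair,
                                generate_tube_mesh)

log = logging.getLogger("organgeo")

ALL_STAGES = ("simulate", "geometry", "morphometrics", "compare",
              "proximity", "profiles")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str = "organgeo_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    n_per_group: int = 10
    k_pseudolandmarks: int = 500
    delta_frac: float = 0.05
    cutoff: float = 0.3
    n_grid: int = 200
    iterations: int = 1000
    contact_threshold: float = 5.0
    n_intensity_traces: int = 8
    female_params: dict = field(default_factory=dict)
    male_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.delta_frac < 0.5:
            raise ValueError("delta_frac must lie in (0, 0.5)")
        if self.k_pseudolandmarks < 3:
            raise ValueError("k_pseudolandmarks must be ≥ 3")
        if self.iterations < 1:
            raise ValueError("iterations must be ≥ 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - fields
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def cohort_spec(self) -> CohortSpec:
        from organgeo.synthetic import default_female_params, default_male_params

        fp = dataclasses.replace(default_female_params(), **self.female_params)
        mp = dataclasses.replace(default_male_params(), **self.male_params)
        return CohortSpec(n_per_group=self.n_per_group,
                          group_params={"female": fp, "male": mp},
                          seed=self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out: Path, config: RunConfig):
        self.out = out
        self.data = {"organgeo_version": __version__, "seed": config.seed,
                     "config": dataclasses.asdict(config) | {"stages": list(config.stages)},
                     "stages": {}, "files": {}}
        self.data["config_hash"] = hashlib.sha256(
            json.dumps(self.data["config"], sort_keys=True, default=str)
            .encode()).hexdigest()

    def add(self, path: Path) -> None:
        self.data["files"][str(path.relative_to(self.out))] = _sha256(path)

    def stage(self, name: str, seconds: float, **info) -> None:
        self.data["stages"][name] = {"seconds": round(seconds, 3), **info}

    def write(self, failed: str | None = None) -> None:
        if failed:
            self.data["failed_stage"] = failed
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True, default=str)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the manifest dictionary. A stage failure halts the run; the
    manifest is still written with the failing stage marked, and partial
    outputs are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    config.to_yaml(out / "effective_config.yaml")
    manifest.add(out / "effective_config.yaml")
    state: dict = {}
    stages = [s for s in ALL_STAGES if s in config.stages]
    for name in stages:
        t0 = time.time()
        log.info("stage %s starting", name)
        try:
            globals()[f"_stage_{name}"](config, out, state, manifest)
        except Exception:
            log.exception("stage %s failed", name)
            manifest.write(failed=name)
            raise
        manifest.stage(name, time.time() - t0)
        log.info("stage %s done in %.1fs", name, time.time() - t0)
    manifest.write()
    return manifest.data


def _save_csv(df: pd.DataFrame, path: Path, manifest: _Manifest) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.add(path)


def _stage_simulate(cfg: RunConfig, out: Path, state: dict, man: _Manifest) -> None:
    cohort = generate_cohort(cfg.cohort_spec())
    state["cohort"] = cohort
    cl_dir = out / "centrelines"
    cl_dir.mkdir(exist_ok=True)
    for c in cohort.centrelines:
        write_centreline(c, cl_dir / f"{c.specimen_id}.csv", "csv", seed=cfg.seed)
        man.add(cl_dir / f"{c.specimen_id}.csv")
    _save_csv(cohort.metadata, out / "metadata.csv", man)
    log.info("simulated %d specimens", len(cohort))


def _specimen_curves(state: dict):
    for c in state["cohort"].centrelines:
        p = parameterize(c)
        yield c, p, subset_by_landmarks(p, "loop_start", "loop_end")


def _stage_geometry(cfg: RunConfig, out: Path, state: dict, man: _Manifest) -> None:
    meta = state["cohort"].metadata.set_index("specimen_id")
    rows = []
    curv_profiles = {}
    for c, p, sub in _specimen_curves(state):
        kap, tau = curvature_torsion(p, cfg.delta_frac, cutoff=cfg.cutoff)
        kn = normalize_by_length(kap, p.L)
        loop_mask = (kap.s >= p.s[0] + 0.30 * p.L) & (kap.s <= 0.80 * p.L)
        mesh = generate_tube_mesh(p, meta.loc[c.specimen_id, "true_radius"],
                                  n_rings=120)
        rad = radius_profile(p, mesh, cfg.cutoff)
        rows.append({"specimen_id": c.specimen_id, "sex": c.sex,
                     "gut_length": p.L,
                     "loop_norm_curvature_mean": float(np.mean(kn.values[loop_mask])),
                     "tilt_deg": tilt_angle(p, sub),
                     "radius_mean": float(np.mean(rad.values))})
        kn.specimen_id = c.specimen_id
        curv_profiles[c.specimen_id] = kn
    state["geometry"] = pd.DataFrame(rows)
    state["curvature_profiles"] = curv_profiles
    _save_csv(state["geometry"], out / "geometry.csv", man)


def _stage_morphometrics(cfg: RunConfig, out: Path, state: dict, man: _Manifest) -> None:
    cohort = state["cohort"]
    configs = [resample_equal(sub, cfg.k_pseudolandmarks)
               for _, _, sub in _specimen_curves(state)]
    aligned = gpa_align(configs, metadata=cohort.metadata)
    state["aligned"] = aligned
    pca = shape_pca(aligned)
    scores = pd.DataFrame(pca.scores[:, :3], columns=["PC1", "PC2", "PC3"])
    scores.insert(0, "specimen_id", cohort.metadata["specimen_id"])
    _save_csv(scores, out / "pca_scores.csv", man)
    tab = procrustes_anova_rrpp(
        aligned, ["sex", "gonad_volume", "crop_volume", "gut_length", "batch"],
        iterations=cfg.iterations, seed=cfg.seed)
    tab.table.to_csv(out / "procrustes_anova.csv")
    man.add(out / "procrustes_anova.csv")
    pw = pairwise_group_comparison(aligned, "sex", null_terms=["batch"],
                                   iterations=cfg.iterations, seed=cfg.seed)
    pw.to_csv(out / "pairwise_sex.csv")
    man.add(out / "pairwise_sex.csv")
    state["anova"] = tab
    state["pairwise"] = pw


def _stage_compare(cfg: RunConfig, out: Path, state: dict, man: _Manifest) -> None:
    cohort = state["cohort"]
    profs = [state["curvature_profiles"][c.specimen_id]
             for c in cohort.centrelines]
    dm = distance_matrix(profs, relative=True, n_grid=cfg.n_grid)
    dm.to_frame().to_csv(out / "curvature_distances.csv")
    man.add(out / "curvature_distances.csv")
    emb = mds_embed(dm, dim=3, seed=cfg.seed)
    sexes = cohort.metadata["sex"].to_numpy()
    _save_csv(emb.to_frame(groups=sexes), out / "mds_embedding.csv", man)
    ellipsoids = {}
    for sex in pd.unique(sexes):
        ellipsoids[sex] = group_ellipsoid(emb.coords[sexes == sex]).to_dict()
    with open(out / "group_ellipsoids.json", "w") as fh:
        json.dump(ellipsoids, fh, indent=2)
    man.add(out / "group_ellipsoids.json")
    sex_levels = list(pd.unique(sexes))
    p, test = location_test(emb.coords[sexes == sex_levels[0]],
                            emb.coords[sexes == sex_levels[1]])
    with open(out / "location_test.json", "w") as fh:
        json.dump({"groups": sex_levels, "p": p, "test": test,
                   "stress": emb.stress}, fh, indent=2)
    man.add(out / "location_test.json")
    state["mds"] = emb
    state["location_test"] = (p, test)


def _stage_proximity(cfg: RunConfig, out: Path, state: dict, man: _Manifest) -> None:
    meta = state["cohort"].metadata.set_index("specimen_id")
    rng = np.random.default_rng(cfg.seed + 1)
    profiles = []
    for c, p, sub in _specimen_curves(state):
        mesh = generate_tube_mesh(p, meta.loc[c.specimen_id, "true_radius"],
                                  n_rings=120)
        # a neighbour organ near the loop region, at a random clearance
        gap = float(rng.uniform(0.0, 2.0 * cfg.contact_threshold))
        organ, _ = generate_organ_pair(0.0, "sphere",
                                       seed=int(rng.integers(2**31 - 1)),
                                       radius=60.0)
        anchor_idx = len(sub.points) // 2
        direction = np.array([0.0, 0.0, 1.0])
        centre = sub.points[anchor_idx] + direction * (
            60.0 + gap + meta.loc[c.specimen_id, "true_radius"])
        organ.vertices = organ.vertices - organ.vertices.mean(axis=0) + centre
        organ.organ_name = "neighbour"
        prof = centreline_proximity(sub, mesh, organ)
        prof.specimen_id = c.specimen_id
        profiles.append(prof)
    contacts = contact_call(profiles, cfg.contact_threshold)
    contacts["threshold"] = cfg.contact_threshold
    _save_csv(contacts, out / "contacts.csv", man)
    _save_csv(pd.concat([pr.to_frame() for pr in profiles]),
              out / "proximity_profiles.csv", man)
    state["contacts"] = contacts


def _stage_profiles(cfg: RunConfig, out: Path, state: dict, man: _Manifest) -> None:
    spec = cfg.cohort_spec()
    results = {}
    for sex, params in spec.group_params.items():
        traces = [generate_intensity_trace(200, params, seed=cfg.seed * 1000 + i)
                  for i in range(cfg.n_intensity_traces)]
        binned = align_and_bin(traces)
        _save_csv(binned.to_frame(), out / f"binned_intensity_{sex}.csv", man)
        curvs = [unit_normalize(state["curvature_profiles"][c.specimen_id])
                 for c in state["cohort"].centrelines if c.sex == sex]
        ints = [unit_normalize(t) for t in traces]
        cs = pairwise_profile_correlation(curvs, ints)
        _save_csv(cs.to_frame(), out / f"correlations_{sex}.csv", man)
        _, null = ar_null(traces, curvs, n_sim=1, order=1, seed=cfg.seed)
        _save_csv(null.to_frame(), out / f"correlations_null_{sex}.csv", man)
        results[sex] = {"observed_mean_r": float(cs.flat().mean()),
                        "null_mean_r": float(null.flat().mean()),
                        "n_pairs": cs.n_pairs}
    with open(out / "profiles_summary.json", "w") as fh:
        json.dump(results, fh, indent=2)
    man.add(out / "profiles_summary.json")
    state["profiles"] = results
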