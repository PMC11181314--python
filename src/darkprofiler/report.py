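"""End-to-end pipeline orchestration and summary artifacts.

Composes the profiling stages in screen order — aggregate sites to wells,
select robust features, Z-score against DMSO controls, call activity by
induction, build cluster subprofiles and assign compounds — and writes the
summary tables (activity table, replicate-concordance report, per-cluster
count table, funnel report) together with a run manifest that makes every
output traceable: config snapshot, input digests, seed registry, software
version, timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .profiles import (
    DEFAULT_SIGNIFICANCE_CUTOFF,
    activity_call,
    aggregate_to_wells,
    replicate_concordance,
    select_robust_features,
    zscore_wells,
)
from .subprofiles import assign_clusters, build_subprofile, cluster_counts
from .synthdata import GeneratorSpec, generate_reference_plate_pair, \
    generate_replicate_pair, generate_run, make_cluster_templates

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Every screen threshold as a named key, defaulting to the study values."""

    activity_induction: float = 5.0        # percent: active at induction >= 5
    retest_induction: float = 10.0         # percent: retested at induction >= 10
    full_profile_biosim: float = 75.0      # percent, full-profile similarity
    cluster_biosim: float = 80.0           # percent, subprofile similarity
    robust_feature_similarity: float = 80.0  # percent, cross-repeat rule (0.8)
    sign_consistency: float = 0.85         # fraction, subprofile construction
    significance_cutoff: float = DEFAULT_SIGNIFICANCE_CUTOFF  # |z| cutoff
    min_available_mg: float = 2.0          # funnel availability stage
    min_heavy_atoms: int = 25              # funnel size stage


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "run_output"
    thresholds: Thresholds = field(default_factory=Thresholds)
    # file inputs; when absent, data is synthesised from `generator`
    run1_path: str | None = None
    run2_path: str | None = None
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            raw = yaml.safe_load(path.read_text()) or {}
        else:
            raw = tomllib.loads(path.read_text())
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    seeds: dict[str, int]
    version: str
    started: str
    finished: str | None = None
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full analysis and write its summary artifacts.

    With file inputs (``run1_path``/``run2_path`` pointing at site-level
    feature tables) the pipeline analyses those; otherwise it generates a
    synthetic replicate pair plus a cluster-defining run from
    ``config.generator``.  Deterministic given inputs and seed.
    """
    thr = config.thresholds
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    digests: dict[str, str] = {}
    seeds = {"pipeline": config.seed}

    from .tables import read_feature_table

    if config.run1_path:
        run1_sites = read_feature_table(config.run1_path)
        digests[config.run1_path] = _sha256(config.run1_path)
        run2_sites = None
        if config.run2_path:
            run2_sites = read_feature_table(config.run2_path)
            digests[config.run2_path] = _sha256(config.run2_path)
        run1 = aggregate_to_wells(run1_sites) if "site" in run1_sites else run1_sites
        run2 = (aggregate_to_wells(run2_sites)
                if run2_sites is not None and "site" in run2_sites
                else run2_sites)
        truth = None
        spec = None
    else:
        gen = dict(config.generator)
        gen.setdefault("seed", config.seed)
        spec = GeneratorSpec(**gen)
        if spec.cluster_templates is None:
            spec = dataclasses.replace(
                spec, cluster_templates=make_cluster_templates(
                    spec.n_clusters, spec.n_features, spec.template_support,
                    seed=spec.seed))
        seeds["generator"] = spec.seed
        r1_sites, r2_sites, truth = generate_replicate_pair(
            spec, site_level=True)
        run1 = aggregate_to_wells(r1_sites)
        run2 = aggregate_to_wells(r2_sites)

    # robust feature selection from a synthetic reference-plate pair when no
    # measured reference plates are supplied
    rep_a, rep_b, _ = generate_reference_plate_pair(
        n_signal=20, n_noise=5, n_wells=96, seed=config.seed + 1)
    seeds["reference_plates"] = config.seed + 1
    robust_ref = select_robust_features(
        rep_a, rep_b, min_similarity=thr.robust_feature_similarity)
    logger.info("reference-plate robust feature set: %d features",
                len(robust_ref))

    # Z-profiles over all features of the actual run tables
    profiles1 = zscore_wells(run1, robust=None,
                             significance_cutoff=thr.significance_cutoff)
    activity = pd.DataFrame({
        "induction": profiles1["induction"],
        "active": activity_call(profiles1["induction"].to_numpy(),
                                thr.activity_induction),
    })
    activity.to_csv(outdir / "activity_table.csv")

    outputs = ["activity_table.csv"]
    concord_summary = None
    if run2 is not None:
        profiles2 = zscore_wells(run2, robust=None,
                                 significance_cutoff=thr.significance_cutoff)
        retest = profiles1[profiles1["induction"] >= thr.retest_induction]
        per_compound, concord_summary = replicate_concordance(
            retest, profiles2,
            biosim_threshold=thr.cluster_biosim,
            activity_threshold=thr.activity_induction)
        per_compound.to_csv(outdir / "concordance_per_compound.csv")
        (outdir / "concordance_summary.json").write_text(
            json.dumps(concord_summary, indent=1))
        outputs += ["concordance_per_compound.csv", "concordance_summary.json"]

    if truth is not None and spec is not None:
        # cluster subprofiles from a dedicated defining run with known labels
        defining_assign = {}
        for i, name in enumerate(spec.cluster_templates):
            for j in range(8):
                defining_assign[f"def_{name}_{j}"] = name
        def_spec = dataclasses.replace(spec, seed=config.seed + 2,
                                       precipitation_rate=0.0)
        seeds["defining_run"] = config.seed + 2
        def_sites, _ = generate_run(def_spec, assignments=defining_assign,
                                    site_level=False)
        def_profiles = zscore_wells(def_sites,
                                    significance_cutoff=thr.significance_cutoff)
        subs = []
        for name in spec.cluster_templates:
            block = def_profiles[
                def_profiles.index.get_level_values(0).str.startswith(
                    f"def_{name}_")]
            subs.append(build_subprofile(name, block,
                                         consistency=thr.sign_consistency))
        active_profiles = profiles1[activity_call(
            profiles1["induction"].to_numpy(), thr.activity_induction)]
        assignment = assign_clusters(active_profiles, subs,
                                     threshold=thr.cluster_biosim)
        counts = cluster_counts(assignment)
        assignment.drop(columns=["assigned"]).to_csv(
            outdir / "cluster_assignment.csv")
        counts.to_csv(outdir / "cluster_counts.csv")
        truth.to_csv(outdir / "ground_truth.csv", index=False)
        outputs += ["cluster_assignment.csv", "cluster_counts.csv",
                    "ground_truth.csv"]

    manifest = RunManifest(
        config=config.to_dict(), input_digests=digests, seeds=seeds,
        version=__version__, started=started,
        finished=datetime.now(timezone.utc).isoformat(), outputs=outputs)
    manifest.write(outdir / "manifest.json")
    return manifest
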