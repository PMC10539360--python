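"""End-to-end orchestration: simulate -> preprocess -> train -> predict ->
analyze-errors -> explain -> phenotype, with a provenance manifest.

A run is described by a `RunConfig` (loadable from YAML). One global seed
fans out to named substreams so each stage is individually reproducible;
every stage records its inputs, outputs and seed in `manifest.json`, and
rerunning the same config reproduces deterministic artifacts bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .augment import AugmentationScheme
from .attribution import integrated_gradients, stratify_importance
from .circadian import circadian_summary
from .clock import ClockConfig, GestationalAgeClock
from .enrichment import assign_error_groups, group_difference_tests, oe_effect, permutation_test
from .exceptions import ConfigError
from .phenotype import cluster_enrichment, cluster_graph, embedding_distances
from .simulate import SimulationConfig, generate_cohort, write_cohort_csv


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    clock: ClockConfig = field(default_factory=ClockConfig)
    scheme: AugmentationScheme = field(default_factory=AugmentationScheme)
    split_fractions: tuple = (0.6, 0.1, 0.3)
    downsample: int = 1
    tau: object = "balance"
    rho_cutoff: float = 0.6
    n_permutations: int = 1000
    oakley_threshold: float = 80.0
    n_attribution_samples: int = 10
    ig_steps: int = 64
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw["simulation"])
        if "clock" in raw:
            kwargs["clock"] = ClockConfig(**{
                k: tuple(v) if k == "kernel_sizes" else v for k, v in raw["clock"].items()
            })
        if "scheme" in raw:
            sch = dict(raw["scheme"])
            if "operators" in sch:
                sch["operators"] = tuple(sch["operators"])
            kwargs["scheme"] = AugmentationScheme(**sch)
        for key in ("split_fractions", "downsample", "tau", "rho_cutoff", "n_permutations",
                    "oakley_threshold", "n_attribution_samples", "ig_steps", "seed", "log_level"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key == "split_fractions" else raw[key]
        return cls(**kwargs)


def validate_config(config: RunConfig) -> list:
    """Return the list of invariant violations (empty iff the config is valid)."""
    violations = []
    try:
        config.simulation.validate()
    except ConfigError as e:
        violations.append(f"simulation: {e}")
    try:
        config.clock.validate()
    except ConfigError as e:
        violations.append(f"clock: {e}")
    if not np.isclose(sum(config.split_fractions), 1.0):
        violations.append("split_fractions must sum to 1")
    if isinstance(config.tau, str) and config.tau != "balance":
        violations.append("tau must be a number of weeks or 'balance'")
    if not isinstance(config.tau, str) and config.tau < 0:
        violations.append("tau must be >= 0")
    if not 0 <= config.rho_cutoff <= 1:
        violations.append("rho_cutoff must lie in [0, 1]")
    if config.n_permutations < 1000:
        violations.append("n_permutations must be >= 1000")
    if config.oakley_threshold <= 0:
        violations.append("oakley_threshold must be > 0")
    return violations


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_checkpoint(model: GestationalAgeClock, path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), *[p.value for p in model.net.params])
    path.with_suffix(".json").write_text(json.dumps(asdict(model.config), default=list))


def load_checkpoint(path, dataset=None, scheme=None, downsample: int = 1) -> GestationalAgeClock:
    path = Path(path)
    raw = json.loads(path.with_suffix(".json").read_text())
    raw["kernel_sizes"] = tuple(raw["kernel_sizes"])
    model = GestationalAgeClock(dataset=dataset, config=ClockConfig(**raw),
                                scheme=scheme, downsample=downsample)
    with np.load(path.with_suffix(".npz")) as data:
        model.net.load_state([data[k] for k in data.files])
    return model


def run_pipeline(config: RunConfig, outdir, verbose: bool = False) -> dict:
    """Execute every stage; halt naming the failing stage, retaining artifacts."""
    violations = validate_config(config)
    if violations:
        raise ConfigError("; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": json.loads(json.dumps(asdict(config), default=list)),
                "stages": {}, "seed": config.seed}
    stage = "simulate"
    try:
        t0 = time.time()
        recordings, metadata, truth = generate_cohort(config.simulation)
        cohort_csv = outdir / "cohort.csv"
        write_cohort_csv(recordings, cohort_csv)
        metadata.to_csv(outdir / "metadata.csv")
        truth.patients.to_csv(outdir / "truth_patients.csv", index=False)
        truth.measurements.to_csv(outdir / "truth_measurements.csv", index=False)
        manifest["stages"][stage] = {
            "seed": config.simulation.seed,
            "outputs": {"cohort": _sha256(cohort_csv)},
            "seconds": round(time.time() - t0, 2),
        }

        stage = "preprocess"
        t0 = time.time()
        samples = []
        ga = dict(zip(truth.measurements.sample_id, truth.measurements.ga_weeks))
        for rec, meas in zip(recordings, truth.measurements.itertuples()):
            keep, reason = aio.quality_filter(rec)
            if not keep:
                continue
            samples.append(aio.make_sample(rec, meas.sample_id, ga[meas.sample_id],
                                           oakley_threshold=config.oakley_threshold))
        kept_ids = {s.sample_id for s in samples}
        metadata.data = metadata.data[metadata.data.sample_id.isin(kept_ids)].reset_index(drop=True)
        dataset = aio.split_by_patient(samples, config.split_fractions,
                                       seed=config.seed, metadata=metadata)
        train_mask = metadata.data.patient_id.map(dataset.splits).eq("train").to_numpy()
        dataset.metadata = aio.preprocess_metadata(metadata, train_mask)
        manifest_csv = aio.write_samples(samples, outdir / "samples", dataset.splits)
        manifest["stages"][stage] = {"n_samples": len(samples),
                                     "seconds": round(time.time() - t0, 2)}

        stage = "metrics"
        t0 = time.time()
        rows = []
        for s in samples:
            summ = circadian_summary(s.activity_counts, s.signal[0], s.sleep_mask,
                                     s.start_weekday)
            rows.append({"sample_id": s.sample_id, **summ.as_dict()})
        pd.DataFrame(rows).to_csv(outdir / "circadian_metrics.csv", index=False)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "train"
        t0 = time.time()
        model = GestationalAgeClock(dataset, config.clock, config.scheme,
                                    downsample=config.downsample)
        results = model.fit(verbose=verbose)
        save_checkpoint(model, outdir / "clock")
        results.history.to_csv(outdir / "history.csv", index=False)
        manifest["stages"][stage] = {"epochs": int(len(results.history)),
                                     "best_val_loss": results.best_val_loss,
                                     "seconds": round(time.time() - t0, 2)}

        stage = "predict"
        t0 = time.time()
        records = results.predict_all()
        records.to_csv(outdir / "predictions.csv", index=False)
        manifest["stages"][stage] = {"metrics": {
            split: results.evaluate(split) for split in ("train", "val", "test")
        }, "seconds": round(time.time() - t0, 2)}

        stage = "analyze-errors"
        t0 = time.time()
        grouping = assign_error_groups(records, config.tau)
        grouping.assignments.to_csv(outdir / "error_groups.csv", index=False)
        md = dataset.metadata
        ordered = md.data.set_index("sample_id").loc[grouping.assignments.sample_id]
        md_aligned = aio.MetadataTable(ordered.reset_index(), md.kinds, md.categories)
        tests = group_difference_tests(md_aligned, grouping.assignments.group.to_numpy())
        tests.to_csv(outdir / "group_tests.csv", index=False)
        sizes = grouping.sizes()
        flags = ordered["ptb"].astype(bool).to_numpy()
        counts = {g: float(flags[(grouping.assignments.group == g).to_numpy()].sum())
                  for g in sizes}
        enr = oe_effect(sizes, counts)
        perm = permutation_test(grouping.assignments.group.to_numpy(), flags.astype(float),
                                group_of_interest="higher", n_iter=config.n_permutations,
                                rng=np.random.default_rng(config.seed + 7), method="tail")
        pd.DataFrame([
            {"group": g, "observed": e.observed, "expected": e.expected,
             "oe_ratio": e.oe_ratio, "effect_pct": e.effect_pct,
             "p_perm_higher": perm.p_value}
            for g, e in enr.items()
        ]).to_csv(outdir / "ptb_enrichment.csv", index=False)
        manifest["stages"][stage] = {"tau": grouping.threshold,
                                     "sizes": sizes,
                                     "seconds": round(time.time() - t0, 2)}

        stage = "explain"
        t0 = time.time()
        test_samples = dataset.subset("test") or samples
        strata_rows = []
        for s in test_samples[: config.n_attribution_samples]:
            x = model._prepare_signal(s.signal)
            amap = integrated_gradients(model, x, n_steps=config.ig_steps,
                                        sample_id=s.sample_id)
            mask = s.sleep_mask
            if config.downsample > 1:
                L = len(mask) - len(mask) % config.downsample
                mask = mask[:L].reshape(-1, config.downsample).mean(axis=1) >= 0.5
            st = stratify_importance(amap, mask, s.start_weekday)
            st["sample_id"] = s.sample_id
            strata_rows.append(st)
        pd.concat(strata_rows).to_csv(outdir / "importance_strata.csv", index=False)
        manifest["stages"][stage] = {"n_samples": len(strata_rows),
                                     "seconds": round(time.time() - t0, 2)}

        stage = "phenotype"
        t0 = time.time()
        emb, ids = results.embeddings("test") if dataset.subset("test") else (
            model.embed_array(np.stack([model._prepare_signal(s.signal) for s in samples])),
            [s.sample_id for s in samples],
        )
        D = embedding_distances(emb)
        clust = cluster_graph(D, seed=config.seed)
        pd.DataFrame({"sample_id": ids, "cluster": clust["labels"]}).to_csv(
            outdir / "clusters.csv", index=False)
        sub = md.data.set_index("sample_id").loc[ids].reset_index()
        enrich = cluster_enrichment(clust["labels"],
                                    aio.MetadataTable(sub, md.kinds, md.categories),
                                    n_iter=config.n_permutations, seed=config.seed + 11)
        enrich.to_csv(outdir / "cluster_enrichment.csv", index=False)
        manifest["stages"][stage] = {"n_clusters": int(len(np.unique(clust["labels"]))),
                                     "seconds": round(time.time() - t0, 2)}
    except Exception as e:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
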