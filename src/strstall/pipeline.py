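"""End-to-end pipeline orchestration with a single seeded configuration.

Stages run in order — design -> simulate -> score -> classify -> map ->
mutations -> genome — communicating only through files in the run
directory, with a provenance manifest recording the configuration,
seed and per-stage outputs. Rerunning with the same configuration
reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import coverage as _coverage
from . import genome as _genome
from . import kinetics as _kinetics
from . import library as _library
from . import motifs as _motifs
from . import simulate as _simulate
from . import variants as _variants

log = logging.getLogger("strstall")


@dataclass
class PipelineConfig:
    seed: int = 0
    max_period: int = 6
    str_lengths: tuple[int, ...] = (24, 48, 72)
    n_hairpin: int = 960
    n_g4: int = 1500
    n_imot: int = 472
    n_random: int = 1000
    time_points: tuple[float, ...] = _simulate.TIME_POINTS
    depth: int = 10_000
    replicates: int = 2
    subsample: int | None = None  # cap on simulated entries (smoke runs)
    n_mutation_entries: int = 20
    reads_per_entry: int = 200
    fixture_loci: int = 2000

    def __post_init__(self) -> None:
        times = tuple(self.time_points)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("time_points must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(self).items()
                },
                fh,
            )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, writing outputs and a provenance manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "started": time.time()}
    rng = np.random.default_rng(config.seed)

    def stage(name):
        def deco(fn):
            t0 = time.time()
            log.info("stage %s", name)
            entry = manifest["stages"].setdefault(name, {})
            try:
                result = fn()
            except Exception as exc:  # preserve partial outputs
                entry.update(status="failed", error=str(exc))
                with open(out / "manifest.json", "w") as fh:
                    json.dump(manifest, fh, indent=1, default=str)
                raise StageError(name, exc) from exc
            entry.update(status="ok", seconds=round(time.time() - t0, 2))
            return result

        return deco

    @stage("design")
    def _design():
        catalog = _motifs.enumerate_primitive_motifs(config.max_period)
        entries = _library.build_library(
            catalog,
            config.n_hairpin,
            config.n_g4,
            config.n_imot,
            config.n_random,
            seed=config.seed,
        )
        _motifs.catalog_dataframe(catalog).to_csv(
            out / "motif_catalog.tsv", sep="\t", index=False
        )
        _library.manifest_dataframe(entries).to_csv(
            out / "library_manifest.tsv", sep="\t", index=False
        )
        _library.write_fasta(entries, out / "library_oligos.fasta")
        return catalog, entries

    catalog, entries = _design

    if config.subsample is not None and config.subsample < len(entries):
        # keep all controls; subsample the STR bulk
        controls = [e for e in entries if e.category != "STR"]
        strs = [e for e in entries if e.category == "STR"]
        take = max(config.subsample - len(controls), 0)
        idx = rng.choice(len(strs), size=take, replace=False)
        sim_entries = controls + [strs[i] for i in sorted(idx)]
    else:
        sim_entries = entries

    @stage("simulate")
    def _sim():
        truths = _simulate.sample_ground_truth(sim_entries, seed=config.seed)
        counts = _simulate.simulate_counts(
            truths,
            depth=config.depth,
            replicates=config.replicates,
            times=config.time_points,
            seed=config.seed,
        )
        counts.to_csv(out / "counts.tsv", sep="\t", index=False)
        return truths, counts

    truths, counts = _sim

    @stage("score")
    def _score():
        controls = [e.entry_id for e in sim_entries if e.category == "RANDOM"]
        profiles = _kinetics.build_stall_profiles(counts, controls)
        _kinetics.profiles_dataframe(profiles).to_csv(
            out / "stall_profiles.tsv", sep="\t", index=False
        )
        return profiles

    profiles = _score

    @stage("classify")
    def _cls():
        by_id = {e.entry_id: e for e in sim_entries}
        ctrl_ids = [
            e.entry_id
            for e in sim_entries
            if e.category in ("HAIRPIN", "G4", "IMOT")
        ]
        designed = {
            i: {"HAIRPIN": "HAIRP", "G4": "QUAD", "IMOT": "IMOT"}[by_id[i].category]
            for i in ctrl_ids
        }
        labels = _classify.build_training_labels(
            {i: profiles[i] for i in ctrl_ids}, designed
        )
        feats = np.array(
            [
                _classify.feature_vector(profiles[i], by_id[i].insert)
                for i in labels.index
            ]
        )
        model = _classify.train(feats, labels.to_numpy(), seed=config.seed)
        str_ids = [e.entry_id for e in sim_entries if e.category == "STR"]
        str_feats = np.array(
            [_classify.feature_vector(profiles[i], by_id[i].insert) for i in str_ids]
        )
        calls = _classify.predict(model, str_feats, str_ids)
        _classify.calls_dataframe(calls).to_csv(
            out / "structure_calls.tsv", sep="\t", index=False
        )
        manifest["stages"]["classify"]["holdout_accuracy"] = model.holdout_accuracy
        return model, calls

    model, calls = _cls

    @stage("map")
    def _map():
        rows = []
        subset = [t for t in truths if t.true_class == "HAIRP"][:50]
        by_id = {e.entry_id: e for e in sim_entries}
        for truth in subset:
            cov = _simulate.simulate_coverage(
                truth,
                by_id[truth.entry_id].insert_length,
                times=config.time_points,
                seed=config.seed,
            )
            rows.append(cov)
        if not rows:
            return pd.DataFrame()
        cov = pd.concat(rows, ignore_index=True)
        prof = _coverage.profiles_from_table(cov)
        travel = _coverage.travel_table(prof)
        travel.to_csv(out / "travel_distances.tsv", sep="\t", index=False)
        return travel

    _map

    @stage("mutations")
    def _mut():
        by_id = {e.entry_id: e for e in sim_entries}
        str_truths = [
            t for t in truths if by_id[t.entry_id].category == "STR"
        ][: config.n_mutation_entries]
        all_calls = []
        for truth in str_truths:
            entry = by_id[truth.entry_id]
            reads, parental = _simulate.simulate_reads_with_variants(
                truth, entry, n_reads=config.reads_per_entry, seed=config.seed
            )
            unit = entry.motif or entry.insert
            cands = _variants.call_raw_variants(reads, entry.insert, entry.entry_id)
            all_calls.extend(_variants.filter_variants(cands, unit, parental))
        _variants.calls_dataframe(all_calls).to_csv(
            out / "variant_calls.tsv", sep="\t", index=False
        )
        return all_calls

    _mut

    @stage("genome")
    def _gen():
        class_sigma: dict[str, float] = {}
        ds_of = {e.entry_id: _motifs.canonical_ds_class(e.motif) for e in sim_entries if e.category == "STR" and e.motif}
        sig = {
            e: profiles[e].sigma_mean[min(config.time_points)]
            for e in ds_of
            if e in profiles
        }
        agg: dict[str, list[float]] = {}
        for eid, s in sig.items():
            agg.setdefault(ds_of[eid], []).append(s)
        class_sigma = {k: float(np.mean(v)) for k, v in agg.items()}
        if len(class_sigma) < 2:
            class_sigma = {"AAG": 0.2, "AGG": 0.6}
        cfg = _genome.FixtureConfig(
            motif_sigma=class_sigma, n_loci=config.fixture_loci
        )
        loci, snps, params, truth = _genome.generate_genome_fixture(
            cfg, seed=config.seed
        )
        _genome.write_fixture(loci, snps, params, truth, str(out / "fixture"))
        unstable = [l for l in loci if l.mu > _genome.MU_QUANTIFICATION_FLOOR]
        stable = [l for l in loci if l.mu <= _genome.MU_QUANTIFICATION_FLOOR]
        res = _genome.boundary_enrichment(
            unstable, stable, snps, "unstable (mu > 1e-7.5) vs stable loci"
        )
        manifest["stages"]["genome"]["boundary_odds_ratio"] = res.odds_ratio
        manifest["stages"]["genome"]["boundary_p"] = res.p_value
        return res

    _gen

    manifest["finished"] = time.time()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
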