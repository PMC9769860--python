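"""End-to-end orchestration: simulate -> profile -> screen -> gs -> cohort.

A :class:`RunConfig` holds every input path and every numeric rule of the
pipeline (core floor 0.01%, DRM retention 0.1%, alignment identity 80%,
merged coverage 90%, bin majority 0.5, VF stability 0.6, sketch
parameters k=31 / 10,000 / 10 reps) plus the global seed.  ``run_all``
executes the requested stages, writes per-stage TSV/JSON outputs under
the output directory, and records a manifest with the package version,
seeds, thresholds and collected warnings — enough to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import gene_screen as gs_mod
from . import io as gio
from . import kmer, profile, stats, synthetic

__all__ = ["RunConfig", "run_all", "load_config"]


@dataclass
class RunConfig:
    out_dir: str = "gutcohort_out"
    seed: int = 0

    # inputs; empty string means "not provided" (stage may simulate instead)
    abundance_path: str = ""
    abundance_dialect: str = "matrix"
    metadata_path: str = ""
    alignments_path: str = ""
    alignments_format: str = "tabular"
    catalog_path: str = ""
    drm_list_path: str = ""
    class_map_path: str = ""
    fasta_a: str = ""
    fasta_b: str = ""

    simulate: bool = True
    months: int = 12
    stages: tuple[str, ...] = ("profile", "screen", "gs", "cohort")

    # rule thresholds (percent unless noted)
    core_floor: float = 0.01
    drm_retention: float = 0.1
    min_identity: float = 80.0
    min_coverage: float = 90.0
    bin_fraction: float = 0.5  # fraction, not percent
    vf_fraction: float = 0.6  # fraction, not percent

    # sketch parameters
    k: int = 31
    sketch_size: int = 10_000
    reps: int = 10

    n_perm: int = 999

    def validate(self) -> None:
        if not (0 <= self.core_floor <= 100 and 0 <= self.drm_retention <= 100):
            raise ValueError("abundance thresholds must lie in [0,100] percent")
        if not (0 <= self.min_identity <= 100 and 0 <= self.min_coverage <= 100):
            raise ValueError("alignment thresholds must lie in [0,100] percent")
        if not (0 <= self.bin_fraction <= 1 and 0 <= self.vf_fraction <= 1):
            raise ValueError("bin/vf fractions must lie in [0,1]")
        if self.k < 1 or self.sketch_size < 1 or self.reps < 1:
            raise ValueError("sketch parameters must be positive")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def _stage(name: str):
    """Decorator: re-raise stage failures naming the stage."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages": {},
        "warnings": [],
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table, meta = _load_or_simulate(config)
        gio.write_abundance(table, out / "abundance.tsv")
        gio.write_metadata(meta, out / "metadata.tsv")

        if "profile" in config.stages:
            _run_profile(config, table, out, manifest)
        if "screen" in config.stages:
            _run_screen(config, meta, out, manifest)
        if "gs" in config.stages:
            _run_gs(config, out, manifest)
        if "cohort" in config.stages:
            _run_cohort(config, table, meta, out, manifest)

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


@_stage("input")
def _load_or_simulate(config: RunConfig):
    if config.abundance_path and config.metadata_path:
        table = gio.read_abundance(config.abundance_path, config.abundance_dialect)
        meta = gio.read_metadata(config.metadata_path)
        return table, meta
    if not config.simulate:
        raise FileNotFoundError(
            "abundance/metadata paths not provided and simulate=False"
        )
    cfg = synthetic.CohortConfig(
        n_regions=1 if config.months else 4,
        locations_per_region=1 if config.months else 3,
        participants_per_location=7 if config.months else 4,
        months=config.months,
        seed=config.seed,
    )
    return synthetic.simulate_cohort(cfg)


@_stage("profile")
def _run_profile(config: RunConfig, table, out: Path, manifest: dict) -> None:
    div = profile.diversity(table, detection_floor=config.core_floor)
    core = profile.core_taxa(table, floor=config.core_floor)
    if config.drm_list_path:
        drm_df = pd.read_csv(config.drm_list_path, sep="\t")
    else:
        drm_df = profile.default_drm_list()
    drm = profile.drm_screen(
        table, list(drm_df.iloc[:, 0]), retention=config.drm_retention
    )
    ent = profile.enterotype(table)
    div.to_csv(out / "diversity.tsv", sep="\t")
    core.to_csv(out / "core_taxa.tsv", sep="\t")
    drm.to_csv(out / "drm_screen.tsv", sep="\t")
    ent.to_csv(out / "enterotypes.tsv", sep="\t")
    manifest["stages"]["profile"] = {
        "n_core": int(core["is_core"].sum()),
        "n_drm_retained": int(drm["retained"].sum()),
    }


@_stage("screen")
def _run_screen(config: RunConfig, meta, out: Path, manifest: dict) -> None:
    if config.alignments_path:
        if not Path(config.alignments_path).exists():
            raise FileNotFoundError(f"alignment file not found: {config.alignments_path}")
        if not config.catalog_path:
            raise ValueError("screen stage needs a catalog with provided alignments")
        catalog = _load_catalog(config.catalog_path)
        hits = gio.read_alignments(
            config.alignments_path, config.alignments_format, catalog
        )
        by_sample = {"sample": hits}
    else:
        catalog = synthetic.GeneCatalog(
            {f"gene{i:03d}_1_SYN{i:05d}": 600 + 50 * (i % 7) for i in range(30)}
        )
        truth = synthetic.plant_gene_truth(
            meta, catalog, n_cohort_stable=4, n_individual_stable=8,
            n_transient=10, seed=config.seed,
        )
        by_sample = synthetic.simulate_gene_hits(truth, catalog, seed=config.seed)
    presence, coverage = gs_mod.screen_cohort(
        by_sample, catalog, config.min_identity, config.min_coverage
    )
    class_map = (
        gio.read_class_map(config.class_map_path)
        if config.class_map_path
        else gs_mod.default_class_map()
    )
    classes = gs_mod.rollup(presence, class_map)
    presence.astype(int).to_csv(out / "gene_presence.tsv", sep="\t")
    coverage.to_csv(out / "gene_coverage.tsv", sep="\t")
    classes.to_csv(out / "class_rollup.tsv", sep="\t")
    manifest["stages"]["screen"] = {
        "n_present_calls": int(presence.values.sum()),
        "n_genes": len(catalog),
    }


def _load_catalog(path: str):
    p = Path(path)
    if p.suffix in (".fa", ".fasta", ".fna"):
        return gio.read_catalog_fasta(p)
    return gio.read_catalog_tsv(p)


@_stage("gs")
def _run_gs(config: RunConfig, out: Path, manifest: dict) -> None:
    if config.fasta_a and config.fasta_b:
        from Bio import SeqIO

        seqs_a = [str(r.seq) for r in SeqIO.parse(config.fasta_a, "fasta")]
        seqs_b = [str(r.seq) for r in SeqIO.parse(config.fasta_b, "fasta")]
        set_a = kmer.canonical_kmers(seqs_a, config.k)
        set_b = kmer.canonical_kmers(seqs_b, config.k)
    else:
        set_a, set_b = synthetic.simulate_sequence_sets(
            40_000, containment=0.25, seed=config.seed, k=config.k
        )
    sk_a = kmer.build_sketch_set(
        set_a, config.sketch_size, config.reps, config.seed, "A"
    )
    sk_b = kmer.build_sketch_set(
        set_b, config.sketch_size, config.reps, config.seed, "B"
    )
    res = kmer.genetic_similarity(sk_a, sk_b)
    (out / "gs.json").write_text(
        json.dumps(
            {
                "sample_a": res.sample_a,
                "sample_b": res.sample_b,
                "shared_counts": res.shared_counts,
                "n_sum": res.n_sum,
                "gs": res.gs,
            },
            indent=2,
        )
    )
    manifest["stages"]["gs"] = {"gs": res.gs, "n_sum": res.n_sum}


@_stage("cohort")
def _run_cohort(config: RunConfig, table, meta, out: Path, manifest: dict) -> None:
    d = stats.bray_curtis(table.renormalize())
    factors = ["participant_id", "region", "location"]
    factors = [f for f in factors if f in meta.df.columns and meta.df[f].nunique() > 1]
    sweep = stats.factor_sweep(d, meta, factors, n_perm=config.n_perm, seed=config.seed)
    sweep.to_csv(out / "permanova_sweep.tsv", sep="\t")
    ord_res = stats.pcoa(d, n_axes=2)
    ord_res.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
    contrasts = {}
    for factor in factors:
        try:
            c = stats.group_contrast(d, meta, factor)
        except ValueError:
            continue
        contrasts[factor] = {
            "within_mean": float(np.mean(c.within)),
            "between_mean": float(np.mean(c.between)),
            "p": c.p_value,
        }
    (out / "contrasts.json").write_text(json.dumps(contrasts, indent=2))
    manifest["stages"]["cohort"] = {
        "top_factor": sweep.index[0] if len(sweep) else None,
        "contrasts": contrasts,
    }
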