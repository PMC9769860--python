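"""Synthetic cohort generator.

Emulates the study design the pipeline is built for — a multi-region
cross-sectional survey (four regions, one of them subdivided into
locations) plus a small longitudinal arm (seven participants sampled
monthly for a year) — with the statistical structure the downstream
analyses assume:

* abundances are a softmax of per-taxon log-scale effects
  (base mean + region offset + individual offset + cumulative monthly
  random-walk drift + sample noise), scaled to percent, so each effect
  is independent and can be switched off;
* a planted set of core taxa is guaranteed to reach the 0.01% floor in
  every sample, while every non-core taxon is forced absent somewhere;
* a configurable fraction of participants is Prevotella-dominant
  (enterotype ET_P), the rest Bacteroides-dominant (ET_B);
* gene-screen inputs are emitted with exact planted merged coverage and
  identity, so presence truth is known per (sample, gene);
* sequence sets for the k-mer module are generated with an exact planted
  containment.

Everything is a pure function of the config seed: one global seed, all
sub-generators derive child seeds deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import AbundanceTable, AlignmentHit, GeneCatalog, Metadata

__all__ = [
    "CohortConfig",
    "PlantedGene",
    "simulate_cohort",
    "simulate_gene_hits",
    "simulate_sequence_sets",
    "plant_gene_truth",
    "plant_presence",
    "default_cross_sectional",
    "default_longitudinal",
]

_REGION_NAMES = ["Beijing", "Wuxi", "Zigong", "Kaifeng"]


@dataclass
class CohortConfig:
    """Design and effect sizes of a simulated cohort.

    All effect SDs are on the log-abundance scale.  ``months = 0`` gives a
    cross-sectional cohort (one sample per participant, no month index);
    ``months = m > 0`` samples every participant once per month.
    ``drift_sd`` is the per-month scale of a Gaussian random walk, which
    makes the expected community dissimilarity grow with the sampling
    interval.  ``enterotype_fraction`` is the proportion of participants
    whose community is Prevotella-dominant.
    """

    n_regions: int = 4
    locations_per_region: int = 3
    participants_per_location: int = 4
    n_taxa: int = 150
    n_core_taxa: int = 30
    months: int = 0
    region_effect_sd: float = 0.3
    individual_effect_sd: float = 0.8
    noise_sd: float = 0.2
    drift_sd: float = 0.15
    enterotype_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("region_effect_sd", "individual_effect_sd", "noise_sd", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_core_taxa > self.n_taxa:
            raise ValueError("n_core_taxa cannot exceed n_taxa")
        if not (0.0 <= self.enterotype_fraction <= 1.0):
            raise ValueError("enterotype_fraction must lie in [0,1]")
        if self.months > 0 and self.participants_per_location == 0:
            raise ValueError("longitudinal design needs participants")


def default_cross_sectional(seed: int = 0) -> CohortConfig:
    """Four regions x three locations x four participants, single visit."""
    return CohortConfig(seed=seed)


def default_longitudinal(seed: int = 0) -> CohortConfig:
    """One region, seven participants, twelve monthly samples each."""
    return CohortConfig(
        n_regions=1,
        locations_per_region=1,
        participants_per_location=7,
        months=12,
        seed=seed,
    )


def _taxon_names(n_taxa: int) -> list[str]:
    names = ["Bacteroides", "Prevotella", "Faecalibacterium", "Alistipes",
             "Parabacteroides", "Roseburia", "Eubacterium", "Ruminococcus"]
    names = names[: min(len(names), n_taxa)]
    names += [f"Genus_{i:03d}" for i in range(len(names), n_taxa)]
    return names


def simulate_cohort(config: CohortConfig) -> tuple[AbundanceTable, Metadata]:
    """Generate a (percent-scale) abundance table and matching metadata.

    The first ``n_core_taxa`` taxa (Bacteroides, Prevotella, ...) are the
    planted core set: abundance >= 0.01% in every sample.  Non-core taxa
    are transient — each is forced absent in at least one sample.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    names = _taxon_names(cfg.n_taxa)
    n_visits = max(cfg.months, 1)

    # base log-means: Bacteroides-dominated community, core taxa elevated
    base = rng.normal(0.0, 1.0, size=cfg.n_taxa)
    base[: cfg.n_core_taxa] = rng.normal(1.5, 0.6, size=cfg.n_core_taxa)
    base[0] = 4.5  # Bacteroides
    if cfg.n_taxa > 1:
        base[1] = 2.2  # Prevotella
    if cfg.n_taxa > 2:
        base[2] = 3.2  # Faecalibacterium

    region_off = rng.normal(0.0, cfg.region_effect_sd, size=(cfg.n_regions, cfg.n_taxa))

    meta_rows = []
    log_rows = []
    participant_counter = 0
    sexes = np.array(["F", "M"])
    for r in range(cfg.n_regions):
        region = _REGION_NAMES[r] if r < len(_REGION_NAMES) else f"Region{r+1}"
        for loc in range(cfg.locations_per_region):
            location = f"{region}-L{loc + 1}"
            for _ in range(cfg.participants_per_location):
                participant_counter += 1
                pid = f"P{participant_counter:03d}"
                indiv = rng.normal(0.0, cfg.individual_effect_sd, size=cfg.n_taxa)
                is_etp = rng.random() < cfg.enterotype_fraction
                # enterotype dominance is part of the individual effect:
                # with individual_effect_sd = 0 there are no per-person
                # community differences, enterotypes included
                if is_etp and cfg.n_taxa > 1 and cfg.individual_effect_sd > 0:
                    # Prevotella-dominant participant: push Prevotella above
                    # Bacteroides on the log scale for this individual
                    indiv[1] += (base[0] - base[1]) + 1.5
                lifestyle = {
                    "sex": sexes[rng.integers(2)],
                    "yogurt": bool(rng.random() < 0.4),
                    "alcohol": bool(rng.random() < 0.35),
                    "smoking": bool(rng.random() < 0.25),
                    "exercise": bool(rng.random() < 0.5),
                    "age": float(np.round(rng.uniform(18, 69), 1)),
                    "bmi": float(np.round(rng.normal(21.8, 2.2), 1)),
                }
                drift = np.zeros(cfg.n_taxa)
                for t in range(n_visits):
                    if t > 0:
                        drift = drift + rng.normal(0.0, cfg.drift_sd, size=cfg.n_taxa)
                    noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_taxa)
                    log_ab = base + region_off[r] + indiv + drift + noise
                    sid = f"{pid}-m{t:02d}" if cfg.months > 0 else pid
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "participant_id": pid,
                            "region": region,
                            "location": location,
                            "month_index": t if cfg.months > 0 else pd.NA,
                            **lifestyle,
                        }
                    )
                    log_rows.append(log_ab)

    logm = np.array(log_rows)
    expm = np.exp(logm - logm.max(axis=1, keepdims=True))

    # transient (non-core) taxa: Bernoulli presence, >=1 forced absence each.
    # Skipped when every effect SD is zero: the degenerate generator is fully
    # deterministic and produces identical samples.
    stochastic = any(
        sd > 0
        for sd in (cfg.region_effect_sd, cfg.individual_effect_sd, cfg.noise_sd, cfg.drift_sd)
    )
    n_samples = expm.shape[0]
    if stochastic and cfg.n_taxa > cfg.n_core_taxa and n_samples > 1:
        transient = slice(cfg.n_core_taxa, cfg.n_taxa)
        present = rng.random((n_samples, cfg.n_taxa - cfg.n_core_taxa)) < 0.7
        all_present = present.all(axis=0)
        for j in np.flatnonzero(all_present):
            present[rng.integers(n_samples), j] = False
        expm[:, transient] *= present

    pct = 100.0 * expm / expm.sum(axis=1, keepdims=True)
    # guarantee the planted core floor: clamp with 2x margin, renormalize once
    floor = 0.01
    core = slice(0, cfg.n_core_taxa)
    pct[:, core] = np.maximum(pct[:, core], 2 * floor)
    pct = 100.0 * pct / pct.sum(axis=1, keepdims=True)

    table = AbundanceTable(
        pd.DataFrame(pct, index=[m["sample_id"] for m in meta_rows], columns=names),
        rank="genus",
    )
    meta = Metadata(pd.DataFrame(meta_rows))
    return table, meta


# ---------------------------------------------------------------------------
# gene-screen truth


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one (sample, gene): target merged coverage
    fraction, per-hit identity, and a persistence label."""

    sample_id: str
    gene_id: str
    coverage: float
    identity: float
    label: str = "transient"  # {cohort_stable, individual_stable, transient, absent}

    def expected_present(
        self, min_identity: float = 80.0, min_coverage: float = 90.0, gene_length: int | None = None
    ) -> bool:
        if self.label == "absent" or self.coverage <= 0:
            return False
        if not (self.identity > min_identity):
            return False
        if gene_length is None:
            return 100.0 * self.coverage > min_coverage
        covered = int(round(self.coverage * gene_length))
        return 100.0 * covered / gene_length > min_coverage


def simulate_gene_hits(
    truth: list[PlantedGene],
    catalog: GeneCatalog,
    read_len: int = 150,
    seed: int = 0,
    identity_jitter: float = 0.8,
) -> dict[str, list[AlignmentHit]]:
    """Emit alignment hits realizing each planted (sample, gene) truth.

    The gene is tiled left-to-right with intervals of at most ``read_len``
    bases so the merged coverage equals round(coverage * length) exactly;
    per-hit identities are the planted identity plus a small uniform
    jitter (never enough to cross the 80% filter for the planted grid).
    Genes labeled absent (or with zero coverage) emit no hits.
    """
    rng = np.random.default_rng(seed)
    hits: dict[str, list[AlignmentHit]] = {}
    for rec in truth:
        hits.setdefault(rec.sample_id, [])
        length = catalog.length(rec.gene_id)
        if read_len > length:
            raise ValueError(
                f"read_len {read_len} exceeds gene {rec.gene_id!r} length {length}"
            )
        if rec.label == "absent" or rec.coverage <= 0:
            continue
        if not (0.0 <= rec.coverage <= 1.0):
            raise ValueError(f"planted coverage {rec.coverage} outside [0,1]")
        covered = int(round(rec.coverage * length))
        if covered == 0:
            continue
        pos = 1
        i = 0
        while pos <= covered:
            end = min(pos + read_len - 1, covered)
            ident = rec.identity + rng.uniform(-identity_jitter, identity_jitter)
            hits[rec.sample_id].append(
                AlignmentHit(
                    read_id=f"{rec.sample_id}|{rec.gene_id}|r{i}",
                    gene_id=rec.gene_id,
                    identity_pct=float(np.clip(ident, 0.0, 100.0)),
                    ref_start=pos,
                    ref_end=end,
                )
            )
            pos = end + 1
            i += 1
    return hits


def plant_gene_truth(
    meta: Metadata,
    catalog: GeneCatalog,
    n_cohort_stable: int,
    n_individual_stable: int,
    n_transient: int,
    seed: int = 0,
    identity: float = 99.0,
) -> list[PlantedGene]:
    """Assign persistence labels to catalog genes over a longitudinal design.

    Cohort-stable genes are present (full coverage) in every sample;
    individual-stable genes in every sample of a random subset of
    participants; transient genes in a strict, nonempty subset of each
    carrier participant's samples.  Remaining genes are absent.
    """
    rng = np.random.default_rng(seed)
    genes = catalog.gene_ids
    need = n_cohort_stable + n_individual_stable + n_transient
    if need > len(genes):
        raise ValueError("not enough catalog genes for the requested design")
    part = meta.column("participant_id")
    participants = sorted(part.dropna().unique())
    by_part = {p: list(part.index[part == p]) for p in participants}
    truth: list[PlantedGene] = []

    def present(sid, gid, label):
        truth.append(PlantedGene(sid, gid, 1.0, identity, label))

    def absent(sid, gid):
        truth.append(PlantedGene(sid, gid, 0.0, identity, "absent"))

    idx = 0
    for gid in genes[:n_cohort_stable]:
        for sid in part.index:
            present(sid, gid, "cohort_stable")
    idx = n_cohort_stable
    for gid in genes[idx : idx + n_individual_stable]:
        k = rng.integers(1, max(len(participants), 2))
        carriers = set(rng.choice(participants, size=k, replace=False))
        # never all participants, else the gene would be cohort-stable
        if len(carriers) == len(participants):
            carriers.discard(sorted(carriers)[0])
        for p in participants:
            for sid in by_part[p]:
                if p in carriers:
                    present(sid, gid, "individual_stable")
                else:
                    absent(sid, gid)
    idx += n_individual_stable
    for gid in genes[idx : idx + n_transient]:
        p = participants[rng.integers(len(participants))]
        samples = by_part[p]
        k = rng.integers(1, len(samples))  # nonempty strict subset
        chosen = set(rng.choice(samples, size=k, replace=False))
        for sid in part.index:
            if sid in chosen:
                present(sid, gid, "transient")
            else:
                absent(sid, gid)
    for gid in genes[idx + n_transient :]:
        for sid in part.index:
            absent(sid, gid)
    return truth


def plant_presence(truth: list[PlantedGene]) -> pd.DataFrame:
    """Feature x sample boolean presence frame implied by planted truth."""
    recs = {}
    for rec in truth:
        recs.setdefault(rec.gene_id, {})[rec.sample_id] = (
            rec.label != "absent" and rec.coverage > 0
        )
    return pd.DataFrame(recs).T.fillna(False).astype(bool)


# ---------------------------------------------------------------------------
# sequence sets with exact containment


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_canonical_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    """Distinct canonical k-mers, deterministic in rng state."""
    out: dict[str, None] = {}
    comp_rev_axis = None
    while len(out) < n:
        m = max(int((n - len(out)) * 1.3), 1024)
        vals = rng.integers(0, 1 << (2 * k), size=m, dtype=np.uint64)
        shifts = (np.uint64(2) * np.arange(k, dtype=np.uint64))[np.newaxis, :]
        digits = ((vals[:, np.newaxis] >> shifts) & np.uint64(3)).astype(np.uint8)
        fwd = _DECODE[digits]
        rc = _DECODE[(3 - digits)[:, ::-1]]
        fwd_bytes = fwd.tobytes()
        rc_bytes = rc.tobytes()
        for i in range(m):
            f = fwd_bytes[i * k : (i + 1) * k]
            r = rc_bytes[i * k : (i + 1) * k]
            canon = (f if f <= r else r).decode("ascii")
            if canon not in out:
                out[canon] = None
                if len(out) == n:
                    break
    return list(out)


def simulate_sequence_sets(
    universe_size: int,
    containment: float,
    seed: int = 0,
    k: int = 31,
) -> tuple[set[str], set[str]]:
    """Two equal-size canonical k-mer sets with exact planted containment.

    Both sets have ``universe_size`` elements and share exactly
    ``round(containment * universe_size)`` of them, so the true
    containment |A∩B| / min(|A|,|B|) equals the target within
    1/universe_size.
    """
    if not (0.0 <= containment <= 1.0):
        raise ValueError("containment must lie in [0,1]")
    if universe_size < 1:
        raise ValueError("universe_size must be positive")
    n_shared = int(round(containment * universe_size))
    rng = np.random.default_rng(seed)
    total = 2 * universe_size - n_shared
    kmers = _random_canonical_kmers(rng, total, k)
    a = set(kmers[:universe_size])
    b = set(kmers[universe_size - n_shared :])
    return a, b
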