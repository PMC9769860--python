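"""Per-cohort taxonomic summaries.

Implements the cohort's community-level rules: alpha diversity
(richness, Shannon in nats, Pielou evenness), the core-taxon rule (a
taxon is core when it reaches the detection floor, 0.01% relative
abundance by default, in every sample), the disease-related-microorganism
(DRM) retention rule (>0.1% in at least one sample), and the
dominant-marker enterotype call (ET_P when Prevotella exceeds
Bacteroides, else ET_B).
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AbundanceTable

__all__ = [
    "diversity",
    "core_taxa",
    "drm_screen",
    "enterotype",
    "default_drm_list",
]

CORE_FLOOR_PCT = 0.01  # detection floor for the core rule, percent
DRM_RETENTION_PCT = 0.1  # strict > threshold for DRM retention, percent


def diversity(
    table: AbundanceTable, detection_floor: float = CORE_FLOOR_PCT, base: float = np.e
) -> pd.DataFrame:
    """Per-sample richness S, Shannon H and Pielou evenness J = H / log S.

    Taxa below ``detection_floor`` (percent) are treated as undetected;
    the remaining abundances are renormalized before H.  H is reported in
    the logarithm ``base`` (natural log by default).  J is missing when
    S <= 1; a sample with no detected taxa gets S = 0, H = 0, J missing.
    """
    rows = []
    for sid in table.sample_ids:
        x = table.data.loc[sid].to_numpy(dtype=float)
        detected = x[x >= detection_floor]
        s = int(detected.size)
        if s == 0:
            rows.append((sid, 0, 0.0, np.nan))
            continue
        p = detected / detected.sum()
        h = float(-(p * np.log(p)).sum() / np.log(base))
        j = h / (np.log(s) / np.log(base)) if s > 1 else np.nan
        rows.append((sid, s, h, j))
    return pd.DataFrame(rows, columns=["sample_id", "richness", "shannon", "pielou"]).set_index(
        "sample_id"
    )


def core_taxa(table: AbundanceTable, floor: float = CORE_FLOOR_PCT) -> pd.DataFrame:
    """Prevalence, mean abundance with 95% CI, core flag and CV per taxon.

    A taxon is core when its abundance reaches ``floor`` (percent,
    inclusive) in every sample.  The mean and normal-theory (t-based)
    95% CI are over all samples; the coefficient of variation is over
    positive samples only (those at or above the floor), where the
    fluctuation of an intermittent taxon is actually observed.
    """
    if len(table.sample_ids) < 2:
        raise ValueError("core_taxa requires at least 2 samples")
    if not table.taxon_ids:
        raise ValueError("empty abundance table")
    x = table.values
    n = x.shape[0]
    above = x >= floor
    prevalence = above.mean(axis=0)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    half = tcrit * sd / np.sqrt(n)
    cv = np.full(x.shape[1], np.nan)
    for j in range(x.shape[1]):
        pos = x[above[:, j], j]
        if pos.size >= 2 and pos.mean() > 0:
            cv[j] = pos.std(ddof=1) / pos.mean()
    return pd.DataFrame(
        {
            "prevalence": prevalence,
            "mean_pct": mean,
            "ci_lower": mean - half,
            "ci_upper": mean + half,
            "is_core": above.all(axis=0),
            "cv": cv,
        },
        index=pd.Index(table.taxon_ids, name="taxon"),
    )


def drm_screen(
    table: AbundanceTable,
    drm_list: list[str],
    retention: float = DRM_RETENTION_PCT,
    positivity: float | None = None,
) -> pd.DataFrame:
    """Screen a species-rank table against a pathogen watch list.

    A listed species is *retained* when its abundance strictly exceeds
    ``retention`` (percent) in at least one sample.  Per-sample positivity
    uses the same strict threshold unless ``positivity`` overrides it
    (e.g. 0 for any-nonzero detection); cohort prevalence is the percent
    of positive samples.  Species absent from the table count as absent
    everywhere.
    """
    if not drm_list:
        raise ValueError("empty DRM list")
    if positivity is None:
        positivity = retention
    n = len(table.sample_ids)
    rows = []
    pos_matrix = {}
    for species in drm_list:
        if species in table.data.columns:
            x = table.data[species].to_numpy(dtype=float)
        else:
            x = np.zeros(n)
        retained = bool((x > retention).any())
        positive = x > positivity
        pos_matrix[species] = positive
        rows.append((species, retained, int(positive.sum()), 100.0 * positive.mean()))
    result = pd.DataFrame(
        rows, columns=["species", "retained", "n_positive", "prevalence_pct"]
    ).set_index("species")
    result.attrs["positivity"] = pd.DataFrame(pos_matrix, index=table.sample_ids).T
    return result


def enterotype(
    table: AbundanceTable, markers: tuple[str, str] = ("Bacteroides", "Prevotella")
) -> pd.Series:
    """Dominant-marker enterotype per sample: ET_P iff Prevotella > Bacteroides.

    Ties (including both markers at zero when at least one is present in
    the table) resolve to ET_B.  Samples where both marker genera are
    absent from the table get a missing label with a warning.
    """
    bact, prev = markers
    have_b = bact in table.data.columns
    have_p = prev in table.data.columns
    if not have_b and not have_p:
        warnings.warn(f"neither marker genus ({bact!r}, {prev!r}) present; labels missing")
        return pd.Series(pd.NA, index=table.sample_ids, name="enterotype")
    b = table.data[bact] if have_b else pd.Series(0.0, index=table.data.index)
    p = table.data[prev] if have_p else pd.Series(0.0, index=table.data.index)
    labels = np.where(p > b, "ET_P", "ET_B")
    return pd.Series(labels, index=table.sample_ids, name="enterotype")


def default_drm_list() -> pd.DataFrame:
    """Packaged representative pathogen watch list (species, risk_group).

    A small synthetic stand-in for a full regulatory pathogen list;
    users substitute their own TSV with the same columns.
    """
    with resources.files("gutcohort").joinpath("data/drm_list.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
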