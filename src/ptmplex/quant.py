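"""Reporter-ion rollup and the site-abundance normalization chain.

The chain for PTM site data is, in order:

1. roll PSM intensities up to unique sites (raw sums; zeros are treated as
   non-detections and become missing),
2. log2 transform,
3. scale against the log2 *global peptide* data (not batch corrected) by
   subtracting each sample's global-column median — this removes TMT
   channel-loading offsets and median-centers in one step,
4. batch correction across plexes (per-feature batch-mean centering with
   grand-mean restoration),
5. subtraction of the per-condition mean normalized *protein* abundance, so
   what remains tracks site occupancy rather than protein expression.

Global protein data runs 1-2, then batch correction and median centering.
Each step tags the matrix; steps that depend on order assert it.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .design import PlexDesign
from .errors import StateError, ValidationError
from .ingest import (
    INTENSITY_PREFIX,
    PsmTable,
    SiteId,
    map_to_sites,
    parse_mods,
    validate_channels,
)
from .matrices import AbundanceMatrix

import warnings


# ---------------------------------------------------------------------------
# Rollup
# ---------------------------------------------------------------------------

def _melt_to_samples(psms: PsmTable, design: PlexDesign, feature: pd.Series) -> pd.DataFrame:
    """Long-format (feature, sample, intensity) with zeros treated as missing."""
    validate_channels(psms, design)
    df = psms.df.copy()
    df["__feature"] = feature.values
    long = df.melt(
        id_vars=["plex_id", "__feature"],
        value_vars=psms.intensity_columns(),
        var_name="channel_id",
        value_name="intensity",
    )
    long["channel_id"] = long["channel_id"].str[len(INTENSITY_PREFIX):]
    # zeros are non-detections in reporter-ion data
    long.loc[long["intensity"] <= 0, "intensity"] = np.nan
    dmap = design.table[["plex_id", "channel_id", "sample_id", "channel_role"]]
    long = long.merge(dmap, on=["plex_id", "channel_id"], how="left")
    long = long[long["channel_role"] != "empty"]
    return long


def _rollup(psms: PsmTable, design: PlexDesign, feature: pd.Series) -> AbundanceMatrix:
    long = _melt_to_samples(psms, design, feature)
    pivot = long.pivot_table(
        index="__feature",
        columns="sample_id",
        values="intensity",
        aggfunc=lambda v: v.sum(min_count=1),
        dropna=False,
    )
    # stable sample order from the design
    ordered = [s for s in design.samples["sample_id"] if s in pivot.columns]
    pivot = pivot.reindex(columns=ordered)
    pivot.index.name = "feature_id"
    pivot.columns.name = None
    return AbundanceMatrix(pivot, scale="raw", modality=psms.modality, tags=["rollup"])


def rollup_protein(psms: PsmTable, design: PlexDesign) -> AbundanceMatrix:
    """Sum raw reporter intensities over each protein's PSMs, per sample."""
    return _rollup(psms, design, psms.df["protein_accession"].astype(str))


def rollup_peptide(psms: PsmTable, design: PlexDesign) -> AbundanceMatrix:
    """Sum raw reporter intensities per (peptide, mods) feature, per sample.

    This is the "global peptide data" used to scale PTM site abundances for
    channel loading.
    """
    key = psms.df["peptide"].astype(str) + "|" + psms.df["mods"].fillna("").astype(str)
    return _rollup(psms, design, key)


def rollup_site(
    psms: PsmTable, design: PlexDesign, target_mod: str, fasta: Mapping[str, str]
) -> AbundanceMatrix:
    """Sum raw reporter intensities per unique modified site, per sample.

    Multiply-modified peptides roll up under one composite site key covering
    all of their ``target_mod`` positions.  PSMs without the target
    modification (enrichment contaminants) carry no site and are dropped;
    the count is recorded in ``notes["n_without_target_mod"]``.
    """
    keys = []
    mask = []
    for _, row in psms.df.iterrows():
        has_mod = any(
            name == target_mod and pos != "nt" for name, pos in parse_mods(row["mods"])
        )
        mask.append(has_mod)
        keys.append(str(map_to_sites(row, fasta, target_mod)) if has_mod else "")
    mask = pd.Series(mask, index=psms.df.index)
    on_target = PsmTable(psms.df[mask.values].reset_index(drop=True), modality=psms.modality)
    site_keys = pd.Series([k for k, m in zip(keys, mask) if m])
    m = _rollup(on_target, design, site_keys)
    m.notes["n_without_target_mod"] = int((~mask).sum())
    return m


def site_parent_map(site_ids) -> dict[str, str]:
    """Map site-key strings back to their parent protein accession."""
    return {s: s.rsplit("-", 1)[0] for s in site_ids}


# ---------------------------------------------------------------------------
# Normalization chain
# ---------------------------------------------------------------------------

def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2 of raw intensities; zeros and missing stay missing."""
    m.require_scale("raw")
    with np.errstate(divide="ignore", invalid="ignore"):
        data = np.log2(m.data.where(m.data > 0))
    return m.tagged("log2", data=data, scale="log2")


def median_center(m: AbundanceMatrix) -> AbundanceMatrix:
    """Subtract each sample column's non-missing median."""
    m.require_scale("log2")
    medians = m.data.median(axis=0, skipna=True)
    all_missing = medians.isna()
    if all_missing.any():
        warnings.warn(
            f"column(s) entirely missing, left untouched: {list(medians.index[all_missing])}"
        )
        medians = medians.fillna(0.0)
    return m.tagged("median-centered", data=m.data.sub(medians, axis=1))


def batch_correct(m: AbundanceMatrix, design: PlexDesign) -> AbundanceMatrix:
    """Per-feature batch-mean centering with grand-mean restoration.

    Within-batch sample differences are preserved exactly.  Features observed
    in only one batch pass through unchanged and are recorded in
    ``notes["single_batch_features"]``.
    """
    m.require_scale("log2")
    batch_of = design.batch_map()
    batches = pd.Series({s: batch_of.get(s) for s in m.samples})
    if batches.isna().any():
        raise ValidationError(
            f"sample(s) not in design: {list(batches.index[batches.isna()])}"
        )
    if batches.nunique() < 2:
        warnings.warn("single batch in matrix; batch correction is a no-op")
        return m.tagged("batch-corrected")

    data = m.data.copy()
    values = data.to_numpy(dtype=float)
    batch_labels = batches.to_numpy()
    uniq = pd.unique(batch_labels)
    grand = np.nanmean(values, axis=1)
    observed_batches = np.zeros(len(data), dtype=int)
    adjusted = values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        batch_means = {b: np.nanmean(values[:, batch_labels == b], axis=1) for b in uniq}
    for b in uniq:
        observed_batches += (~np.isnan(batch_means[b])).astype(int)
    single = observed_batches <= 1
    for b in uniq:
        cols = batch_labels == b
        shift = batch_means[b] - grand
        shift = np.where(np.isnan(shift) | single, 0.0, shift)
        adjusted[:, cols] = values[:, cols] - shift[:, None]
    out = pd.DataFrame(adjusted, index=data.index, columns=data.columns)
    return m.tagged(
        "batch-corrected",
        data=out,
        notes={"single_batch_features": list(data.index[single])},
    )


def scale_ptm_to_global(
    site_m: AbundanceMatrix, global_peptide_m: AbundanceMatrix
) -> AbundanceMatrix:
    """Subtract the global peptide column medians from the site columns.

    The global peptide matrix must be log2 but NOT batch corrected: its
    per-sample medians estimate the TMT channel-loading offsets, and
    subtracting them both corrects loading and median-centers the site data.
    Site samples without a matching global sample pass through untouched and
    are recorded as unscaled.
    """
    site_m.require_scale("log2")
    global_peptide_m.require_scale("log2")
    if "batch-corrected" in global_peptide_m.tags:
        raise StateError("global peptide matrix must not be batch corrected before scaling")
    medians = global_peptide_m.data.median(axis=0, skipna=True)
    shared = [s for s in site_m.samples if s in medians.index and not np.isnan(medians[s])]
    unscaled = [s for s in site_m.samples if s not in shared]
    data = site_m.data.copy()
    data[shared] = data[shared].sub(medians[shared], axis=1)
    if unscaled:
        warnings.warn(f"sample(s) without global data left unscaled: {unscaled}")
    return site_m.tagged("global-scaled", data=data, notes={"unscaled_samples": unscaled})


def correct_for_protein(
    site_m: AbundanceMatrix,
    protein_m: AbundanceMatrix,
    condition_map: Mapping[str, str],
    site_to_protein: Mapping[str, str] | None = None,
    min_replicates: int = 2,
) -> AbundanceMatrix:
    """Subtract per-condition mean normalized protein abundance from site values.

    ``condition_map`` assigns each sample to a condition.  Protein condition
    means use non-missing replicates only; a (site, condition) cell whose
    protein has fewer than ``min_replicates`` non-missing values in that
    condition — or whose protein is absent from the global data — passes
    through uncorrected and is recorded in ``notes["uncorrected"]``.
    """
    site_m.require_tags(["log2", "global-scaled", "batch-corrected"])
    protein_m.require_scale("log2")
    if site_to_protein is None:
        site_to_protein = site_parent_map(site_m.features)

    cond = pd.Series({s: condition_map.get(s) for s in site_m.samples})
    if cond.isna().any():
        raise ValidationError(f"sample(s) without condition: {list(cond.index[cond.isna()])}")

    # per-protein, per-condition means over non-missing replicates
    shared_cols = [s for s in protein_m.samples if s in condition_map]
    pm = protein_m.data[shared_cols]
    groups = pd.Series({s: condition_map[s] for s in shared_cols})
    means = pm.T.groupby(groups).mean()      # condition x protein
    counts = pm.T.groupby(groups).count()    # non-missing replicate counts

    data = site_m.data.copy()
    uncorrected: list[tuple[str, str]] = []
    parents = pd.Series({s: site_to_protein.get(s) for s in data.index})
    for condition in cond.unique():
        cols = cond.index[cond == condition]
        if condition in means.index:
            cmeans = parents.map(means.loc[condition])
            enough = parents.map(counts.loc[condition]).fillna(0) >= min_replicates
            shift = cmeans.where(enough)
        else:
            shift = pd.Series(np.nan, index=data.index)
        data[cols] = data[cols].sub(shift.fillna(0.0), axis=0)
        uncorrected.extend((site, condition) for site in data.index[shift.isna()])
    return site_m.tagged("protein-corrected", data=data, notes={"uncorrected": uncorrected})


# ---------------------------------------------------------------------------
# Missing-value filter
# ---------------------------------------------------------------------------

class MissingFilterResult(NamedTuple):
    matrix: AbundanceMatrix
    dropped: list


def filter_missing(
    m: AbundanceMatrix,
    condition_map: Mapping[str, str],
    max_na_per_condition: int = 2,
) -> MissingFilterResult:
    """Drop features with more than ``max_na_per_condition`` missing values
    in any single condition."""
    cond = pd.Series({s: condition_map.get(s) for s in m.samples})
    if cond.isna().any():
        raise ValidationError(f"sample(s) without condition: {list(cond.index[cond.isna()])}")
    sizes = cond.value_counts()
    small = sizes[sizes < max_na_per_condition + 1]
    if len(small):
        warnings.warn(
            f"condition(s) with <= {max_na_per_condition} replicates can never "
            f"trigger the NA rule: {list(small.index)}"
        )
    na_counts = m.data.isna().T.groupby(cond).sum().T  # feature x condition
    drop = (na_counts > max_na_per_condition).any(axis=1)
    kept = m.tagged("na-filtered", data=m.data[~drop])
    return MissingFilterResult(kept, list(m.data.index[drop]))
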