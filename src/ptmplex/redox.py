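"""Cysteine thiol-oxidation stoichiometry.

Oxidation samples have free thiols blocked with NEM before enrichment, so
their reporter intensities reflect only reversibly oxidized cysteines;
total-thiol samples skip the blocking and report reduced + oxidized thiols
combined.  The mean % oxidation of a site is the ratio of the average
(normalized) oxidation-channel intensity to the average total-thiol
intensity, times 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PlexDesign
from .errors import UndefinedResultError, ValidationError
from .matrices import AbundanceMatrix


@dataclass
class StoichiometryTable:
    """Per (site, condition) mean % cysteine thiol oxidation."""

    table: pd.DataFrame  # columns: site, condition, mean_percent_oxidation,
    #                                n_oxidation_channels, n_total_channels, over_range
    n_skipped: int = 0  # sites with no usable total-thiol signal

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def channel_loading_factors(global_m: AbundanceMatrix) -> pd.Series:
    """Linear per-sample loading factors from log2 global (unenriched) data.

    The per-sample median of the global data estimates the TMT channel
    loading on the log2 scale; factors are centered so their geometric mean
    is 1.  Dividing raw reporter intensities by these factors removes
    loading differences between channels *without* equalizing the
    systematic oxidation/total-thiol intensity gap — which is the signal.
    """
    global_m.require_scale("log2")
    med = global_m.data.median(axis=0, skipna=True)
    if med.isna().any():
        raise UndefinedResultError(
            f"global column(s) entirely missing: {list(med.index[med.isna()])}"
        )
    return 2.0 ** (med - med.mean())


def percent_oxidation(
    site_m: AbundanceMatrix,
    design: PlexDesign,
    loading_factors: pd.Series | None = None,
    clip: bool = False,
) -> StoichiometryTable:
    """Mean % cysteine thiol oxidation per site and condition.

    Per condition: 100 x mean(normalized oxidation-channel intensities) /
    mean(normalized total-thiol intensities).  Normalization divides each
    channel by its loading factor (see :func:`channel_loading_factors`),
    which cancels loading differences between +NEM and -NEM samples; when
    ``loading_factors`` is None the raw ratio is used.  Values above 100%
    are flagged (``over_range``) rather than clipped unless ``clip=True``.
    Sites with no total-thiol signal in a condition are skipped and counted.
    """
    site_m.require_scale("raw")
    roles = design.role_map()
    conditions = design.condition_map()
    ox_cols = [s for s in site_m.samples if roles.get(s) == "oxidation"]
    tot_cols = [s for s in site_m.samples if roles.get(s) == "total_thiol"]
    if not ox_cols or not tot_cols:
        raise ValidationError("design must provide >=1 oxidation and >=1 total_thiol channel")

    data = site_m.data[ox_cols + tot_cols].astype(float)
    if loading_factors is not None:
        factors = loading_factors.reindex(data.columns).fillna(1.0)
        if (factors <= 0).any():
            raise ValidationError("loading factors must be positive")
        data = data.div(factors, axis=1)

    rows = []
    n_skipped = 0
    ox_cond = {s: conditions[s] for s in ox_cols}
    for condition in dict.fromkeys(ox_cond.values()):
        cond_ox = [s for s in ox_cols if ox_cond[s] == condition]
        # total-thiol singlets may be shared across conditions; prefer
        # condition-matched totals, fall back to all total channels
        cond_tot = [s for s in tot_cols if conditions[s] == condition] or tot_cols
        for site in data.index:
            ox = data.loc[site, cond_ox].dropna()
            tot = data.loc[site, cond_tot].dropna()
            if tot.empty or tot.mean() <= 0:
                n_skipped += 1
                continue
            if ox.empty:
                continue
            pct = 100.0 * ox.mean() / tot.mean()
            over = pct > 100.0
            if clip and over:
                pct = 100.0
            rows.append(
                {
                    "site": site,
                    "condition": condition,
                    "mean_percent_oxidation": pct,
                    "n_oxidation_channels": len(ox),
                    "n_total_channels": len(tot),
                    "over_range": bool(over and not clip),
                }
            )
    return StoichiometryTable(pd.DataFrame(rows), n_skipped=n_skipped)


def oxidation_distribution(st: StoichiometryTable, bin_width: float = 5.0) -> dict:
    """Deciles and fixed-width histogram of % oxidation values.

    Histogram bins cover [0, 100] in ``bin_width`` steps; over-range values
    (> 100%) pool into a terminal overflow bin.
    """
    if len(st.table) == 0:
        raise UndefinedResultError("empty stoichiometry table")
    values = st.table["mean_percent_oxidation"].to_numpy(dtype=float)
    deciles = {f"q{10 * i}": float(np.percentile(values, 10 * i)) for i in range(11)}
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    in_range = values[values <= 100.0]
    counts, _ = np.histogram(in_range, bins=edges)
    return {
        "deciles": deciles,
        "bin_edges": edges.tolist(),
        "bin_counts": counts.tolist(),
        "over_range_count": int((values > 100.0).sum()),
        "n": len(values),
    }
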