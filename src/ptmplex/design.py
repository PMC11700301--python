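"""Plex design: the map from (plex, channel) to sample metadata.

A TMT experiment is described by one row per reporter channel per plex.
Channels carry a role: ``oxidation`` (+NEM thiol-oxidation samples, which
are also the quantitative samples for global/phospho/acetyl data),
``total_thiol`` (-NEM samples used as the denominator of the oxidation
stoichiometry), ``standard`` (plain quantitative samples in designs without
a redox arm), or ``empty`` (skipped channels left unlabeled to limit
isotope-impurity bleed-through into low-intensity neighbors).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import FormatError, ValidationError

REQUIRED_COLUMNS = (
    "plex_id",
    "channel_id",
    "sample_id",
    "condition",
    "timepoint",
    "replicate",
    "channel_role",
    "batch",
)

ROLES = ("oxidation", "total_thiol", "standard", "empty")
#: roles whose channels carry quantitative sample measurements
SAMPLE_ROLES = ("oxidation", "total_thiol", "standard")


@dataclass
class PlexDesign:
    """Validated plex design table (one row per plex x channel)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"plex design missing required column(s): {', '.join(missing)}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].fillna("").astype(str)
        dup = df.duplicated(subset=["plex_id", "channel_id"], keep=False)
        if dup.any():
            offenders = df.loc[dup, ["plex_id", "channel_id"]].drop_duplicates()
            pairs = ", ".join(f"({r.plex_id}, {r.channel_id})" for r in offenders.itertuples())
            raise ValidationError(f"duplicate (plex, channel) pairs in design: {pairs}")
        bad_role = ~df["channel_role"].isin(ROLES)
        if bad_role.any():
            raise ValidationError(
                f"unknown channel_role value(s): {sorted(df.loc[bad_role, 'channel_role'].unique())}"
            )
        empties = df["channel_role"] == "empty"
        if (df.loc[empties, "sample_id"] != "").any():
            raise ValidationError("empty channels must not carry a sample_id")
        if (df.loc[~empties, "sample_id"] == "").any():
            raise ValidationError("non-empty channels must carry a sample_id")
        dup_samples = df.loc[~empties, "sample_id"].duplicated(keep=False)
        if dup_samples.any():
            raise ValidationError(
                f"sample_id values reused across channels: "
                f"{sorted(df.loc[~empties].loc[dup_samples, 'sample_id'].unique())}"
            )
        n_batches = df.groupby("plex_id")["batch"].nunique()
        if (n_batches > 1).any():
            raise ValidationError(
                f"each plex must map to exactly one batch; offending plex(es): "
                f"{sorted(n_batches[n_batches > 1].index)}"
            )
        self.table = df.reset_index(drop=True)

    # -- lookups -----------------------------------------------------------
    @property
    def samples(self) -> pd.DataFrame:
        """Rows for non-empty channels."""
        return self.table[self.table["channel_role"] != "empty"]

    def channels(self, plex_id: str) -> list[str]:
        return list(self.table.loc[self.table["plex_id"] == plex_id, "channel_id"])

    def sample_for(self, plex_id: str, channel_id: str) -> str | None:
        row = self.table[
            (self.table["plex_id"] == plex_id) & (self.table["channel_id"] == channel_id)
        ]
        if row.empty:
            return None
        sid = row["sample_id"].iloc[0]
        return sid or None

    def batch_map(self) -> dict[str, str]:
        """sample_id -> batch."""
        s = self.samples
        return dict(zip(s["sample_id"], s["batch"]))

    def condition_map(self) -> dict[str, str]:
        """sample_id -> condition label ("<condition> <timepoint>")."""
        s = self.samples
        return {
            sid: f"{cond} {tp}"
            for sid, cond, tp in zip(s["sample_id"], s["condition"], s["timepoint"])
        }

    def role_map(self) -> dict[str, str]:
        s = self.samples
        return dict(zip(s["sample_id"], s["channel_role"]))

    def plex_batches(self) -> dict[str, str]:
        """plex_id -> batch."""
        return dict(self.table.groupby("plex_id")["batch"].first())

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_plex_design(path) -> PlexDesign:
    """Read and validate a tab-separated plex design file."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot parse plex design {path}: {exc}") from exc
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").fillna(0).astype(int)
    df["sample_id"] = df.get("sample_id", pd.Series(dtype=str)).replace({"": ""})
    return PlexDesign(df)
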