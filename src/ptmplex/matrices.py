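"""Feature x sample abundance matrices with processing-state tracking.

The matrix remembers the ordered list of processing steps applied to it
(``tags``), which lets downstream operations assert that the normalization
chain was run in the documented order instead of silently accepting a
half-normalized input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import StateError, ValidationError

MODALITIES = ("global", "redox", "phospho", "acetyl")


@dataclass
class AbundanceMatrix:
    """Features (proteins, peptides or PTM sites) x samples.

    ``data`` holds raw intensities (>= 0, NaN = missing) or log2 intensities
    depending on ``scale``.  ``tags`` is the ordered list of processing steps
    already applied.
    """

    data: pd.DataFrame
    scale: str = "raw"  # "raw" | "log2"
    modality: str = "global"
    tags: list[str] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.scale == "raw" and (self.data < 0).any().any():
            raise ValidationError("raw intensities must be >= 0")

    # -- state bookkeeping -------------------------------------------------
    def tagged(self, *new_tags: str, **updates) -> "AbundanceMatrix":
        """Copy with additional processing tags (and optional field updates)."""
        return AbundanceMatrix(
            data=updates.pop("data", self.data).copy(),
            scale=updates.pop("scale", self.scale),
            modality=self.modality,
            tags=[*self.tags, *new_tags],
            notes={**self.notes, **updates.pop("notes", {})},
        )

    def require_tags(self, ordered: list[str]) -> None:
        """Assert that ``ordered`` appears as a subsequence of ``self.tags``."""
        it = iter(self.tags)
        for want in ordered:
            if not any(tag == want for tag in it):
                raise StateError(
                    f"matrix processing order violated: need {ordered}, have {self.tags}"
                )

    def require_scale(self, scale: str) -> None:
        if self.scale != scale:
            raise StateError(f"operation requires {scale}-scale matrix, got {self.scale}")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    # -- I/O ---------------------------------------------------------------
    def write(self, path) -> None:
        """Write as TSV plus a YAML sidecar recording scale/modality/tags."""
        path = Path(path)
        self.data.to_csv(path, sep="\t", index_label="feature_id")
        sidecar = path.with_suffix(path.suffix + ".meta.yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump(
                {"scale": self.scale, "modality": self.modality, "tags": self.tags},
                fh,
                sort_keys=False,
            )

    @classmethod
    def read(cls, path) -> "AbundanceMatrix":
        path = Path(path)
        data = pd.read_csv(path, sep="\t", index_col="feature_id")
        sidecar = path.with_suffix(path.suffix + ".meta.yaml")
        meta = {}
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh) or {}
        return cls(
            data=data,
            scale=meta.get("scale", "raw"),
            modality=meta.get("modality", "global"),
            tags=list(meta.get("tags", [])),
        )
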