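"""PSM-table ingestion: parsing, quality filtering, site mapping, search QC.

PSM tables are tab-separated with one row per peptide-spectrum match and one
``intensity_<channel>`` column per reporter channel.  Modifications are
encoded as a ``;``-separated list of ``name@pos`` tokens where ``pos`` is the
zero-based position within the bare peptide sequence and ``nt`` denotes the
peptide N-terminus, e.g. ``nem@1;phospho@4;tmt@nt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from pyteomics import fasta as _pyt_fasta

from .errors import FormatError, MappingError, UndefinedResultError, ValidationError
from .design import PlexDesign

INTENSITY_PREFIX = "intensity_"

REQUIRED_PSM_COLUMNS = (
    "psm_id",
    "plex_id",
    "peptide",
    "mods",
    "protein_accession",
    "peptide_start",
    "mass_error_ppm",
    "pepq",
)


def parse_mods(spec: str) -> list[tuple[str, int | str]]:
    """Parse a ``name@pos`` list; positions are ints or the string ``"nt"``."""
    if not spec or (isinstance(spec, float) and np.isnan(spec)):
        return []
    out: list[tuple[str, int | str]] = []
    for token in str(spec).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            name, pos = token.split("@")
        except ValueError:
            raise FormatError(f"bad modification token {token!r} (expected name@pos)") from None
        out.append((name, "nt" if pos == "nt" else int(pos)))
    return out


def format_mods(mods: Iterable[tuple[str, int | str]]) -> str:
    return ";".join(f"{name}@{pos}" for name, pos in mods)


@dataclass
class PsmTable:
    """PSM records for one quantification modality (global/redox/phospho/acetyl)."""

    df: pd.DataFrame
    modality: str = "global"

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_PSM_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"PSM table missing required column(s): {', '.join(missing)}")
        for _, row in self.df.iterrows():
            for name, pos in parse_mods(row["mods"]):
                if pos != "nt" and not (0 <= pos < len(row["peptide"])):
                    raise ValidationError(
                        f"PSM {row['psm_id']}: mod {name}@{pos} outside peptide "
                        f"of length {len(row['peptide'])}"
                    )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def channels(self) -> list[str]:
        return [
            c[len(INTENSITY_PREFIX):] for c in self.df.columns if c.startswith(INTENSITY_PREFIX)
        ]

    def intensity_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(INTENSITY_PREFIX)]

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_psm_table(path, modality: str = "global") -> PsmTable:
    df = pd.read_csv(path, sep="\t")
    df["mods"] = df["mods"].fillna("")
    return PsmTable(df, modality=modality)


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences into an accession -> sequence mapping.

    The accession is the first whitespace-delimited token of the header; a
    UniProt-style ``db|ACC|NAME`` header is reduced to ``ACC``.
    """
    seqs: dict[str, str] = {}
    with _pyt_fasta.read(str(path)) as reader:
        for header, seq in reader:
            acc = header.split()[0]
            if acc.count("|") == 2:
                acc = acc.split("|")[1]
            seqs[acc] = seq.upper()
    return seqs


# ---------------------------------------------------------------------------
# PSM quality filtering
# ---------------------------------------------------------------------------

class FilterResult(NamedTuple):
    psms: "PsmTable"
    n_removed: int


def filter_psms(psms: PsmTable, max_ppm: float = 10.0, max_pepq: float = 0.01) -> FilterResult:
    """Keep PSMs with |mass error| <= ``max_ppm`` ppm AND PepQ < ``max_pepq``.

    The ppm bound is inclusive and the PepQ bound strict.  Row order is
    preserved; the number of removed records is returned alongside.
    """
    df = psms.df
    keep = (df["mass_error_ppm"].abs() <= max_ppm) & (df["pepq"] < max_pepq)
    kept = df[keep].reset_index(drop=True)
    return FilterResult(PsmTable(kept, modality=psms.modality), int((~keep).sum()))


# ---------------------------------------------------------------------------
# Site mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteId:
    """A modified-site key: accession plus 1-based protein positions.

    Peptides carrying several target modifications yield one composite key
    over all modified positions (sorted ascending), mirroring unique-site
    aggregation where multiply-modified peptides are distinct features.
    """

    accession: str
    sites: tuple[tuple[str, int], ...]  # ((residue letter, 1-based position), ...)

    def __post_init__(self) -> None:
        positions = [p for _, p in self.sites]
        if positions != sorted(positions):
            object.__setattr__(self, "sites", tuple(sorted(self.sites, key=lambda s: s[1])))

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for _, p in self.sites)

    def __str__(self) -> str:
        return f"{self.accession}-" + "".join(f"{letter}{pos}" for letter, pos in self.sites)


def map_to_sites(psm_row, fasta: dict[str, str], target_mod: str) -> SiteId:
    """Map a PSM's ``target_mod`` positions to 1-based protein coordinates.

    ``psm_row`` is a mapping with at least peptide, mods, protein_accession
    and peptide_start (1-based start of the peptide in the protein).  Raises
    :class:`MappingError` when the peptide does not match the FASTA sequence
    at the declared start, and :class:`ValidationError` when the peptide has
    no ``target_mod``.
    """
    acc = psm_row["protein_accession"]
    peptide = psm_row["peptide"]
    start = int(psm_row["peptide_start"])
    if acc not in fasta:
        raise MappingError(f"accession {acc!r} not in FASTA")
    seq = fasta[acc]
    if seq[start - 1 : start - 1 + len(peptide)] != peptide:
        raise MappingError(
            f"peptide {peptide!r} does not match {acc} at position {start}"
        )
    mods = psm_row["mods"]
    if isinstance(mods, str):
        mods = parse_mods(mods)
    sites = []
    for name, pos in mods:
        if name != target_mod or pos == "nt":
            continue
        prot_pos = start + int(pos)  # 1-based protein coordinate
        letter = seq[prot_pos - 1]
        if letter != peptide[int(pos)]:  # defensive; implied by the subsequence check
            raise MappingError(f"{acc}: residue mismatch at {prot_pos}")
        sites.append((letter, prot_pos))
    if not sites:
        raise ValidationError(
            f"PSM {psm_row.get('psm_id', '?')} carries no {target_mod!r} modification"
        )
    return SiteId(acc, tuple(sites))


# ---------------------------------------------------------------------------
# Search-level QC metrics
# ---------------------------------------------------------------------------

def labeling_efficiency(psms: PsmTable, label_mod: str = "tmt") -> float:
    """Fraction of labelable positions (K residues and N-termini) carrying the label.

    Requires the search to have treated the label as a *dynamic* modification
    so unlabeled positions are observable.
    """
    labelable = 0
    labeled = 0
    for _, row in psms.df.iterrows():
        peptide = row["peptide"]
        mods = parse_mods(row["mods"])
        k_positions = {i for i, aa in enumerate(peptide) if aa == "K"}
        labelable += 1 + len(k_positions)  # N-terminus + lysines
        for name, pos in mods:
            if name != label_mod:
                continue
            if pos == "nt" or pos in k_positions:
                labeled += 1
    if labelable == 0:
        raise UndefinedResultError("no labelable positions in PSM table")
    return labeled / labelable


def enrichment_selectivity(
    psms: PsmTable,
    target_mod: str | None = None,
    target_residue: str | None = None,
    unit: str = "peptide",
) -> float:
    """Fraction of identifications bearing the enrichment target.

    The target is either a modification name (``target_mod``, e.g.
    ``"phospho"``) or a residue letter (``target_residue``, e.g. ``"C"`` for
    thiol-affinity capture, where any cysteine peptide is on-target).  The
    denominator is unique peptides by default (``unit="peptide"``) or PSMs
    (``unit="psm"``).
    """
    if (target_mod is None) == (target_residue is None):
        raise ValidationError("specify exactly one of target_mod / target_residue")
    if len(psms.df) == 0:
        raise UndefinedResultError("empty PSM table")

    def on_target(peptide: str, mods: str) -> bool:
        if target_residue is not None:
            return target_residue in peptide
        return any(name == target_mod for name, _ in parse_mods(mods))

    df = psms.df
    if unit == "peptide":
        seen: dict[str, bool] = {}
        for _, row in df.iterrows():
            key = f"{row['peptide']}|{row['mods']}"
            if key not in seen:
                seen[key] = on_target(row["peptide"], row["mods"])
        return sum(seen.values()) / len(seen)
    if unit == "psm":
        hits = sum(on_target(r["peptide"], r["mods"]) for _, r in df.iterrows())
        return hits / len(df)
    raise ValidationError(f"unknown unit {unit!r} (expected 'peptide' or 'psm')")


def validate_channels(psms: PsmTable, design: PlexDesign) -> None:
    """Ensure every intensity channel in the PSM table exists in the design."""
    by_plex = {p: set(design.channels(p)) for p in design.table["plex_id"].unique()}
    psm_channels = set(psms.channels)
    for plex in psms.df["plex_id"].unique():
        if plex not in by_plex:
            raise ValidationError(f"plex {plex!r} present in PSMs but absent from design")
        extra = psm_channels - by_plex[plex]
        if extra:
            raise ValidationError(
                f"channel(s) {sorted(extra)} present in PSMs but absent from design plex {plex!r}"
            )
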