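"""Ground-truth-parameterized simulation of multiplexed multi-PTM datasets.

The generator emulates the statistical structure of a two-plex TMT18
time-course: per-condition protein abundances, PTM site occupancies,
per-site oxidation stoichiometries, per-channel loading factors, per-plex
batch offsets, multiplicative log-normal measurement noise, and
missing-at-random dropout.  The default design mirrors a cytokine
time-course: {Control, Cytokine} x {4, 8, 24 h} with quadruplicate
oxidation (+NEM) channels split across two plexes, one total-thiol (-NEM)
singlet per condition, and three empty channels per plex.

The raw reporter intensity of feature *f* in channel *c* of plex *b* is

    2 ** (baseline_f + protein_effect + occupancy_effect
          + peptide_offset + lambda_c + delta_b + eps),   eps ~ N(0, sigma^2)

independently per (feature, channel).  Redox oxidation channels scale the
total-thiol level by the site's per-condition stoichiometry s/100.  All
randomness flows from a single seed through per-modality child streams, so
adding one modality does not perturb the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .design import PlexDesign
from .errors import ConfigurationError, ValidationError
from .ingest import PsmTable, format_mods
from .matrices import AbundanceMatrix
from .structure import build_structure

TMT18_CHANNELS = [
    "126C", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C",
    "131N", "131C", "132N", "132C", "133N", "133C", "134N", "134C", "135N",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_MODALITY_STREAM = {"proteins": 0, "redox": 1, "phospho": 2, "acetyl": 3, "global": 4}
_SITE_MODS = {"redox": "nem", "phospho": "phospho", "acetyl": "acetyl"}
_SITE_RESIDUES = {"redox": ("C",), "phospho": ("S", "T", "Y"), "acetyl": ("K",)}


@dataclass
class SimulationConfig:
    """Study conditions for the simulator (defaults mirror the time-course design)."""

    n_proteins: int = 200
    n_sites: dict = field(
        default_factory=lambda: {"redox": 300, "phospho": 300, "acetyl": 100}
    )
    conditions: tuple = ("Control", "Cytokine")
    timepoints: tuple = ("4 h", "8 h", "24 h")
    n_replicates: int = 4
    n_plexes: int = 2
    affected_fraction: float = 0.2
    protein_effect_size: float = 1.0
    occupancy_effect_size: float = 1.0
    sigma: float = 0.25           # log2-scale multiplicative noise SD
    dropout: float = 0.1          # missing-at-random rate
    loading_sd: float = 0.3       # per-channel loading factors (log2)
    batch_sd: float = 0.5         # per-plex batch offsets (log2)
    baseline_mean: float = 17.0   # log2 reporter intensity scale
    baseline_sd: float = 1.5
    mean_peptides_per_protein: float = 2.0
    peptide_offset_sd: float = 1.0
    tmt_labeling_rate: float = 0.993
    selectivity: dict = field(
        default_factory=lambda: {"redox": 0.914, "phospho": 0.868, "acetyl": 0.95}
    )
    qc_fail_fraction: float = 0.0  # PSMs injected to fail the ppm/PepQ filter
    mass_error_sd: float = 2.0

    @property
    def condition_labels(self) -> list[str]:
        return [f"{c} {t}" for c in self.conditions for t in self.timepoints]

    def validate(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must be in [0, 1)")
        if not 0 <= self.affected_fraction <= 1:
            raise ConfigurationError("affected_fraction must be in [0, 1]")
        n_needed = len(self.condition_labels) * self.n_replicates + len(self.condition_labels)
        capacity = self.n_plexes * len(TMT18_CHANNELS)
        if n_needed > capacity:
            raise ConfigurationError(
                f"design needs {n_needed} channels but {self.n_plexes} plex(es) "
                f"provide only {capacity}"
            )
        if self.n_replicates % self.n_plexes:
            raise ConfigurationError("replicates must split evenly across plexes")


@dataclass
class SyntheticTruth:
    """Everything the simulator knows: the injected parameters per feature."""

    config: SimulationConfig
    seed: int
    proteins: pd.DataFrame       # accession, sequence, baseline; fc[<condition>] cols
    sites: dict                  # modality -> DataFrame(site, accession, letter, position,
    #                              offset, stoich (redox only); fc[<condition>] cols)
    channel_loadings: pd.DataFrame  # plex_id, channel_id, loading
    batch_offsets: dict          # plex_id -> delta (log2)

    def protein_fc(self, condition: str) -> pd.Series:
        return self.proteins.set_index("accession")[f"fc[{condition}]"]

    def site_fc(self, modality: str, condition: str) -> pd.Series:
        return self.sites[modality].set_index("site")[f"fc[{condition}]"]

    def stoichiometry(self, condition: str) -> pd.Series:
        """Per-condition % oxidation of redox sites."""
        df = self.sites["redox"].set_index("site")
        s = df["stoich"] * 2.0 ** df[f"fc[{condition}]"]
        return s.clip(upper=100.0)


def default_design(config: SimulationConfig | None = None) -> PlexDesign:
    """The standard two-plex TMT18 layout for the simulated time-course."""
    config = config or SimulationConfig()
    config.validate()
    rows = []
    labels = config.condition_labels
    reps_per_plex = config.n_replicates // config.n_plexes
    per_plex_totals = -(-len(labels) // config.n_plexes)  # ceil split of singlets
    for p in range(config.n_plexes):
        plex = f"P{p + 1}"
        channel_iter = iter(TMT18_CHANNELS)
        for cond in config.conditions:
            for tp in config.timepoints:
                for r in range(reps_per_plex):
                    rep = p * reps_per_plex + r + 1
                    rows.append(
                        {
                            "plex_id": plex,
                            "channel_id": next(channel_iter),
                            "sample_id": f"{cond[:3]}_{tp.replace(' ', '')}_r{rep}",
                            "condition": cond,
                            "timepoint": tp,
                            "replicate": rep,
                            "channel_role": "oxidation",
                            "batch": plex,
                        }
                    )
        for label in labels[p * per_plex_totals : (p + 1) * per_plex_totals]:
            cond, tp = label.split(" ", 1)
            rows.append(
                {
                    "plex_id": plex,
                    "channel_id": next(channel_iter),
                    "sample_id": f"Tot_{cond[:3]}_{tp.replace(' ', '')}",
                    "condition": cond,
                    "timepoint": tp,
                    "replicate": 1,
                    "channel_role": "total_thiol",
                    "batch": plex,
                }
            )
        for ch in channel_iter:
            rows.append(
                {
                    "plex_id": plex,
                    "channel_id": ch,
                    "sample_id": "",
                    "condition": "",
                    "timepoint": "",
                    "replicate": 0,
                    "channel_role": "empty",
                    "batch": plex,
                }
            )
    return PlexDesign(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def _effect_columns(rng, n, labels, affected_fraction, effect_size, reference_condition):
    """Per-condition effect columns.

    The first ``round(affected_fraction * n)`` features are affected (a
    deterministic count) and carry a random-sign effect in every condition
    not belonging to the reference arm.
    """
    n_affected = int(round(affected_fraction * n))
    signs = rng.choice([-1.0, 1.0], size=n)
    cols = {}
    for label in labels:
        fc = np.zeros(n)
        if not label.startswith(reference_condition):
            fc[:n_affected] = signs[:n_affected] * effect_size
        cols[f"fc[{label}]"] = fc
    return cols


def generate_truth(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Draw a reproducible ground-truth parameter set from a single seed."""
    config = config or SimulationConfig()
    config.validate()
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_MODALITY_STREAM) + 1)
    rngs = {name: np.random.default_rng(children[i]) for name, i in _MODALITY_STREAM.items()}
    rng_design = np.random.default_rng(children[-1])
    labels = config.condition_labels

    rng = rngs["proteins"]
    accs = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    lengths = rng.integers(80, 200, size=config.n_proteins)
    sequences = ["".join(rng.choice(list(AMINO_ACIDS), size=n)) for n in lengths]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_proteins)
    cols = _effect_columns(
        rng, config.n_proteins, labels, config.affected_fraction,
        config.protein_effect_size, config.conditions[0],
    )
    proteins = pd.DataFrame(
        {"accession": accs, "sequence": sequences, "baseline": baseline, **cols}
    )

    # PTM sites: pick proteins and positions, patch the sequence letter so the
    # site residue is chemically valid
    sites: dict[str, pd.DataFrame] = {}
    seq_arr = {acc: list(seq) for acc, seq in zip(accs, sequences)}
    taken: dict[str, set[int]] = {acc: set() for acc in accs}
    for modality, n_sites in config.n_sites.items():
        if n_sites <= 0:
            continue
        rng = rngs[modality]
        residues = _SITE_RESIDUES[modality]
        rows = []
        for _ in range(n_sites):
            acc = accs[int(rng.integers(0, config.n_proteins))]
            seq = seq_arr[acc]
            pos = int(rng.integers(8, len(seq) - 7))
            for _attempt in range(100):
                if pos not in taken[acc]:
                    break
                pos = int(rng.integers(8, len(seq) - 7))
            taken[acc].add(pos)
            letter = residues[int(rng.integers(0, len(residues)))]
            seq[pos - 1] = letter  # pos is 1-based
            rows.append(
                {
                    "accession": acc,
                    "letter": letter,
                    "position": pos,
                    "offset": float(rng.normal(-2.0, 1.0)),
                }
            )
        df = pd.DataFrame(rows)
        df["site"] = df["accession"] + "-" + df["letter"] + df["position"].astype(str)
        cols = _effect_columns(
            rng, n_sites, labels, config.affected_fraction,
            config.occupancy_effect_size, config.conditions[0],
        )
        for name, values in cols.items():
            df[name] = values
        if modality == "redox":
            df["stoich"] = np.clip(100.0 * rng.beta(1.2, 4.0, size=n_sites), 0.5, 100.0)
        sites[modality] = df

    proteins["sequence"] = ["".join(seq_arr[acc]) for acc in accs]

    loadings = []
    batch_offsets = {}
    for p in range(config.n_plexes):
        plex = f"P{p + 1}"
        batch_offsets[plex] = (
            float(rng_design.normal(0.0, config.batch_sd)) if config.batch_sd > 0 else 0.0
        )
        for ch in TMT18_CHANNELS:
            loadings.append(
                {
                    "plex_id": plex,
                    "channel_id": ch,
                    "loading": (
                        float(rng_design.normal(0.0, config.loading_sd))
                        if config.loading_sd > 0
                        else 0.0
                    ),
                }
            )
    return SyntheticTruth(
        config=config,
        seed=seed,
        proteins=proteins,
        sites=sites,
        channel_loadings=pd.DataFrame(loadings),
        batch_offsets=batch_offsets,
    )


# ---------------------------------------------------------------------------
# PSM-table simulation
# ---------------------------------------------------------------------------

class SimulatedData(NamedTuple):
    psm_tables: dict          # modality -> PsmTable
    qc_fail_ids: dict         # modality -> set of psm_ids injected to fail QC


def _qc_fields(rng, config, fail: bool):
    if fail:
        if rng.random() < 0.5:  # fail on mass error
            return (
                float(rng.uniform(10.5, 25.0) * rng.choice([-1.0, 1.0])),
                float(rng.uniform(0.0, 0.009)),
            )
        return float(np.clip(rng.normal(0.0, config.mass_error_sd), -9.9, 9.9)), float(
            rng.uniform(0.01, 0.2)
        )
    ppm = float(np.clip(rng.normal(0.0, config.mass_error_sd), -9.9, 9.9))
    return ppm, float(rng.uniform(0.0, 0.009))


def _tmt_mods(rng, peptide: str, rate: float) -> list[tuple[str, object]]:
    """Dynamic TMT labels: N-terminus plus lysines, each labeled at ``rate``."""
    mods: list[tuple[str, object]] = [("tmt", "nt")] if rng.random() < rate else []
    for i, aa in enumerate(peptide):
        if aa == "K" and rng.random() < rate:
            mods.append(("tmt", i))
    return mods


def _peptide_around(seq: str, pos: int, length: int = 13) -> tuple[str, int]:
    """A peptide window covering 1-based ``pos``; returns (sequence, 1-based start)."""
    half = length // 2
    start = max(1, min(pos - half, len(seq) - length + 1))
    return seq[start - 1 : start - 1 + length], start


class _ChannelModel:
    """Raw intensities for every (plex, channel) given per-condition log2 means."""

    def __init__(self, truth: SyntheticTruth, design: PlexDesign):
        self.config = truth.config
        lam = truth.channel_loadings.set_index(["plex_id", "channel_id"])["loading"]
        self.rows = []
        for row in design.table.itertuples():
            self.rows.append(
                (
                    row.plex_id,
                    f"intensity_{row.channel_id}",
                    f"{row.condition} {row.timepoint}" if row.channel_role != "empty" else None,
                    row.channel_role,
                    float(lam.get((row.plex_id, row.channel_id), 0.0)),
                    truth.batch_offsets.get(row.plex_id, 0.0),
                )
            )

    def sample(self, rng, plex: str, base: dict, ox_scale: dict | None = None) -> dict:
        cfg = self.config
        out = {}
        for p, col, label, role, lam, delta in self.rows:
            if p != plex:
                continue
            if role == "empty":
                out[col] = np.nan
                continue
            log2v = base[label] + lam + delta
            if cfg.sigma > 0:
                log2v += rng.normal(0.0, cfg.sigma)
            v = 2.0 ** log2v
            if ox_scale is not None and role == "oxidation":
                v *= ox_scale[label] / 100.0
            if cfg.dropout > 0 and rng.random() < cfg.dropout:
                v = np.nan
            out[col] = v
        return out


def simulate_psm_tables(
    truth: SyntheticTruth, design: PlexDesign, with_dynamic_tmt: bool = False
) -> SimulatedData:
    """Simulate one PSM table per modality from the truth parameters.

    Every peptide yields one PSM per plex (reporter intensities are
    extracted per plex).  In PTM modalities a fraction ``1 - selectivity``
    of features are replaced by off-target contaminant peptides, which is
    what enrichment selectivity measures.  ``with_dynamic_tmt`` annotates
    global PSMs with dynamic TMT labels at the configured labeling rate for
    labeling-efficiency QC.
    """
    config = truth.config
    streams = np.random.SeedSequence(truth.seed + 1_000_003).spawn(4)
    channels = _ChannelModel(truth, design)
    plexes = list(design.table["plex_id"].unique())
    prot = truth.proteins.set_index("accession")
    labels = config.condition_labels
    fc = {label: prot[f"fc[{label}]"] for label in labels}
    tables: dict[str, PsmTable] = {}
    qc_fail: dict[str, set] = {}

    # ---- global: several peptides per protein ---------------------------
    rng = np.random.default_rng(streams[0])
    rows: list[dict] = []
    fails: set[str] = set()
    counter = 0
    for acc, p in prot.iterrows():
        n_pep = 1 + rng.poisson(max(config.mean_peptides_per_protein - 1, 0.0))
        for _ in range(n_pep):
            center = int(rng.integers(7, len(p["sequence"]) - 6))
            peptide, start = _peptide_around(p["sequence"], center)
            pep_offset = rng.normal(0.0, config.peptide_offset_sd)
            base = {lb: p["baseline"] + fc[lb][acc] + pep_offset for lb in labels}
            mods = _tmt_mods(rng, peptide, config.tmt_labeling_rate) if with_dynamic_tmt else []
            for plex in plexes:
                counter += 1
                psm_id = f"g{counter:06d}"
                fail = rng.random() < config.qc_fail_fraction
                if fail:
                    fails.add(psm_id)
                ppm, pepq = _qc_fields(rng, config, fail)
                rows.append(
                    {
                        "psm_id": psm_id,
                        "plex_id": plex,
                        "peptide": peptide,
                        "mods": format_mods(mods),
                        "protein_accession": acc,
                        "peptide_start": start,
                        "mass_error_ppm": ppm,
                        "pepq": pepq,
                        **channels.sample(rng, plex, base),
                    }
                )
    tables["global"] = _finish_table(rows, "global")
    qc_fail["global"] = fails

    # ---- PTM modalities ---------------------------------------------------
    for i, modality in enumerate(("redox", "phospho", "acetyl")):
        if modality not in truth.sites:
            continue
        rng = np.random.default_rng(streams[i + 1])
        mod_name = _SITE_MODS[modality]
        site_df = truth.sites[modality]
        stoich = (
            {lb: truth.stoichiometry(lb) for lb in labels} if modality == "redox" else None
        )
        rows = []
        fails = set()
        counter = 0
        for idx, site in site_df.iterrows():
            acc = site["accession"]
            p = prot.loc[acc]
            # on/off target decided once per feature so unique-peptide
            # selectivity matches the configured rate
            on_target = rng.random() < config.selectivity.get(modality, 1.0)
            if on_target:
                peptide, start = _peptide_around(p["sequence"], int(site["position"]))
                mods = [(mod_name, int(site["position"]) - start)]
                acc_out = acc
            else:
                other = truth.proteins.iloc[int(rng.integers(len(truth.proteins)))]
                seq = other["sequence"]
                if modality == "redox":  # off-target = no cysteine for thiol capture
                    seq = seq.replace("C", "A")
                peptide, start = _peptide_around(seq, int(rng.integers(7, len(seq) - 6)))
                mods = []
                acc_out = "CONTAM_" + other["accession"]
            base = {
                lb: p["baseline"] + fc[lb][acc] + site["offset"]
                + (0.0 if modality == "redox" else site[f"fc[{lb}]"])
                for lb in labels
            }
            scale = {lb: float(stoich[lb][site["site"]]) for lb in labels} if stoich else None
            for plex in plexes:
                counter += 1
                psm_id = f"{modality[0]}{counter:06d}"
                fail = rng.random() < config.qc_fail_fraction
                if fail:
                    fails.add(psm_id)
                ppm, pepq = _qc_fields(rng, config, fail)
                rows.append(
                    {
                        "psm_id": psm_id,
                        "plex_id": plex,
                        "peptide": peptide,
                        "mods": format_mods(mods),
                        "protein_accession": acc_out,
                        "peptide_start": start,
                        "mass_error_ppm": ppm,
                        "pepq": pepq,
                        **channels.sample(rng, plex, base, scale),
                    }
                )
        tables[modality] = _finish_table(rows, modality)
        qc_fail[modality] = fails
    return SimulatedData(tables, qc_fail)


def _finish_table(rows: list[dict], modality: str) -> PsmTable:
    df = pd.DataFrame(rows)
    for ch in TMT18_CHANNELS:
        col = f"intensity_{ch}"
        if col not in df.columns:
            df[col] = np.nan
    ordered = [c for c in df.columns if not c.startswith("intensity_")] + [
        f"intensity_{ch}" for ch in TMT18_CHANNELS
    ]
    return PsmTable(df[ordered], modality=modality)


def write_fasta(truth: SyntheticTruth, path) -> None:
    """Write the simulated proteome as FASTA."""
    with open(path, "w") as fh:
        for row in truth.proteins.itertuples():
            fh.write(f">{row.accession} synthetic protein\n{row.sequence}\n")


# ---------------------------------------------------------------------------
# Focused redox-site matrix (stoichiometry recovery experiments)
# ---------------------------------------------------------------------------

def simulate_redox_site_matrix(
    stoichiometries,
    n_sites: int = 1000,
    n_oxidation: int = 4,
    n_total: int = 2,
    cv: float = 0.10,
    seed: int = 0,
) -> tuple[AbundanceMatrix, PlexDesign, pd.Series]:
    """Single-condition raw redox site matrix with known % oxidation per site.

    ``stoichiometries`` cycles over the sites.  Each intensity carries
    independent multiplicative log-normal noise with the given CV.  Returns
    (matrix, one-plex design, per-site true stoichiometry).
    """
    rng = np.random.default_rng(seed)
    s = np.resize(np.asarray(stoichiometries, dtype=float), n_sites)
    sigma_ln = np.sqrt(np.log1p(cv**2))
    totals_base = 2.0 ** rng.normal(17.0, 1.5, size=n_sites)

    def noisy(shape):
        return np.exp(rng.normal(0.0, sigma_ln, size=shape) - sigma_ln**2 / 2.0)

    tot = totals_base[:, None] * noisy((n_sites, n_total))
    ox = (s[:, None] / 100.0) * totals_base[:, None] * noisy((n_sites, n_oxidation))
    cols = [f"Ox_r{i + 1}" for i in range(n_oxidation)] + [
        f"Tot_r{i + 1}" for i in range(n_total)
    ]
    data = pd.DataFrame(
        np.hstack([ox, tot]),
        index=[f"S{i + 1:05d}-C1" for i in range(n_sites)],
        columns=cols,
    )
    rows = []
    for i, col in enumerate(cols):
        role = "oxidation" if col.startswith("Ox") else "total_thiol"
        rows.append(
            {
                "plex_id": "P1",
                "channel_id": TMT18_CHANNELS[i],
                "sample_id": col,
                "condition": "Control",
                "timepoint": "4 h",
                "replicate": i + 1,
                "channel_role": role,
                "batch": "P1",
            }
        )
    design = PlexDesign(pd.DataFrame(rows))
    truth = pd.Series(s, index=data.index, name="stoichiometry")
    return AbundanceMatrix(data, scale="raw", modality="redox"), design, truth


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

def write_toy_structure(
    residues: list[tuple[str, int]],
    coordinates,
    plddt,
    path,
    accession: str = "TOY",
) -> None:
    """Write a minimal CA-only model as PDB or mmCIF (chosen by extension).

    ``residues`` are (letter, 1-based position) pairs; ``plddt`` goes into
    the B-factor column following the predicted-structure convention.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (len(residues), 3):
        raise ValidationError("coordinates must be (n_residues, 3)")
    st = build_structure(accession, residues, coordinates, plddt)
    path = str(path)
    if path.endswith((".cif", ".mmcif")):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)
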