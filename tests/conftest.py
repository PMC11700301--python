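"""Shared fixtures: small simulated datasets and hand-built tables."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import ptmplex as px
from ptmplex.matrices import AbundanceMatrix


def make_matrix(values, scale="log2", modality="global", index=None, columns=None, tags=None):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=index or [f"f{i + 1}" for i in range(values.shape[0])],
        columns=columns or [f"s{i + 1}" for i in range(values.shape[1])],
    )
    return AbundanceMatrix(df, scale=scale, modality=modality, tags=list(tags or []))


def one_plex_design(n_oxidation=4, n_total=2, n_empty=0, conditions=None):
    """Single-plex design with simple sequential channel ids."""
    from ptmplex.simulate import TMT18_CHANNELS

    rows = []
    i = 0
    conditions = conditions or ["Control"] * n_oxidation
    for r in range(n_oxidation):
        rows.append(
            dict(
                plex_id="P1",
                channel_id=TMT18_CHANNELS[i],
                sample_id=f"Ox_r{r + 1}",
                condition=conditions[r],
                timepoint="4 h",
                replicate=r + 1,
                channel_role="oxidation",
                batch="P1",
            )
        )
        i += 1
    for r in range(n_total):
        rows.append(
            dict(
                plex_id="P1",
                channel_id=TMT18_CHANNELS[i],
                sample_id=f"Tot_r{r + 1}",
                condition="Control",
                timepoint="4 h",
                replicate=r + 1,
                channel_role="total_thiol",
                batch="P1",
            )
        )
        i += 1
    for _ in range(n_empty):
        rows.append(
            dict(
                plex_id="P1",
                channel_id=TMT18_CHANNELS[i],
                sample_id="",
                condition="",
                timepoint="",
                replicate=0,
                channel_role="empty",
                batch="P1",
            )
        )
        i += 1
    return px.PlexDesign(pd.DataFrame(rows))


def psm_frame(rows, channels):
    """Build a PSM DataFrame from dicts; missing intensity columns filled with NaN."""
    df = pd.DataFrame(rows)
    for ch in channels:
        col = f"intensity_{ch}"
        if col not in df.columns:
            df[col] = np.nan
    defaults = dict(mods="", peptide_start=1, mass_error_ppm=0.0, pepq=0.001)
    for key, val in defaults.items():
        if key not in df.columns:
            df[key] = val
    if "psm_id" not in df.columns:
        df["psm_id"] = [f"p{i}" for i in range(len(df))]
    return df


@pytest.fixture(scope="session")
def sim_bundle():
    """A small but complete simulated multi-modality dataset (default study design)."""
    cfg = px.SimulationConfig(
        n_proteins=60, n_sites={"redox": 80, "phospho": 80, "acetyl": 30}
    )
    truth = px.generate_truth(cfg, seed=7)
    design = px.default_design(cfg)
    sim = px.simulate_psm_tables(truth, design)
    fasta = {r.accession: r.sequence for r in truth.proteins.itertuples()}
    return SimpleNamespace(cfg=cfg, truth=truth, design=design, sim=sim, fasta=fasta)


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Noise-free dataset with occupancy-only effects (loading/batch still on)."""
    cfg = px.SimulationConfig(
        n_proteins=80,
        n_sites={"redox": 60, "phospho": 120},
        sigma=0.0,
        dropout=0.0,
        protein_effect_size=0.0,
        selectivity={"redox": 1.0, "phospho": 1.0, "acetyl": 1.0},
    )
    truth = px.generate_truth(cfg, seed=3)
    design = px.default_design(cfg)
    sim = px.simulate_psm_tables(truth, design)
    fasta = {r.accession: r.sequence for r in truth.proteins.itertuples()}
    return SimpleNamespace(cfg=cfg, truth=truth, design=design, sim=sim, fasta=fasta)


def run_site_chain(bundle, modality, target_mod):
    """ingest -> rollup -> full site normalization chain for one modality."""
    design = bundle.design
    tables = bundle.sim.psm_tables
    pep = px.log2_transform(px.rollup_peptide(tables["global"], design))
    prot_norm = px.median_center(
        px.batch_correct(px.log2_transform(px.rollup_protein(tables["global"], design)), design)
    )
    site_raw = px.rollup_site(tables[modality], design, target_mod, bundle.fasta)
    site_m = px.correct_for_protein(
        px.batch_correct(
            px.scale_ptm_to_global(px.log2_transform(site_raw), pep), design
        ),
        prot_norm,
        design.condition_map(),
    )
    return SimpleNamespace(
        peptide_log2=pep, protein_norm=prot_norm, site_raw=site_raw, site_norm=site_m
    )


def contrast_estimate(matrix, design, condition_a, condition_b):
    """Mean difference of oxidation-channel samples between two conditions."""
    cm = design.condition_map()
    roles = design.role_map()
    cond = pd.Series({s: cm[s] for s, r in roles.items() if r == "oxidation"})
    a = matrix.data[cond.index[cond == condition_a]].mean(axis=1)
    b = matrix.data[cond.index[cond == condition_b]].mean(axis=1)
    return a - b
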