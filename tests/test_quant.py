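"""Rollup oracles and the normalization chain's contracts."""

import numpy as np
import pandas as pd
import pytest

import ptmplex as px
from ptmplex.errors import StateError, ValidationError
from ptmplex.ingest import INTENSITY_PREFIX, PsmTable

from conftest import make_matrix, one_plex_design, psm_frame


def brute_force_rollup(psms: PsmTable, design, feature_of_row):
    """Independent accumulation oracle: python loops over (row, channel)."""
    acc: dict = {}
    for _, row in psms.df.iterrows():
        feature = feature_of_row(row)
        for col in psms.intensity_columns():
            channel = col[len(INTENSITY_PREFIX):]
            sample = design.sample_for(row["plex_id"], channel)
            if sample is None:
                continue
            v = row[col]
            if pd.isna(v) or v <= 0:
                continue
            acc.setdefault((feature, sample), 0.0)
            acc[(feature, sample)] += v
    return acc


class TestRollup:
    def test_sum_and_missing_propagation(self):
        design = one_plex_design(n_oxidation=2, n_total=0)
        rows = [
            dict(psm_id="a", plex_id="P1", peptide="AAA", protein_accession="P1",
                 intensity_126C=100.0, intensity_127N=np.nan),
            dict(psm_id="b", plex_id="P1", peptide="CCC", protein_accession="P1",
                 intensity_126C=250.0, intensity_127N=np.nan),
            dict(psm_id="c", plex_id="P1", peptide="DDD", protein_accession="P2",
                 intensity_126C=0.0, intensity_127N=50.0),
        ]
        table = PsmTable(psm_frame(rows, ["126C", "127N"]))
        m = px.rollup_protein(table, design)
        assert m.data.loc["P1", "Ox_r1"] == 350.0
        assert np.isnan(m.data.loc["P1", "Ox_r2"])  # all contributions missing
        assert np.isnan(m.data.loc["P2", "Ox_r1"])  # zero treated as missing
        assert m.data.loc["P2", "Ox_r2"] == 50.0

    def test_unknown_channel_rejected(self):
        design = one_plex_design(n_oxidation=1, n_total=0)
        rows = [dict(psm_id="a", plex_id="P1", peptide="AAA", protein_accession="P1",
                     intensity_126C=1.0, intensity_135N=2.0)]
        with pytest.raises(ValidationError, match="135N"):
            px.rollup_protein(PsmTable(psm_frame(rows, ["126C", "135N"])), design)

    def test_protein_rollup_matches_brute_force(self, sim_bundle):
        table = sim_bundle.sim.psm_tables["global"]
        sub = PsmTable(table.df.head(200).copy(), modality="global")
        m = px.rollup_protein(sub, sim_bundle.design)
        oracle = brute_force_rollup(sub, sim_bundle.design, lambda r: r["protein_accession"])
        for (feature, sample), expected in oracle.items():
            assert m.data.loc[feature, sample] == pytest.approx(expected, rel=1e-12)
        n_filled = m.data.notna().sum().sum()
        assert n_filled == len(oracle)

    def test_site_rollup_matches_brute_force(self, sim_bundle):
        table = sim_bundle.sim.psm_tables["phospho"]
        m = px.rollup_site(table, sim_bundle.design, "phospho", sim_bundle.fasta)

        def site_of(row):
            return str(px.map_to_sites(row, sim_bundle.fasta, "phospho"))

        on_target = PsmTable(
            table.df[table.df["mods"].str.contains("phospho")].reset_index(drop=True),
            modality="phospho",
        )
        oracle = brute_force_rollup(on_target, sim_bundle.design, site_of)
        assert m.data.notna().sum().sum() == len(oracle)
        for (feature, sample), expected in oracle.items():
            assert m.data.loc[feature, sample] == pytest.approx(expected, rel=1e-12)

    def test_composite_site_key_does_not_leak_to_single_sites(self):
        design = one_plex_design(n_oxidation=1, n_total=0)
        fasta = {"P1": "MSTSY" + "A" * 10}
        rows = [
            dict(psm_id="a", plex_id="P1", peptide="STSY", mods="phospho@0;phospho@2",
                 protein_accession="P1", peptide_start=2, intensity_126C=40.0),
            dict(psm_id="b", plex_id="P1", peptide="STSY", mods="phospho@0",
                 protein_accession="P1", peptide_start=2, intensity_126C=60.0),
        ]
        m = px.rollup_site(PsmTable(psm_frame(rows, ["126C"])), design, "phospho", fasta)
        assert m.data.loc["P1-S2S4", "Ox_r1"] == 40.0
        assert m.data.loc["P1-S2", "Ox_r1"] == 60.0


class TestLog2AndMedianCenter:
    def test_log2_values(self):
        m = make_matrix([[8.0, 1.0], [0.0, 1024.0]], scale="raw")
        out = px.log2_transform(m)
        assert out.data.iloc[0, 0] == 3.0
        assert out.data.iloc[0, 1] == 0.0
        assert np.isnan(out.data.iloc[1, 0])  # zero stays missing
        assert out.data.iloc[1, 1] == 10.0
        assert out.scale == "log2" and "log2" in out.tags

    def test_log2_twice_is_state_error(self):
        m = px.log2_transform(make_matrix([[8.0]], scale="raw"))
        with pytest.raises(StateError):
            px.log2_transform(m)

    def test_median_center_column(self):
        m = make_matrix([[1.0], [2.0], [3.0]])
        out = px.median_center(m)
        assert list(out.data.iloc[:, 0]) == [-1.0, 0.0, 1.0]

    def test_median_center_idempotent_and_zero_medians(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(500, 17)))
        once = px.median_center(m)
        assert np.abs(once.data.median(axis=0)).max() < 1e-9
        twice = px.median_center(once)
        assert np.abs(twice.data - once.data).max().max() < 1e-9


class TestBatchCorrect:
    def _two_batch_design(self):
        rows = []
        for p, batch in (("P1", "P1"), ("P2", "P2")):
            for i in range(2):
                rows.append(
                    dict(plex_id=p, channel_id=f"12{6 + i}C", sample_id=f"{p}_s{i + 1}",
                         condition="Control", timepoint="4 h", replicate=i + 1,
                         channel_role="oxidation", batch=batch)
                )
        return px.PlexDesign(pd.DataFrame(rows))

    def test_mean_shift_arithmetic(self):
        design = self._two_batch_design()
        m = make_matrix([[4.0, 6.0, 6.0, 8.0]], columns=["P1_s1", "P1_s2", "P2_s1", "P2_s2"])
        out = px.batch_correct(m, design)
        # batch means 5 and 7, grand mean 6 -> +1 / -1 shifts
        assert list(out.data.iloc[0]) == [5.0, 7.0, 5.0, 7.0]

    def test_within_batch_differences_preserved(self, sim_bundle):
        m = px.log2_transform(
            px.rollup_protein(sim_bundle.sim.psm_tables["global"], sim_bundle.design)
        )
        out = px.batch_correct(m, sim_bundle.design)
        batch = sim_bundle.design.batch_map()
        cols = [s for s in m.samples if batch[s] == "P1"][:4]
        before = m.data[cols[0]] - m.data[cols[1]]
        after = out.data[cols[0]] - out.data[cols[1]]
        pd.testing.assert_series_equal(before, after, check_exact=False, atol=1e-12)

    def test_injected_offsets_removed(self):
        """Injected inter-plex offsets vanish per feature after correction."""
        cfg = px.SimulationConfig(
            n_proteins=60, n_sites={}, sigma=0.0, dropout=0.0, loading_sd=0.0,
            protein_effect_size=0.0,
        )
        truth = px.generate_truth(cfg, seed=9)
        design = px.default_design(cfg)
        sim = px.simulate_psm_tables(truth, design)
        m = px.log2_transform(px.rollup_protein(sim.psm_tables["global"], design))
        batch = pd.Series(design.batch_map())
        # pre-correction shift equals the injected delta
        p1 = m.data[batch.index[batch == "P1"]].mean(axis=1)
        p2 = m.data[batch.index[batch == "P2"]].mean(axis=1)
        delta = truth.batch_offsets["P1"] - truth.batch_offsets["P2"]
        assert np.abs((p1 - p2) - delta).max() < 1e-9
        out = px.batch_correct(m, design)
        q1 = out.data[batch.index[batch == "P1"]].mean(axis=1)
        q2 = out.data[batch.index[batch == "P2"]].mean(axis=1)
        assert np.abs(q1 - q2).max() < 1e-9

    def test_idempotent(self, sim_bundle):
        m = px.log2_transform(
            px.rollup_protein(sim_bundle.sim.psm_tables["global"], sim_bundle.design)
        )
        once = px.batch_correct(m, sim_bundle.design)
        twice = px.batch_correct(once, sim_bundle.design)
        assert np.nanmax(np.abs(twice.data.to_numpy() - once.data.to_numpy())) < 1e-9

    def test_single_batch_is_noop_with_warning(self):
        design = one_plex_design(n_oxidation=3, n_total=0)
        m = make_matrix([[1.0, 2.0, 3.0]], columns=["Ox_r1", "Ox_r2", "Ox_r3"])
        with pytest.warns(UserWarning, match="single batch"):
            out = px.batch_correct(m, design)
        pd.testing.assert_frame_equal(out.data, m.data)


class TestScalePtmToGlobal:
    def test_subtracts_global_column_medians(self):
        site = make_matrix([[1.0, 2.0], [3.0, 4.0]], modality="phospho")
        glob = make_matrix([[0.5, 0.0], [0.5, 0.0], [0.5, 0.0]])
        out = px.scale_ptm_to_global(site, glob)
        assert list(out.data["s1"]) == [0.5, 2.5]
        assert list(out.data["s2"]) == [2.0, 4.0]
        assert "global-scaled" in out.tags

    def test_identity_when_global_centered(self):
        site = make_matrix([[1.0, 2.0]])
        glob = make_matrix([[-1.0, -2.0], [0.0, 0.0], [1.0, 2.0]])
        out = px.scale_ptm_to_global(site, glob)
        pd.testing.assert_frame_equal(out.data, site.data)

    def test_batch_corrected_global_rejected(self):
        site = make_matrix([[1.0]])
        glob = make_matrix([[1.0]], tags=["log2", "batch-corrected"])
        with pytest.raises(StateError):
            px.scale_ptm_to_global(site, glob)

    def test_unmatched_sample_passes_through(self):
        site = make_matrix([[1.0, 2.0]], columns=["a", "b"])
        glob = make_matrix([[0.5], [0.5]], columns=["a"])
        with pytest.warns(UserWarning, match="unscaled"):
            out = px.scale_ptm_to_global(site, glob)
        assert out.data.loc["f1", "a"] == 0.5
        assert out.data.loc["f1", "b"] == 2.0
        assert out.notes["unscaled_samples"] == ["b"]

    def test_loading_offsets_cancelled(self):
        """Injected channel loadings leave site-column medians near zero."""
        # ~2000 peptides in the global matrix and 2000 sites
        cfg = px.SimulationConfig(
            n_proteins=700, n_sites={"phospho": 2000}, sigma=0.25, dropout=0.0,
            selectivity={"phospho": 1.0}, affected_fraction=0.0,
        )
        truth = px.generate_truth(cfg, seed=13)
        design = px.default_design(cfg)
        sim = px.simulate_psm_tables(truth, design)
        fasta = {r.accession: r.sequence for r in truth.proteins.itertuples()}
        pep = px.log2_transform(px.rollup_peptide(sim.psm_tables["global"], design))
        site = px.log2_transform(
            px.rollup_site(sim.psm_tables["phospho"], design, "phospho", fasta)
        )
        before = site.data.median(axis=0)
        out = px.scale_ptm_to_global(site, pep)
        after = out.data.median(axis=0)
        # loading factors (SD 0.3 log2) dominate the raw column medians ...
        assert before.std() > 0.15
        # ... and are cancelled to within median-estimation noise; the common
        # occupancy offset shared by all columns is irrelevant to fold changes
        assert (after - after.mean()).abs().max() < 0.05


class TestCorrectForProtein:
    def _site_chain_tags(self):
        return ["rollup", "log2", "global-scaled", "batch-corrected"]

    def test_constant_protein_subtracted(self):
        site = make_matrix(
            [[5.0, 6.0]], modality="phospho", index=["P1-S3"], columns=["a", "b"],
            tags=self._site_chain_tags(),
        )
        prot = make_matrix([[2.0, 2.0]], index=["P1"], columns=["a", "b"])
        out = px.correct_for_protein(site, prot, {"a": "c1", "b": "c1"}, min_replicates=2)
        assert list(out.data.iloc[0]) == [3.0, 4.0]

    def test_missing_protein_passes_through_with_tag(self):
        site = make_matrix(
            [[5.0, 6.0]], modality="phospho", index=["P9-S3"], columns=["a", "b"],
            tags=self._site_chain_tags(),
        )
        prot = make_matrix([[2.0, 2.0]], index=["P1"], columns=["a", "b"])
        out = px.correct_for_protein(site, prot, {"a": "c1", "b": "c1"})
        assert list(out.data.iloc[0]) == [5.0, 6.0]
        assert ("P9-S3", "c1") in out.notes["uncorrected"]

    def test_order_enforced(self):
        site = make_matrix([[1.0]], tags=["rollup", "log2"])
        prot = make_matrix([[0.0]])
        with pytest.raises(StateError, match="order"):
            px.correct_for_protein(site, prot, {"s1": "c1"})

    def test_noise_free_contrast_equals_occupancy(self, noise_free_bundle):
        """Noise-free: corrected site contrasts equal injected occupancy log2FCs."""
        from conftest import contrast_estimate, run_site_chain

        chain = run_site_chain(noise_free_bundle, "phospho", "phospho")
        est = contrast_estimate(
            chain.site_norm, noise_free_bundle.design, "Cytokine 4 h", "Control 4 h"
        )
        truth_fc = noise_free_bundle.truth.site_fc("phospho", "Cytokine 4 h")
        common = est.index.intersection(truth_fc.index)
        assert len(common) >= 100
        assert np.abs(est[common] - truth_fc[common]).max() < 1e-9


class TestFilterMissing:
    def test_hand_enumerated_drop_list(self):
        """10-feature toy: drop exactly the features with >2 NA in a condition."""
        cond = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
        rng = np.random.default_rng(0)
        data = rng.normal(size=(10, 8))
        # features 0,3,7: 3 NAs in condition A; feature 5: 4 NAs in B;
        # feature 2: exactly 2 NAs in each condition (kept)
        for f in (0, 3, 7):
            data[f, :3] = np.nan
        data[5, 4:] = np.nan
        data[2, :2] = np.nan
        data[2, 4:6] = np.nan
        m = make_matrix(data, columns=list(cond))
        kept, dropped = px.filter_missing(m, cond, max_na_per_condition=2)
        assert sorted(dropped) == ["f1", "f4", "f6", "f8"]  # 1-based feature ids
        assert "f3" in kept.data.index

    def test_boundary_two_missing_everywhere_kept(self):
        cond = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
        data = np.ones((1, 8))
        data[0, :2] = np.nan
        data[0, 4:6] = np.nan
        m = make_matrix(data, columns=list(cond))
        kept, dropped = px.filter_missing(m, cond)
        assert dropped == []

    def test_small_condition_warns(self):
        cond = {"a": "A", "b": "A", "c": "B"}
        m = make_matrix(np.ones((2, 3)), columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="replicates"):
            px.filter_missing(m, cond, max_na_per_condition=2)


class TestProcessingStateTags:
    def test_full_chain_tag_order(self, sim_bundle):
        from conftest import run_site_chain

        chain = run_site_chain(sim_bundle, "phospho", "phospho")
        tags = chain.site_norm.tags
        order = ["log2", "global-scaled", "batch-corrected", "protein-corrected"]
        positions = [tags.index(t) for t in order]
        assert positions == sorted(positions)
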