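"""End-to-end orchestration: ingest -> quant -> redox -> stats -> ORA -> structure.

A run is described by a single YAML config (see :class:`RunConfig`); all
thresholds default to the documented analysis conventions and are recorded
in the run manifest together with per-stage feature counts, so filter
accounting can be audited after the fact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import read_plex_design
from .errors import ConfigurationError
from .ingest import enrichment_selectivity, filter_psms, read_fasta, read_psm_table
from .enrichment import DEFAULT_ORA_CUTOFFS, collapse_sites_to_genes, ora, ora_hits, read_gmt
from .quant import (
    batch_correct,
    correct_for_protein,
    filter_missing,
    log2_transform,
    median_center,
    rollup_peptide,
    rollup_protein,
    rollup_site,
    scale_ptm_to_global,
)
from .redox import channel_loading_factors, percent_oxidation
from .stats import DEFAULT_DE_CUTOFFS, anova_hits, de_hits, one_way_anova, two_sample_test
from .structure import read_structure, site_distance_matrix

PTM_TARGET_MODS = {"redox": "nem", "phospho": "phospho", "acetyl": "acetyl"}
SELECTIVITY_TARGETS = {
    "redox": {"target_residue": "C"},
    "phospho": {"target_mod": "phospho"},
    "acetyl": {"target_mod": "acetyl"},
}


@dataclass
class RunConfig:
    """Validated run configuration."""

    design: str
    fasta: str
    psm_tables: dict          # modality -> path
    output_dir: str = "ptmplex_out"
    gmt: str | None = None
    structures: list = field(default_factory=list)  # [{path, accession, residues:[...]}]
    max_ppm: float = 10.0
    max_pepq: float = 0.01
    max_na_per_condition: int = 2
    de_cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_DE_CUTOFFS))
    ora_cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_ORA_CUTOFFS))
    anova_reference: str = "Control 4 h"
    plddt_threshold: float = 70.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(doc) - known
        if extra:
            raise ConfigurationError(f"unknown config key(s): {sorted(extra)}")
        try:
            cfg = cls(**doc)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for label, path in [("design", self.design), ("fasta", self.fasta)]:
            if not Path(path).exists():
                raise ConfigurationError(f"{label} file does not exist: {path}")
        if "global" not in self.psm_tables:
            raise ConfigurationError("psm_tables must include the 'global' modality")
        for modality, path in self.psm_tables.items():
            if not Path(path).exists():
                raise ConfigurationError(f"PSM table for {modality!r} missing: {path}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "max_ppm": config.max_ppm,
            "max_pepq": config.max_pepq,
            "max_na_per_condition": config.max_na_per_condition,
            "de_cutoffs": config.de_cutoffs,
            "ora_cutoffs": config.ora_cutoffs,
            "anova_reference": config.anova_reference,
            "plddt_threshold": config.plddt_threshold,
        },
        "stages": {},
    }

    try:
        design = read_plex_design(config.design)
        fasta = read_fasta(config.fasta)
        condition_map = design.condition_map()
        role_map = design.role_map()
        quant_samples = [s for s, r in role_map.items() if r in ("oxidation", "standard")]

        # ---- ingest ------------------------------------------------------
        tables = {}
        for modality, path in config.psm_tables.items():
            raw = read_psm_table(path, modality=modality)
            kept, removed = filter_psms(raw, config.max_ppm, config.max_pepq)
            stage = {"psms_in": len(raw), "psms_removed": removed, "psms_out": len(kept)}
            if modality in SELECTIVITY_TARGETS and len(kept):
                stage["selectivity"] = enrichment_selectivity(
                    kept, **SELECTIVITY_TARGETS[modality]
                )
            manifest["stages"][f"ingest/{modality}"] = stage
            tables[modality] = kept

        # ---- global quant ------------------------------------------------
        protein_raw = rollup_protein(tables["global"], design)
        peptide_log2 = log2_transform(rollup_peptide(tables["global"], design))
        protein_norm = median_center(batch_correct(log2_transform(protein_raw), design))
        protein_norm.write(out / "protein_abundance.tsv")
        manifest["stages"]["rollup/global"] = {
            "proteins": len(protein_norm.features),
            "peptides": len(peptide_log2.features),
        }

        # ---- PTM quant + stats --------------------------------------------
        contrasts = _cytokine_contrasts(condition_map, quant_samples)
        results_by_modality = {}
        for modality in config.psm_tables:
            if modality == "global":
                matrix = protein_norm
            else:
                target = PTM_TARGET_MODS.get(modality)
                if target is None:
                    continue
                site_raw = rollup_site(tables[modality], design, target, fasta)
                site_m = log2_transform(site_raw)
                site_m = scale_ptm_to_global(site_m, peptide_log2)
                site_m = batch_correct(site_m, design)
                site_m = correct_for_protein(site_m, protein_norm, condition_map)
                matrix = site_m
                if modality == "redox":
                    stoich = percent_oxidation(
                        site_raw, design, loading_factors=channel_loading_factors(peptide_log2)
                    )
                    stoich.write(out / "redox_stoichiometry.tsv")
                    manifest["stages"]["redox"] = {
                        "sites": len(site_raw.features),
                        "stoichiometry_rows": len(stoich),
                        "sites_skipped": stoich.n_skipped,
                    }
            filtered, dropped = filter_missing(
                matrix, condition_map, config.max_na_per_condition
            )
            filtered.write(out / f"{modality}_abundance_normalized.tsv")
            manifest["stages"][f"quant/{modality}"] = {
                "features_in": len(matrix.features),
                "dropped_na_rule": len(dropped),
                "features_out": len(filtered.features),
            }

            de_frames = []
            for contrast, (group_a, group_b) in contrasts.items():
                de, skipped = two_sample_test(filtered, group_a, group_b)
                de.insert(0, "contrast", contrast)
                de_frames.append(de)
            de_all = pd.concat(de_frames, ignore_index=True) if de_frames else pd.DataFrame()
            if len(de_all):
                de_all.to_csv(out / f"{modality}_de.tsv", sep="\t", index=False)
            stats_cols = [s for s in filtered.samples if s in quant_samples]
            stats_m = filtered.tagged(data=filtered.data[stats_cols])
            anova = one_way_anova(
                stats_m,
                {s: condition_map[s] for s in stats_cols},
                reference=config.anova_reference,
            ) if _has_reference(condition_map, quant_samples, config.anova_reference) else pd.DataFrame()
            if len(anova):
                anova.to_csv(out / f"{modality}_anova.tsv", sep="\t", index=False)
            hits = de_hits(de_all, config.de_cutoffs) if len(de_all) else pd.DataFrame()
            manifest["stages"][f"stats/{modality}"] = {
                "features_tested": int(de_all["feature_id"].nunique()) if len(de_all) else 0,
                "de_hits": int(len(hits)),
                "anova_hits": int(len(anova_hits(anova))) if len(anova) else 0,
            }
            results_by_modality[modality] = {"matrix": filtered, "de": de_all, "hits": hits}

        # ---- over-representation -----------------------------------------
        if config.gmt:
            sets = read_gmt(config.gmt)
            for modality, res in results_by_modality.items():
                if not len(res["de"]):
                    continue
                universe = list(res["matrix"].features)
                hit_features = res["hits"]["feature_id"].unique() if len(res["hits"]) else []
                if modality != "global":
                    universe = collapse_sites_to_genes(universe)
                    hit_features = collapse_sites_to_genes(hit_features)
                table = ora(set(hit_features), set(universe), sets)
                if len(table):
                    table.to_csv(out / f"{modality}_ora.tsv", sep="\t", index=False)
                manifest["stages"][f"ora/{modality}"] = {
                    "sets_tested": int(len(table)),
                    "sets_passing": int(len(ora_hits(table, config.ora_cutoffs))),
                }
        else:
            manifest["stages"]["ora"] = {"skipped": "no GMT provided"}

        # ---- structures ----------------------------------------------------
        for entry in config.structures:
            model = read_structure(entry["path"], accession=entry.get("accession"))
            residues = [(r[0], int(r[1:])) for r in entry["residues"]]
            dm = site_distance_matrix(model, residues, config.plddt_threshold)
            name = entry.get("accession") or Path(entry["path"]).stem
            dm.distances.to_csv(out / f"structure_{name}_distances.tsv", sep="\t")
            manifest["stages"][f"structure/{name}"] = {
                "sites": len(dm.labels),
                "low_confidence_sites": int(dm.low_confidence.sum()),
            }
    except Exception:
        (out / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _cytokine_contrasts(condition_map, quant_samples) -> dict:
    """Treatment-vs-control contrasts per timepoint, e.g. 'Cytokine 4 h vs Control 4 h'."""
    by_condition: dict[str, list[str]] = {}
    for s in quant_samples:
        by_condition.setdefault(condition_map[s], []).append(s)
    contrasts = {}
    for cond in by_condition:
        arm, _, tp = cond.partition(" ")
        partner = f"Control {tp}"
        if arm != "Control" and partner in by_condition:
            if len(by_condition[cond]) >= 2 and len(by_condition[partner]) >= 2:
                contrasts[f"{cond} vs {partner}"] = (by_condition[cond], by_condition[partner])
    return contrasts


def _has_reference(condition_map, quant_samples, reference) -> bool:
    return any(condition_map[s] == reference for s in quant_samples)
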