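"""End-to-end orchestration: config, per-gene analysis, reports, manifest.

A run executes, per gene: dataset QC -> gap filtering -> M0 -> site-model
fits and LRTs -> per-site posteriors -> structural classification ->
residue join -> enrichment summaries -> viewer-attribute export.  Every
stage writes TSV/JSON and the run manifest records input hashes, the
thresholds and model options in effect, and the seed, so identical
inputs reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from selstruct import __version__
from selstruct.codon_evo import (
    ArrayTree,
    fit_M0,
    site_posteriors,
)
from selstruct.codon_evo.fit import fit_lrt_pair
from selstruct.paralog_compare import (
    delta_omega_table,
    export_delta_attributes,
    match_residues,
)
from selstruct.popgen_mk import mk_by_region
from selstruct.residue_join import (
    column_residue_map,
    enrichment_summary,
    export_attributes,
    join,
    records_to_frame,
    reference_residue_aas,
)
from selstruct.seqdata import (
    read_codon_fasta,
    read_tree,
    strip_gapped_columns,
)
from selstruct.struct_context import classify, read_structure

DEFAULT_THRESHOLDS = {
    "plddt_disorder": 50.0,
    "rel_sesa_buried": 0.3,
    "interface_delta_sasa": 15.0,
    "significance": 0.9,
    "display_cap": 1.5,
    "min_taxa": 5,
    "max_gap_fraction": 0.5,
}

DEFAULT_MODEL_OPTIONS = {
    "n_beta_classes": 10,
    "pi_mode": "F3x4",
    "branch_policy": "M0-fixed",
    "posterior_method": "NEB",
    "fit_m1_m2": True,
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration with paper-default thresholds."""

    output_dir: Path
    seed: int = 0
    reference_taxon: str | None = None
    thresholds: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    genes: list[dict] = field(default_factory=list)
    paralogs: list[dict] = field(default_factory=list)
    mk: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        self.thresholds = {**DEFAULT_THRESHOLDS, **self.thresholds}
        self.model = {**DEFAULT_MODEL_OPTIONS, **self.model}
        if not 0 < self.thresholds["significance"] < 1:
            raise ConfigError("significance threshold must be in (0, 1)")
        if self.thresholds["rel_sesa_buried"] <= 0:
            raise ConfigError("rel_sesa threshold must be positive")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        cfg = RunConfig(
            output_dir=base / raw.get("output_dir", "selstruct_out"),
            seed=int(raw.get("seed", 0)),
            reference_taxon=raw.get("reference_taxon"),
            thresholds=raw.get("thresholds", {}),
            model=raw.get("model", {}),
            genes=raw.get("genes", []),
            paralogs=raw.get("paralogs", []),
            mk=raw.get("mk", []),
        )
        for section in (cfg.genes, cfg.paralogs, cfg.mk):
            for entry in section:
                for key, value in list(entry.items()):
                    if key in (
                        "alignment", "tree", "structure", "structure_a",
                        "structure_b", "track_a", "track_b", "ingroup", "outgroup",
                    ):
                        entry[key] = base / value
        return cfg

    def validate_paths(self) -> None:
        for section, keys in (
            (self.genes, ("alignment", "tree", "structure")),
            (self.paralogs, ("structure_a", "structure_b", "track_a", "track_b")),
            (self.mk, ("ingroup", "outgroup")),
        ):
            for entry in section:
                for key in keys:
                    p = entry.get(key)
                    if p is not None and not Path(p).exists():
                        raise ConfigError(
                            f"{entry.get('name', '?')}: missing input {key} = {p}"
                        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(path: Path, config: RunConfig, inputs: dict, stages: dict) -> None:
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds,
        "model_options": config.model,
        "input_hashes": inputs,
        "stages": stages,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------
# Per-gene analysis
# ---------------------------------------------------------------------

def run_gene(config: RunConfig, gene: dict) -> dict:
    """Full selection + structure analysis for one gene entry."""
    name = gene["name"]
    outdir = config.output_dir / name
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {}
    stages: dict[str, str] = {}
    try:
        aln = read_codon_fasta(gene["alignment"])
        inputs["alignment"] = _sha256(gene["alignment"])
        dtree = read_tree(gene["tree"])
        inputs["tree"] = _sha256(gene["tree"])
        stages["read"] = "ok"

        if aln.n_taxa < config.thresholds["min_taxa"]:
            stages["qc"] = (
                f"EXCLUDED: {aln.n_taxa} taxa < {config.thresholds['min_taxa']}"
            )
            _write_manifest(outdir / "manifest.json", config, inputs, stages)
            return {"gene": name, "excluded": True}
        stages["qc"] = "ok"

        aln, col_map_filter = strip_gapped_columns(
            aln, config.thresholds["max_gap_fraction"]
        )
        stages["gap_filter"] = f"ok ({len(col_map_filter)} columns kept)"

        tree = ArrayTree.from_dendropy(dtree, aln.taxa)
        pi_mode = config.model["pi_mode"]
        m0 = fit_M0(aln, tree, pi_mode)
        rows = [
            {
                "model": "M0", "log_likelihood": m0.log_likelihood,
                "kappa": m0.kappa, "omega": m0.omega,
                "n_params": m0.n_params, "converged": m0.converged,
            }
        ]
        lrt_rows = []
        fits = {"M0": m0}
        pairings = [("M7", "M8")]
        if config.model["fit_m1_m2"]:
            pairings.insert(0, ("M1", "M2"))
        for null_tag, alt_tag in pairings:
            null, alt, test = fit_lrt_pair(
                aln, tree, null_tag, alt_tag,
                config.model["n_beta_classes"], pi_mode, m0,
            )
            fits[null_tag], fits[alt_tag] = null, alt
            for f in (null, alt):
                rows.append(
                    {
                        "model": f.model_tag,
                        "log_likelihood": f.log_likelihood,
                        "kappa": f.kappa,
                        "omega": f.omega,
                        "n_params": f.n_params,
                        "converged": f.converged,
                    }
                )
            lrt_rows.append(
                {
                    "null": null_tag, "alt": alt_tag,
                    "stat": test.stat, "df": test.df, "p_value": test.p_value,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "models.tsv", sep="\t", index=False)
        pd.DataFrame(lrt_rows).to_csv(outdir / "lrt.tsv", sep="\t", index=False)
        stages["site_models"] = "ok"

        track = site_posteriors(
            fits["M8"], aln, method=config.model["posterior_method"]
        )
        track.to_frame().to_csv(outdir / "sites.tsv", sep="\t", index=False)
        stages["posteriors"] = "ok"

        structure_path = gene.get("structure")
        if structure_path:
            reference = gene.get("reference_taxon", config.reference_taxon)
            if reference is None:
                raise ConfigError(f"{name}: structure given but no reference taxon")
            inputs["structure"] = _sha256(structure_path)
            model = read_structure(structure_path)
            contexts = classify(
                model,
                plddt_threshold=config.thresholds["plddt_disorder"],
            )
            col_map = column_residue_map(aln, reference)
            ref_aa = reference_residue_aas(aln, reference)
            records, report = join(
                track, col_map, ref_aa, contexts,
                numbering_offset=int(gene.get("numbering_offset", 0)),
                gene=name, lineage=gene.get("lineage", ""),
            )
            records_to_frame(records).to_csv(
                outdir / "records.tsv", sep="\t", index=False
            )
            enrichment_summary(
                records, config.thresholds["significance"]
            ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            export_attributes(
                records,
                outdir / "omega.defattr",
                cap=config.thresholds["display_cap"],
            )
            with open(outdir / "join_report.json", "w") as fh:
                json.dump(report, fh, indent=1, sort_keys=True)
            stages["structure_join"] = "ok"
        _write_manifest(outdir / "manifest.json", config, inputs, stages)
        return {"gene": name, "excluded": False, "outdir": name}
    except Exception:
        stages["FAILED"] = "see traceback"
        _write_manifest(outdir / "manifest.json", config, inputs, stages)
        raise


def run_paralog(config: RunConfig, pair: dict) -> dict:
    """Matched-residue delta-omega comparison for one paralog pair."""
    name = pair["name"]
    outdir = config.output_dir / name
    outdir.mkdir(parents=True, exist_ok=True)
    model_a = read_structure(pair["structure_a"])
    model_b = read_structure(pair["structure_b"])
    matches, quality = match_residues(model_a, model_b)
    track_a = _read_omega_track(pair["track_a"])
    track_b = _read_omega_track(pair["track_b"])
    table, summary = delta_omega_table(matches, track_a, track_b)
    table.to_csv(outdir / "delta_omega.tsv", sep="\t", index=False)
    export_delta_attributes(table, outdir / "delta_omega.defattr")
    result = {
        "pair": name,
        "tm_score": quality.tm_score,
        "coverage": quality.coverage,
        "rmsd": quality.rmsd,
        "usable": quality.usable,
        "n_pairs": summary.n_pairs,
        "n_higher_a": summary.n_higher_a,
        "n_higher_b": summary.n_higher_b,
        "n_tied": summary.n_tied,
        "mean_delta": summary.mean_delta,
        "t_statistic": summary.t_statistic,
        "p_value": summary.p_value,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result, fh, indent=1, sort_keys=True)
    return result


def _read_omega_track(path: str | Path) -> dict[int, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["residue"].astype(int), df["omega"].astype(float)))


def run_mk(config: RunConfig, entry: dict) -> pd.DataFrame:
    """MK / DoS report for one population set, optionally per region."""
    name = entry["name"]
    outdir = config.output_dir / name
    outdir.mkdir(parents=True, exist_ok=True)
    population = read_codon_fasta(entry["ingroup"])
    from Bio import SeqIO

    out_records = list(SeqIO.parse(str(entry["outgroup"]), "fasta"))
    if len(out_records) != 1:
        raise ConfigError(f"{name}: outgroup FASTA must hold exactly one record")
    outgroup = str(out_records[0].seq).upper()
    regions = entry.get("regions") or {
        "whole_gene": [[1, population.site_count]]
    }
    regions = {k: [tuple(r) for r in v] for k, v in regions.items()}
    table = mk_by_region(population, outgroup, regions)
    table.to_csv(outdir / "mk.tsv", sep="\t", index=False)
    return table


def run_all(config: RunConfig) -> dict:
    """Run every configured gene, paralog pair and MK set."""
    config.validate_paths()
    config.output_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"genes": [], "paralogs": [], "mk": []}
    for gene in config.genes:
        results["genes"].append(run_gene(config, gene))
    for pair in config.paralogs:
        results["paralogs"].append(run_paralog(config, pair))
    for entry in config.mk:
        run_mk(config, entry)
        results["mk"].append(entry["name"])
    with open(config.output_dir / "run_summary.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=str)
    return results
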