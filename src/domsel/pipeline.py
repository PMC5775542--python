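"""End-to-end orchestration: per-gene fits through species-level reports.

``run_pipeline`` consumes a directory with one subdirectory per species
(each holding ``<gene>.fasta`` / ``<gene>.nwk`` pairs) plus a species Ne
table, and writes five result tables and a JSON run manifest:

* ``gene_fits.tsv``        - per-gene model fits and LRT results
* ``species_summary.tsv``  - per-species mean omegas and D/W ratios
* ``dynamics_counts.tsv``  - gene counts per selection-dynamics category
* ``mutation_counts.tsv``  - radical/conservative/synonymous counts and
                             per-species G-tests
* ``correlations.tsv``     - accumulation metrics vs Ne

Genes that fail validation or fitting are recorded in the manifest and
excluded from downstream tables; they are never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dynamics import (dynamics_table, species_table, summarize_species)
from .fitting import FitConfig, apply_bh, fit_gene
from .io import (list_study_genes, read_codon_fasta, read_ne_table,
                 read_tagged_newick, write_json)
from .parsimony import (CONSERVATIVE, RADICAL, SYNONYMOUS,
                        LineageMutationCounts, assign_branch_substitutions,
                        count_lineage_mutations)
from .properties import DEFAULT_SCHEMES, PropertyScheme
from .stats import correlate_metrics, g_test
from .trees import DOMESTIC, WILD

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; dumped into the manifest."""

    data_dir: str = "."
    ne_table: str | None = None
    out_dir: str = "results"
    p_threshold: float = 0.05
    multiple_testing: str = "none"        # none | BH
    freq_model: str = "F3X4"
    omega_bounds: tuple = (1e-4, 999.0)
    optimize_branch_lengths: bool = True
    n_restarts: int = 0
    dynamics_tol: float = 1e-9
    log10_ne: bool = False
    schemes: tuple = DEFAULT_SCHEMES
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.multiple_testing not in ("none", "BH"):
            raise ValueError("multiple_testing must be 'none' or 'BH'")

    def fit_config(self) -> FitConfig:
        return FitConfig(
            freq_model=self.freq_model,
            omega_bounds=self.omega_bounds,
            optimize_branch_lengths=self.optimize_branch_lengths,
            n_restarts=self.n_restarts,
            p_threshold=self.p_threshold,
            seed=self.seed,
        )


@dataclass
class PipelineResult:
    gene_fits: pd.DataFrame
    species_summaries: list
    species_df: pd.DataFrame
    dynamics_df: pd.DataFrame
    mutation_df: pd.DataFrame
    correlation_df: pd.DataFrame | None
    manifest: dict


def _load_schemes(raw) -> tuple:
    if raw and isinstance(raw[0], PropertyScheme):
        return tuple(raw)
    return tuple(PropertyScheme.from_dict(name, mapping)
                 for name, mapping in raw)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run fits, counting, summaries, tests and correlations; write tables."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schemes = _load_schemes(config.schemes)
    fit_cfg = config.fit_config()

    genes_by_species = list_study_genes(config.data_dir)
    if not genes_by_species:
        raise ValueError(f"no species/gene inputs under {config.data_dir}")

    gene_rows = []
    failures = []
    summaries = []
    mutation_rows = []

    for species, genes in genes_by_species.items():
        results, counts = [], []
        for gene_id, fasta, nwk in genes:
            try:
                aln = read_codon_fasta(fasta, gene_id=gene_id)
                tree = read_tagged_newick(nwk)
                res = fit_gene(aln, tree, fit_cfg)
                subs = assign_branch_substitutions(aln, tree)
                cnt = count_lineage_mutations(subs, tree, schemes)
            except (ValueError, FileNotFoundError) as exc:
                logger.warning("%s/%s failed: %s", species, gene_id, exc)
                failures.append({"species": species, "gene_id": gene_id,
                                 "error": str(exc)})
                continue
            logger.info("%s/%s: p=%.3g omega_W=%.3g omega_D=%.3g",
                        species, gene_id, res.p_value, res.omega_W,
                        res.omega_D)
            results.append(res)
            counts.append(cnt)
        if config.multiple_testing == "BH":
            apply_bh(results, config.p_threshold)
        for res in results:
            row = res.tsv_row()
            row["species"] = species
            row["converged"] = res.converged
            gene_rows.append(row)
        summary = summarize_species(results, counts, species,
                                    config.dynamics_tol)
        summaries.append(summary)

        sig_counts = sum((c for r, c in zip(results, counts) if r.significant),
                         start=LineageMutationCounts())
        row = {"species": species}
        for cls, label in ((DOMESTIC, "D"), (WILD, "W")):
            for kind in (RADICAL, CONSERVATIVE, SYNONYMOUS):
                row[f"{label}_{kind.lower()}"] = sig_counts.get(cls, kind)
        table = [[sig_counts.get(DOMESTIC, RADICAL),
                  sig_counts.get(DOMESTIC, CONSERVATIVE)],
                 [sig_counts.get(WILD, RADICAL),
                  sig_counts.get(WILD, CONSERVATIVE)]]
        try:
            g, p = g_test(table)
            row["g_stat"], row["g_p"] = g, p
        except ValueError as exc:
            logger.warning("%s: G-test undefined (%s)", species, exc)
            row["g_stat"], row["g_p"] = float("nan"), float("nan")
        mutation_rows.append(row)

    gene_df = pd.DataFrame(gene_rows)
    species_df = species_table(summaries)
    dyn_df = dynamics_table(summaries)
    mut_df = pd.DataFrame(mutation_rows)

    corr_df = None
    if config.ne_table:
        ne_records = read_ne_table(config.ne_table)
        known = {r.species for r in ne_records}
        missing = [s.species for s in summaries if s.species not in known]
        if missing:
            logger.warning("species without Ne (excluded from correlation): %s",
                           missing)
        reports = correlate_metrics(summaries, ne_records,
                                    log10_ne=config.log10_ne, strict=False)
        corr_df = pd.DataFrame([{"metric": r.metric, "n": r.n, "r": r.r,
                                 "p": r.p} for r in reports])

    manifest = {
        "config": _config_dict(config),
        "version": __version__,
        "n_genes_input": sum(len(g) for g in genes_by_species.values()),
        "n_genes_fitted": len(gene_rows),
        "failures": failures,
        "unconverged_genes": sorted(
            r["gene_id"] for r in gene_rows if not r.get("converged", True)),
    }

    gene_df.to_csv(out_dir / "gene_fits.tsv", sep="\t", index=False)
    species_df.to_csv(out_dir / "species_summary.tsv", sep="\t", index=False)
    dyn_df.to_csv(out_dir / "dynamics_counts.tsv", sep="\t",
                  index_label="species")
    mut_df.to_csv(out_dir / "mutation_counts.tsv", sep="\t", index=False)
    if corr_df is not None:
        corr_df.to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
    write_json(manifest, out_dir / "manifest.json")
    write_json({
        "species_summary": species_df.to_dict(orient="records"),
        "dynamics_counts": dyn_df.reset_index(names="species")
                                 .to_dict(orient="records"),
    }, out_dir / "summary.json")

    return PipelineResult(gene_df, summaries, species_df, dyn_df, mut_df,
                          corr_df, manifest)


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["schemes"] = [
        {"name": s.name,
         "categories": {c: "".join(sorted(m)) for c, m in s.categories}}
        for s in _load_schemes(config.schemes)]
    return d
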