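"""Readers and writers for the pipeline's file formats.

Alignments are aligned FASTA (one file per gene), trees are Newick in
the ``#1`` branch-tag dialect, the Ne table is a two-column TSV, and all
result tables are TSV.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .alignment import CodonAlignment
from .simulate import StudyBundle
from .stats import NeRecord
from .trees import TaggedTree


def read_codon_fasta(path, gene_id: str | None = None) -> CodonAlignment:
    """Read one gene's aligned FASTA into a validated CodonAlignment."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    taxa = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return CodonAlignment(gene_id or path.stem, taxa, seqs)


def write_codon_fasta(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_tagged_newick(path) -> TaggedTree:
    text = Path(path).read_text().strip()
    return TaggedTree.from_newick(text)


def write_tagged_newick(tree: TaggedTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_ne_table(path) -> list:
    """Read the species Ne TSV (header: species<TAB>ne_recent)."""
    df = pd.read_csv(path, sep="\t")
    required = {"species", "ne_recent"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: Ne table needs columns {sorted(required)}")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"{path}: duplicate species {dups}")
    return [NeRecord(row.species, float(row.ne_recent))
            for row in df.itertuples()]


def write_ne_table(ne_by_species: dict, path) -> None:
    pd.DataFrame(
        {"species": list(ne_by_species), "ne_recent": list(ne_by_species.values())}
    ).to_csv(path, sep="\t", index=False)


def write_history_tsv(history, path) -> None:
    """Serialise a simulated gene's true substitution events."""
    rows = [{"branch_id": e.branch_id, "site": e.site,
             "from_codon": e.from_codon, "to_codon": e.to_codon,
             "synonymous": e.synonymous} for e in history.events]
    pd.DataFrame(rows, columns=["branch_id", "site", "from_codon",
                                "to_codon", "synonymous"]
                 ).to_csv(path, sep="\t", index=False)


def write_study(bundle: StudyBundle, out_dir) -> None:
    """Materialise a simulated study in the pipeline's input layout.

    One subdirectory per species holding ``<gene>.fasta`` and
    ``<gene>.nwk`` pairs, a shared ``ne.tsv``, and per-gene true-history
    TSVs plus a true-effect table under ``truth/``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for species, data in bundle.species_data.items():
        sp_dir = out / species
        sp_dir.mkdir(exist_ok=True)
        for aln, tree, hist in zip(data.alignments, data.trees, data.histories):
            write_codon_fasta(aln, sp_dir / f"{aln.gene_id}.fasta")
            write_tagged_newick(tree, sp_dir / f"{aln.gene_id}.nwk")
            write_history_tsv(hist, truth_dir / f"{aln.gene_id}.history.tsv")
    write_ne_table(bundle.ne_records, out / "ne.tsv")
    effects = pd.DataFrame({
        "species": list(bundle.true_effects),
        "expected_log_omega_ratio": list(bundle.true_effects.values()),
    })
    effects.to_csv(truth_dir / "true_effects.tsv", sep="\t", index=False)


def list_study_genes(data_dir) -> dict:
    """Map species -> list of (gene_id, fasta path, newick path)."""
    data_dir = Path(data_dir)
    out = {}
    for sp_dir in sorted(p for p in data_dir.iterdir() if p.is_dir()):
        if sp_dir.name == "truth":
            continue
        genes = []
        for fasta in sorted(sp_dir.glob("*.fasta")):
            nwk = fasta.with_suffix(".nwk")
            if not nwk.exists():
                raise FileNotFoundError(f"no tree for {fasta}")
            genes.append((fasta.stem, fasta, nwk))
        if genes:
            out[sp_dir.name] = genes
    return out


def write_gene_counts_tsv(records, path) -> None:
    """Per-gene, per-branch-class substitution counts.

    ``records`` is an iterable of (species, gene_id, LineageMutationCounts).
    """
    from .parsimony import CONSERVATIVE, RADICAL, SYNONYMOUS
    from .trees import DOMESTIC, WILD

    rows = []
    for species, gene_id, counts in records:
        for cls in (DOMESTIC, WILD):
            rows.append({
                "species": species, "gene_id": gene_id, "class": cls,
                "radical": counts.get(cls, RADICAL),
                "conservative": counts.get(cls, CONSERVATIVE),
                "synonymous": counts.get(cls, SYNONYMOUS),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_counts_tsv(path):
    """Inverse of :func:`write_gene_counts_tsv`:
    {(species, gene_id): LineageMutationCounts}."""
    from .parsimony import (CONSERVATIVE, RADICAL, SYNONYMOUS,
                            LineageMutationCounts)

    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.to_dict("records"):
        key = (row["species"], row["gene_id"])
        counts = out.setdefault(key, LineageMutationCounts())
        counts.counts[row["class"]][RADICAL] = row["radical"]
        counts.counts[row["class"]][CONSERVATIVE] = row["conservative"]
        counts.counts[row["class"]][SYNONYMOUS] = row["synonymous"]
    return out


def _json_default(obj):
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default,
                                     sort_keys=True) + "\n")
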