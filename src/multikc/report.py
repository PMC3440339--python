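"""End-to-end run orchestration and paper-shaped report tables.

``run_full`` wires every stage — simulate (or ingest) reads per sample,
multi-k/multi-C assembly with redundancy depletion, read-back mapping and
abundance, cascade annotation — and emits diff-able TSV tables (assembly/
annotation summary, taxon distribution, gene-set recovery, top-10 abundance,
full abundance) plus a JSON manifest recording parameters, seed and file
checksums.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
import pandas as pd

from . import __version__
from .annotate import (AnnotationParams, annotate_contigs, gene_set_recovery,
                       nonredundant_top_hits, overlap_summary,
                       taxon_distribution, tier_counts)
from .assembly import AssemblyParams
from .cluster import ClusterParams
from .mapping import MappingParams, abundance_records, map_reads, top_n_table
from .pipeline import GridSpec, n50, run_multikc_detailed
from .sim import (SimulationParams, generate_reference, simulate_reads,
                  write_fastq, write_reference_fasta)


@dataclass(frozen=True)
class RunConfig:
    seed: int
    sample_names: tuple = ("gut", "wa")
    simulation: SimulationParams = None  # seed field is overridden by `seed`
    grid: GridSpec = GridSpec()
    cluster: ClusterParams = ClusterParams()
    mapping: MappingParams = MappingParams()
    annotation: AnnotationParams = AnnotationParams()
    output_dir: str = "multikc_out"
    min_contig_len: int = 100
    top_n: int = 10

    def validate(self) -> None:
        if not self.sample_names:
            raise ValueError("sample_names must be non-empty")
        if len(set(self.sample_names)) != len(self.sample_names):
            raise ValueError("sample_names must be unique")
        sim = self.simulation or SimulationParams(seed=self.seed)
        sim.validate()
        self.grid.validate()
        self.cluster.validate()
        self.mapping.validate()
        self.annotation.validate()


def config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a plain (e.g. YAML-loaded) dictionary."""
    seed = int(d["seed"])
    sim_d = dict(d.get("simulation", {}))
    sim_d.setdefault("seed", seed)
    grid_d = d.get("grid", {})
    return RunConfig(
        seed=seed,
        sample_names=tuple(d.get("sample_names", ("gut", "wa"))),
        simulation=SimulationParams(**sim_d),
        grid=GridSpec(
            k_values=tuple(grid_d.get("k_values", GridSpec.k_values)),
            C_values=tuple(float(c) for c in grid_d.get("C_values", GridSpec.C_values)),
        ),
        cluster=ClusterParams(**d.get("cluster", {})),
        mapping=MappingParams(**d.get("mapping", {})),
        annotation=AnnotationParams(**d.get("annotation", {})),
        output_dir=str(d.get("output_dir", "multikc_out")),
        min_contig_len=int(d.get("min_contig_len", 100)),
        top_n=int(d.get("top_n", 10)),
    )


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _abundance_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [{"contig_id": r.contig_id, "n_reads_assembled": r.n_reads_assembled,
          "contig_len": r.contig_len, "depth": f"{r.depth:.2f}", "rank": r.rank}
         for r in records],
        columns=["contig_id", "n_reads_assembled", "contig_len", "depth", "rank"],
    )


def run_full(config: RunConfig) -> dict:
    """Run the whole pipeline for every sample and emit the report bundle."""
    config.validate()
    sim_base = config.simulation or SimulationParams(seed=config.seed)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    reference = generate_reference(replace(sim_base, seed=config.seed))
    write_reference_fasta(reference, out / "reference.fasta")
    groups = {r.id: r.gene_group for r in reference if r.gene_group is not None}

    bundle: dict = {"reference": reference, "samples": {}, "paths": {}}
    stats_rows = []
    nonred_sets: dict[str, set] = {}
    counters: dict[str, dict] = {}

    for i, name in enumerate(config.sample_names):
        stage = "simulate"
        try:
            sim_i = replace(sim_base, seed=config.seed + i + 1)
            reads = simulate_reads(reference, sim_i)
            write_fastq(reads, out / f"reads_{name}.fastq")

            stage = "multikc"
            asm_defaults = AssemblyParams(
                k=31, C=6.0, min_contig_len=config.min_contig_len, sample=name)
            final, per_cell, log = run_multikc_detailed(
                reads, config.grid, config.cluster, asm_defaults)
            final.write_fasta(out / f"contigs_{name}.fasta")
            cell_dir = out / f"cells_{name}"
            cell_dir.mkdir(exist_ok=True)
            for (k, C), cs in per_cell.items():
                cs.write_fasta(cell_dir / f"contigs_k{k}_C{C:g}.fasta")

            stage = "map"
            mres = map_reads(reads, final, config.mapping)
            for c in final:
                c.n_reads_assembled = mres.counts[c.id]
            records = abundance_records(mres, final, sim_i.read_length)
            top = top_n_table(records, config.top_n)

            stage = "annotate"
            hits = annotate_contigs(final, reference, config.annotation)
            tiers = tier_counts(hits)
            nonred = nonredundant_top_hits(hits)
            nonred_sets[name] = set(nonred)
            taxa = taxon_distribution(hits)
            recovery, n_ungrouped = gene_set_recovery(hits, groups)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed for sample {name!r}: {e}") from e

        lengths = final.lengths()
        stats_rows.append({
            "sample": name,
            "n_contigs": len(lengths),
            "mean_len": round(sum(lengths) / len(lengths), 1) if lengths else 0.0,
            "longest": max(lengths) if lengths else 0,
            "n50": n50(lengths),
            "frac_ge_500": round(sum(1 for L in lengths if L >= 500) / len(lengths), 4) if lengths else 0.0,
            "reads_covered_frac": round(mres.n_mapped / len(reads), 4) if reads else 0.0,
            "translated_hits": tiers["translated"],
            "nucleotide_hits": tiers["nucleotide"],
            "no_hits": tiers["none"],
            "nonredundant_hits": len(nonred),
        })
        counters[name] = {
            "n_reads": len(reads),
            "reads_mapped": mres.n_mapped,
            "reads_unmapped": mres.n_unmapped,
            "cells": log,
            "hits_ungrouped": n_ungrouped,
        }
        taxa.to_csv(out / f"table2_taxa_{name}.tsv", sep="\t", index=False)
        recovery.to_csv(out / f"table3_recovery_{name}.tsv", sep="\t", index=False)
        top_frame = _abundance_frame(top.records)
        top_frame.to_csv(out / f"table4_top{config.top_n}_{name}.tsv", sep="\t", index=False)
        with open(out / f"table4_top{config.top_n}_{name}.tsv", "a") as fh:
            fh.write(f"# fold_range\t{top.fold_range}\n")
        _abundance_frame(records).to_csv(
            out / f"table5_abundance_{name}.tsv", sep="\t", index=False)
        bundle["samples"][name] = {
            "reads": reads, "contigs": final, "mapping": mres,
            "abundance": records, "top": top, "hits": hits,
            "taxa": taxa, "recovery": recovery,
        }

    pd.DataFrame(stats_rows).to_csv(out / "table1_stats.tsv", sep="\t", index=False)

    if len(config.sample_names) >= 2:
        a, b = config.sample_names[0], config.sample_names[1]
        ov = overlap_summary(nonred_sets[a], nonred_sets[b])
        pd.DataFrame([ov]).to_csv(out / "overlap.tsv", sep="\t", index=False)
        bundle["overlap"] = ov

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "multikc",
        "version": __version__,
        "seed": config.seed,
        "sample_names": list(config.sample_names),
        "params": {
            "simulation": asdict(replace(sim_base, seed=config.seed)),
            "grid": {"k_values": list(config.grid.k_values),
                     "C_values": list(config.grid.C_values)},
            "cluster": asdict(config.cluster),
            "mapping": asdict(config.mapping),
            "annotation": asdict(config.annotation),
        },
        "counters": counters,
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["paths"] = {"output_dir": out, "manifest": out / "manifest.json"}
    return bundle
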