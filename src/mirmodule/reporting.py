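"""Pipeline orchestration, summary reports and the run manifest.

The pipeline runs preprocess -> annotate -> novel discovery -> quantify/DE
-> target prediction -> module integration, each stage writing plain-text
outputs (TSV/FASTA/GFF3/JSON) into a run directory.  Runs are resumable:
simulated inputs already on disk are reused, and because every analysis
stage is deterministic, re-running after deleting any intermediate
reproduces byte-identical outputs.  A manifest records the config
snapshot, per-stage record counts and a checksum of every output file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from mirmodule import __version__, annotate, integrate, novel_discovery, quant_de
from mirmodule import preprocess as pp
from mirmodule import synthetic_data as synth
from mirmodule import target_predict
from mirmodule._seq import read_fasta_dict, write_fasta
from mirmodule.integrate import summarize_percentages


@dataclass
class PipelineResult:
    """In-memory outputs of a full pipeline run."""

    libraries: list[str]
    tags: dict[str, pp.CleanTag]
    stats: dict[str, pp.LibraryStats]
    annotated: list[annotate.AnnotatedTag]
    annotation_summary: dict[str, dict[str, int]]
    family_reference: annotate.FamilyReference
    novel: list[novel_discovery.NovelMirna]
    known_records: list[quant_de.ExpressionRecord]
    novel_records: list[quant_de.ExpressionRecord]
    sites: list[target_predict.TargetSite]
    modules: list[integrate.Module]
    module_summary: dict[str, Any]
    hubs: list[integrate.HubScore]
    known_verdicts: dict[str, str] = field(default_factory=dict)


def run_in_memory(
    libraries: Mapping[str, Mapping[str, int]],
    genome: Mapping[str, str],
    mature_reference: Mapping[str, str],
    structural_references: Mapping[str, Mapping[str, str]] | None = None,
    transcripts: Mapping[str, str] | None = None,
    gene_de: Mapping[str, str] | None = None,
    adapter_3p: str = "",
    adapter_5p: str = "",
    target_cutoff: float = target_predict.DEFAULT_CUTOFF,
    verify_known: bool = False,
) -> PipelineResult:
    """Run the whole analysis on in-memory inputs.

    *libraries* maps library id to a read multiset (sequence -> count);
    exactly two libraries are required and are compared in sorted order
    (first = reference/control condition A).
    """
    lib_ids = sorted(libraries)
    if len(lib_ids) != 2:
        raise ValueError("exactly two libraries are required")
    lib_a, lib_b = lib_ids

    per_lib: dict[str, dict[str, pp.CleanTag]] = {}
    stats: dict[str, pp.LibraryStats] = {}
    for lib in lib_ids:
        reads = ((f"r{i}", seq, count) for i, (seq, count) in enumerate(sorted(libraries[lib].items())))
        tags_l, stats_l = pp.clean_reads(reads, lib, adapter_3p=adapter_3p, adapter_5p=adapter_5p)
        per_lib[lib] = tags_l
        stats[lib] = stats_l
    tags = pp.merge_libraries(per_lib)

    refs: list[annotate.ReferenceSet] = [
        annotate.ReferenceSet(category="miRNA_mature", records=dict(mature_reference))
    ]
    for category, records in sorted((structural_references or {}).items()):
        refs.append(annotate.ReferenceSet(category=category, records=dict(records)))
    annotated, summary = annotate.classify_tags(tags, refs)

    mature_db = refs[0]
    family_ref = annotate.build_family_reference(annotated, mature_db)

    known_loci = novel_discovery.map_to_genome(
        set(mature_reference.values()), genome
    )
    exclude = [loc for loci in known_loci.values() for loc in loci]
    unannotated = [at.tag.seq for at in annotated if at.category == "unannotated"]
    novel, _pseudo = novel_discovery.discover_novel(unannotated, genome, exclude=exclude)

    totals = {lib: stats[lib].clean_reads for lib in lib_ids}
    known_counts = quant_de.count_known(tags, family_ref, lib_ids)
    known_records = quant_de.call_de(
        quant_de.quantify(known_counts, totals, lib_a, lib_b, "known")
    )
    novel_matures = {nm.mirna_id: nm.mature_seq for nm in novel}
    novel_counts = quant_de.count_novel(tags, novel_matures, lib_ids)
    novel_records = quant_de.call_de(
        quant_de.quantify(novel_counts, totals, lib_a, lib_b, "novel")
    )

    sites: list[target_predict.TargetSite] = []
    modules: list[integrate.Module] = []
    module_summary: dict[str, Any] = {}
    hubs: list[integrate.HubScore] = []
    if transcripts:
        mirna_seqs = dict(family_ref.sequences())
        mirna_seqs.update(novel_matures)
        de_ids = {
            r.mirna_id
            for r in known_records + novel_records
            if r.status in ("up", "down")
        }
        sites = target_predict.scan_transcriptome(
            {mid: seq for mid, seq in mirna_seqs.items() if mid in de_ids},
            transcripts,
            cutoff=target_cutoff,
        )
        if gene_de is not None:
            modules, module_summary = integrate.pair_modules(
                known_records + novel_records, sites, gene_de
            )
            hubs = integrate.rank_hubs(modules)

    verdicts: dict[str, str] = {}
    if verify_known:
        expressed = {
            r.mirna_id: family_ref.sequences()[r.mirna_id]
            for r in known_records
            if r.count_A + r.count_B > 0
        }
        verdicts = novel_discovery.verify_known_hairpins(expressed, genome)

    return PipelineResult(
        libraries=lib_ids,
        tags=tags,
        stats=stats,
        annotated=annotated,
        annotation_summary=summary,
        family_reference=family_ref,
        novel=novel,
        known_records=known_records,
        novel_records=novel_records,
        sites=sites,
        modules=modules,
        module_summary=module_summary,
        hubs=hubs,
        known_verdicts=verdicts,
    )


# ---------------------------------------------------------------------------
# reports


def de_tally(records: list[quant_de.ExpressionRecord], lib_a: str, lib_b: str) -> dict[str, Any]:
    """DE accounting for one miRNA class, in the shared-set style.

    ``n_shared`` counts miRNAs detected (count > 0) in both libraries;
    DE fractions are reported against the shared set and the up fraction
    against the DE set.
    """
    shared = [r for r in records if r.count_A > 0 and r.count_B > 0]
    de = [r for r in records if r.status in ("up", "down")]
    up = [r for r in de if r.status == "up"]
    return {
        "n_quantified": len(records),
        f"n_detected_{lib_a}": sum(1 for r in records if r.count_A > 0),
        f"n_detected_{lib_b}": sum(1 for r in records if r.count_B > 0),
        "n_shared": len(shared),
        "n_DE": len(de),
        "pct_DE_of_shared": summarize_percentages(len(de), len(shared)) if shared else 0.0,
        "n_up": len(up),
        "pct_up_of_DE": summarize_percentages(len(up), len(de)) if de else 0.0,
    }


def make_reports(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Paper-style summary tables from pipeline outputs.

    Returns the annotation category table (unique/total counts with
    percentages), per-library length distributions, DE tallies per miRNA
    class, and the module relation summary.  Sections whose stage did
    not run come back empty rather than failing.
    """
    reports: dict[str, pd.DataFrame] = {}
    reports["annotation"] = annotate.annotation_table(result.annotation_summary)

    rows = []
    for lib in result.libraries:
        dist = pp.length_distribution(result.tags, lib)
        for length, frac in dist.items():
            rows.append({"library_id": lib, "length": length, "fraction": round(frac, 6)})
    reports["length_distribution"] = pd.DataFrame(rows, columns=["library_id", "length", "fraction"])

    lib_a, lib_b = result.libraries
    tally_rows = []
    for cls, records in (("known", result.known_records), ("novel", result.novel_records)):
        row: dict[str, Any] = {"class": cls}
        row.update(de_tally(records, lib_a, lib_b))
        tally_rows.append(row)
    reports["de_tally"] = pd.DataFrame(tally_rows)

    if result.module_summary:
        ms = result.module_summary
        mrows = [
            {
                "relation": rel,
                "n": ms["by_relation"][rel],
                "pct": ms["relation_pct"][rel],
            }
            for rel in integrate.RELATIONS
        ]
        mrows.append({"relation": "inverse_total", "n": ms["n_inverse"], "pct": ms["inverse_pct"]})
        reports["module_summary"] = pd.DataFrame(mrows)
    else:
        reports["module_summary"] = pd.DataFrame(columns=["relation", "n", "pct"])
    return reports


def plot_length_distribution(result: PipelineResult, path: str | Path) -> bool:
    """Optional bar plot of per-library length distributions.

    TSV is the canonical report format; this helper renders the same
    numbers when matplotlib is installed and quietly returns False when
    it is not (headless-safe).
    """
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return False
    fig, axes = plt.subplots(1, len(result.libraries), figsize=(5 * len(result.libraries), 3.5))
    if len(result.libraries) == 1:
        axes = [axes]
    for ax, lib in zip(axes, result.libraries):
        dist = pp.length_distribution(result.tags, lib)
        ax.bar(list(dist), list(dist.values()), color="#4878a8")
        ax.set_title(lib)
        ax.set_xlabel("read length (nt)")
        ax.set_ylabel("fraction of clean reads")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return True


# ---------------------------------------------------------------------------
# file-based orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping[str, Any], outdir: str | Path, resume: bool = False) -> dict[str, Any]:
    """Run the pipeline end to end from a config mapping, writing all outputs.

    The config either carries a ``simulate`` section (a
    :class:`~mirmodule.synthetic_data.SimulationConfig` as a mapping) or
    an ``inputs`` section with paths to reads (two libraries), genome,
    mature reference, optional structural references, transcripts and a
    gene DE table.  Returns the manifest, which is also written as
    ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"])
        fc = sim_kwargs.pop("fc_distribution", None)
        if fc is not None:
            sim_kwargs["fc_distribution"] = synth.FoldChangeDistribution(**fc)
        sim_cfg = synth.SimulationConfig(seed=seed, **sim_kwargs)
        inputs_dir = outdir / "inputs"
        marker = inputs_dir / "truth.tsv"
        if not (resume and marker.exists()):
            dataset = synth.simulate_all(sim_cfg)
            synth.write_dataset(dataset, inputs_dir)
        paths = {
            "reads": {
                sim_cfg.library_A: inputs_dir / f"{sim_cfg.library_A}.fa",
                sim_cfg.library_B: inputs_dir / f"{sim_cfg.library_B}.fa",
            },
            "genome": inputs_dir / "genome.fa",
            "mature": inputs_dir / "mature_reference.fa",
            "structural": {
                c: inputs_dir / f"{c}.fa" for c in ("rRNA", "tRNA", "snRNA", "snoRNA")
            },
            "transcripts": inputs_dir / "transcripts.fa",
            "gene_de": inputs_dir / "gene_de.tsv",
        }
    else:
        inp = config["inputs"]
        paths = {
            "reads": {lib: Path(p) for lib, p in inp["reads"].items()},
            "genome": Path(inp["genome"]),
            "mature": Path(inp["mature"]),
            "structural": {c: Path(p) for c, p in inp.get("structural", {}).items()},
            "transcripts": Path(inp["transcripts"]) if inp.get("transcripts") else None,
            "gene_de": Path(inp["gene_de"]) if inp.get("gene_de") else None,
        }

    libraries = {
        lib: {seq: count for _rid, seq, count in _read_counted(p)}
        for lib, p in paths["reads"].items()
    }
    genome = read_fasta_dict(paths["genome"])
    mature = read_fasta_dict(paths["mature"])
    structural = {
        c: read_fasta_dict(p)
        for c, p in paths["structural"].items()
        if Path(p).exists()
    }
    transcripts = (
        read_fasta_dict(paths["transcripts"])
        if paths.get("transcripts") and Path(paths["transcripts"]).exists()
        else None
    )
    gene_de = (
        integrate.read_gene_de(paths["gene_de"])
        if paths.get("gene_de") and Path(paths["gene_de"]).exists()
        else None
    )

    adapters = config.get("adapters", {})
    result = run_in_memory(
        libraries,
        genome,
        mature,
        structural_references=structural,
        transcripts=transcripts,
        gene_de=gene_de,
        adapter_3p=adapters.get("three_prime", ""),
        adapter_5p=adapters.get("five_prime", ""),
        target_cutoff=float(config.get("target_cutoff", target_predict.DEFAULT_CUTOFF)),
        verify_known=bool(config.get("verify_known", False)),
    )
    outputs = write_outputs(result, outdir)

    manifest: dict[str, Any] = {
        "tool_version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "stage_counts": {
            "clean_reads": {lib: result.stats[lib].clean_reads for lib in result.libraries},
            "unique_tags": len(result.tags),
            "known_mirnas": len(result.known_records),
            "novel_mirnas": len(result.novel),
            "target_sites": len(result.sites),
            "modules": len(result.modules),
        },
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(outputs)},
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


def _read_counted(path: Path):
    from mirmodule._seq import read_sequences

    return read_sequences(path)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_outputs(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Write every stage output under *outdir*; returns the file list."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    for lib in result.libraries:
        pp.write_tags(result.tags, _w(outdir / f"tags_{lib}.fa"), library_id=lib)
    pp.stats_table(result.stats.values()).to_csv(
        _w(outdir / "library_stats.tsv"), sep="\t", index=False
    )

    ann_rows = [
        {
            "seq": at.tag.seq,
            "category": at.category,
            "matched_id": at.matched_id or "",
            "mismatches": at.mismatches,
            **{f"count_{lib}": at.tag.counts.get(lib, 0) for lib in result.libraries},
        }
        for at in result.annotated
    ]
    pd.DataFrame(ann_rows).to_csv(_w(outdir / "annotated_tags.tsv"), sep="\t", index=False)
    annotate.annotation_table(result.annotation_summary).to_csv(
        _w(outdir / "annotation_summary.tsv"), sep="\t", index=False
    )
    write_fasta(
        [(rid, seq) for _fam, (rid, seq) in sorted(result.family_reference.representatives.items())],
        _w(outdir / "family_reference.fa"),
    )

    novel_discovery.write_hairpin_fasta(result.novel, _w(outdir / "novel_hairpins.fa"))
    novel_discovery.write_gff3(result.novel, _w(outdir / "novel_loci.gff3"))
    novel_discovery.write_structures(result.novel, _w(outdir / "novel_structures.txt"))

    quant_de.records_table(result.known_records).to_csv(
        _w(outdir / "expression_known.tsv"), sep="\t", index=False
    )
    quant_de.records_table(result.novel_records).to_csv(
        _w(outdir / "expression_novel.tsv"), sep="\t", index=False
    )

    target_predict.sites_table(result.sites).to_csv(
        _w(outdir / "target_sites.tsv"), sep="\t", index=False
    )
    target_predict.write_alignments(result.sites, _w(outdir / "target_alignments.txt"))

    integrate.modules_table(result.modules).to_csv(
        _w(outdir / "modules.tsv"), sep="\t", index=False
    )
    with open(_w(outdir / "module_summary.json"), "w") as f:
        json.dump(_jsonable(result.module_summary), f, indent=2, sort_keys=True)
    integrate.hubs_table(result.hubs).to_csv(_w(outdir / "hubs.tsv"), sep="\t", index=False)
    if result.modules:
        integrate.export_graph(
            result.modules, _w(outdir / "network.graphml"), _w(outdir / "network_edges.tsv")
        )

    for name, frame in make_reports(result).items():
        frame.to_csv(_w(outdir / f"report_{name}.tsv"), sep="\t", index=False)
    return written
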