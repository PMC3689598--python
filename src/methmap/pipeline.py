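"""End-to-end orchestration: config loading and the all-in-one run.

A run executes simulate-genome -> simulate-library (per protocol x stage)
-> call-sites -> annotate -> compare, writing every artifact plus a
machine-readable manifest into the output directory. A single global seed
fans out to per-stage seeds salted with the stage/protocol name, so any
stage can be rerun in isolation reproducibly; identical configs produce
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import yaml

from . import __version__, io
from .annotate import (GenomeAnnotationIndex, category_fractions,
                       classify_regions, compare_site_sets, coverage_bins,
                       genomic_baseline, summarize_repeats)
from .library_sim import (DEFAULT_ADAPTOR, HELP_COCKTAIL, HME_RDA, ME_RDA,
                          ProtocolConfig, fragments_to_reads, simulate_help,
                          simulate_rda)
from .restriction import DEFAULT_ENZYMES
from .site_caller import PipelineConfig, run_site_calling
from .synthetic_genome import GenomeSpec, MarkModel, assign_methylome, generate_genome

_GENOME_FIELDS = {f.name for f in dataclasses.fields(GenomeSpec)}
_MODEL_FIELDS = {f.name for f in dataclasses.fields(MarkModel)}
_PIPE_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def derive_seed(base_seed: int, salt: str) -> int:
    """Stage-name-salted seed below 2**31, stable across runs."""
    return (int(base_seed) ^ zlib.crc32(salt.encode())) % (2 ** 31)


@dataclasses.dataclass
class RunConfig:
    genome: GenomeSpec
    mark_model: MarkModel
    stages: List[str]
    protocols: List[str]
    coverage: int = 3
    error_rate: float = 0.0
    adaptors: Sequence[str] = (DEFAULT_ADAPTOR,)
    pipeline: Dict[str, object] = dataclasses.field(default_factory=dict)
    bin_bp: int = 100_000
    seed: int = 0
    out_dir: Path = Path("methmap_run")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {"genome", "mark_model", "stages", "protocols", "library",
                 "pipeline", "seed", "out_dir", "bin_bp"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        gdict = dict(raw.get("genome", {}))
        bad = set(gdict) - _GENOME_FIELDS
        if bad:
            raise ValueError(f"unknown genome keys: {sorted(bad)}")
        for key in ("chromosome_lengths",):
            if key in gdict:
                gdict[key] = list(gdict[key])
        for key in ("exons_per_gene", "gene_len", "island_len"):
            if key in gdict:
                gdict[key] = tuple(gdict[key])
        if "interspersed_repeat_classes" in gdict:
            gdict["interspersed_repeat_classes"] = {
                k: tuple(v) for k, v in gdict["interspersed_repeat_classes"].items()}
        mdict = dict(raw.get("mark_model", {}))
        bad = set(mdict) - _MODEL_FIELDS
        if bad:
            raise ValueError(f"unknown mark_model keys: {sorted(bad)}")
        pdict = dict(raw.get("pipeline", {}))
        bad = set(pdict) - _PIPE_FIELDS
        if bad:
            raise ValueError(f"unknown pipeline keys: {sorted(bad)}")
        lib = dict(raw.get("library", {}))
        bad = set(lib) - {"coverage", "error_rate", "adaptors"}
        if bad:
            raise ValueError(f"unknown library keys: {sorted(bad)}")
        return cls(
            genome=GenomeSpec(**gdict),
            mark_model=MarkModel(**mdict),
            stages=list(raw.get("stages", ["D7", "D12"])),
            protocols=[p.upper().replace("-", "_") for p in
                       raw.get("protocols", [ME_RDA, HME_RDA, HELP_COCKTAIL])],
            coverage=int(lib.get("coverage", 3)),
            error_rate=float(lib.get("error_rate", 0.0)),
            adaptors=list(lib.get("adaptors", [DEFAULT_ADAPTOR])),
            pipeline=pdict,
            bin_bp=int(raw.get("bin_bp", 100_000)),
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "methmap_run")),
        )


def protocol_config(protocol: str, enzymes: Mapping[str, object] = DEFAULT_ENZYMES
                    ) -> ProtocolConfig:
    """Default enzyme wiring of each chemistry."""
    if protocol == ME_RDA:
        return ProtocolConfig(ME_RDA, tester_enzyme=enzymes["MspI"],
                              driver_enzyme=enzymes["HpaII"])
    if protocol == HME_RDA:
        return ProtocolConfig(HME_RDA, tester_enzyme=enzymes["FspBI"],
                              driver_enzyme=enzymes["BfaI"])
    if protocol == HELP_COCKTAIL:
        return ProtocolConfig(HELP_COCKTAIL, frequent_cutter=enzymes["TasI"],
                              cocktail=[enzymes["HpaII"], enzymes["AciI"],
                                        enzymes["HinP1I"]])
    raise ValueError(f"unknown protocol {protocol!r}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full run; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = dataclasses.replace(config.genome, seed=derive_seed(config.seed, "genome"))
    genome, ann = generate_genome(spec)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    io.write_fasta(genome, out / "genome.fa")
    io.write_gff3(ann.genes, out / "genes.gff3")
    io.write_repeat_bed(ann.repeats, out / "repeats.bed")
    io.write_repeat_bed(ann.cpg_islands, out / "cpg_islands.bed")

    manifest = {
        "version": __version__, "seed": config.seed,
        "stages": config.stages, "protocols": config.protocols,
        "genome": {"chromosomes": chrom_lengths},
        "libraries": {}, "funnels": {},
    }
    ann_index = GenomeAnnotationIndex(ann.genes, chrom_lengths,
                                      spec.promoter_len)
    baseline = genomic_baseline(ann_index)
    manifest["genomic_baseline"] = baseline

    sites_by_proto_stage: Dict[str, Dict[str, list]] = {}
    for stage in config.stages:
        track = assign_methylome(genome, ann, config.mark_model, stage,
                                 derive_seed(config.seed, f"methylome:{stage}"))
        io.write_truth_set(track, out / f"truth_{stage}.tsv")
        for protocol in config.protocols:
            tag = f"{protocol.lower()}_{stage}"
            pconf = protocol_config(protocol)
            if protocol in (ME_RDA, HME_RDA):
                frags = simulate_rda(genome, track, pconf)
            else:
                frags = simulate_help(genome, track, pconf)
                frags = [f for f in frags if not f.no_internal_site]
            reads = fragments_to_reads(
                frags, config.coverage, config.error_rate,
                (config.adaptors[0] if config.adaptors else "", ""),
                derive_seed(config.seed, f"reads:{tag}"), stage)
            io.write_fasta({r.read_id: r.sequence for r in reads},
                           out / f"reads_{tag}.fa")
            io.write_provenance(
                reads, {f.id: (f.fragment.chrom, f.fragment.start, f.fragment.end,
                               protocol, f.true_left_mark, f.true_right_mark)
                        for f in frags},
                out / f"provenance_{tag}.tsv")
            manifest["libraries"][tag] = {"fragments": len(frags), "reads": len(reads)}

            pipe = PipelineConfig(protocol=protocol, **config.pipeline)
            sites, contigs, report = run_site_calling(
                reads, genome, pipe, stage, adaptors=config.adaptors)
            members = {c.contig_id: c.member_count for c in contigs}
            io.write_sites_bed(sites, out / f"sites_{tag}.bed", members)
            with open(out / f"funnel_{tag}.tsv", "w") as fh:
                fh.write(io.HEADER_PREFIX + "\n")
                for name, value in report.rows():
                    fh.write(f"{name}\t{value}\n")
            manifest["funnels"][tag] = dict(
                (k, v) for k, v in report.__dict__.items())
            sites_by_proto_stage.setdefault(protocol, {})[stage] = sites

            annotated = classify_regions(sites, ann.genes, chrom_lengths,
                                         spec.promoter_len, index=ann_index)
            fracs = category_fractions(annotated)
            with open(out / f"regions_{tag}.tsv", "w") as fh:
                fh.write(io.HEADER_PREFIX + "\n#category\tfraction\tgenomic\n")
                for cat in fracs:
                    fh.write(f"{cat}\t{fracs[cat]:.6f}\t{baseline[cat]:.6f}\n")
            bins = coverage_bins(sites, chrom_lengths, config.bin_bp)
            io.write_bedgraph(bins, config.bin_bp, out / f"coverage_{tag}.bedgraph")

    # stage comparisons per protocol (site-position key)
    with open(out / "stage_overlap.tsv", "w") as fh:
        fh.write(io.HEADER_PREFIX + "\n#protocol\tstageA\tstageB\tonlyA\tshared\tonlyB\n")
        for protocol, by_stage in sites_by_proto_stage.items():
            stages = list(by_stage)
            for i in range(len(stages)):
                for j in range(i + 1, len(stages)):
                    (oa, sh, ob), _ = compare_site_sets(by_stage[stages[i]],
                                                        by_stage[stages[j]])
                    fh.write(f"{protocol}\t{stages[i]}\t{stages[j]}\t{oa}\t{sh}\t{ob}\n")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
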