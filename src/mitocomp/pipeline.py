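"""Whole-pipeline orchestration over a directory of annotated genomes.

``run_all`` executes the comparative stages — composition tables,
codon-usage summaries with the bias-correlation battery, per-gene
Ka/Ks, RNA conservation scoring, the control-region element report and
the four supermatrix exports — writing one TSV bundle plus a JSON run
manifest (config echo, input checksums, per-stage status).  Stages are
independent: a failing stage is recorded in the manifest and the rest
continue.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .at_rich import (find_hairpins, find_microsatellites, find_t_stretches,
                      find_tandem_repeats, flank_consensus, hits_to_bed,
                      longest_stretch, spacer_motif_check)
from .codon_usage import (correlate, count_codons, summary_row, usage_long_table)
from .composition import partition_composition, summarize
from .conservation_rna import (AlignedFamily, conservation_table,
                               default_cloverleaf_mask, region_summary,
                               score_family, strand_conservation_bias)
from .evol_rates import gene_rates, rates_table
from .genome_io import (Mitogenome, PCG_NAMES, extract_gene, feature_table,
                        parse_genbank, partition_set)
from .phylo_matrix import concatenate, strip_third_positions, write_nexus, write_phylip

log = logging.getLogger("mitocomp")

ALL_STAGES = ("parse", "composition", "codons", "rates", "conservation",
              "atrich", "matrix")


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    # control-region scanner thresholds (field-conventional defaults)
    t_stretch_min_major: int = 10
    t_stretch_min_minor: int = 8
    micro_min_n: int = 5
    repeat_min_period: int = 10
    repeat_max_period: int = 60
    repeat_min_identity: float = 0.70
    repeat_min_copies: float = 1.8
    flank_window_5: int = 10
    flank_window_3: int = 15
    flank_threshold: float = 0.8
    spacer_motif: str = "TACTAA"
    correlation_pairs: tuple[tuple[str, str], ...] = (
        ("gc", "enc"), ("gc3", "enc"), ("enc", "cbi"),
        ("gc", "cbi"), ("gc3", "cbi"), ("pcg_at", "at_rich4_share"),
    )

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in sorted(asdict(self).items()):
                fh.write(f"{key} = {json.dumps(value)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = json.loads(value.strip())
        for key in ("stages", "correlation_pairs"):
            if key in kwargs:
                kwargs[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in kwargs[key]
                )
        return cls(**kwargs)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(config: RunConfig) -> dict:
    """Run the requested stages; return (and write) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    inputs = sorted(Path(config.input_dir).glob("*.gb")) + sorted(
        Path(config.input_dir).glob("*.gbk"))
    checksums = {p.name: hashlib.md5(p.read_bytes()).hexdigest() for p in inputs}

    genomes: list[Mitogenome] = []
    try:
        genomes = [parse_genbank(p) for p in inputs]
        if not genomes:
            raise ValueError(f"no GenBank records under {config.input_dir}")
        if "parse" in config.stages:
            _write_tsv(feature_table(genomes), outdir / "features.tsv")
            status["parse"] = "ok"
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        status["parse"] = f"failed: {exc}"
        genomes = []

    psets = {g.id: partition_set(g) for g in genomes}

    for stage in config.stages:
        if stage == "parse" or not genomes:
            continue
        runner = _STAGE_RUNNERS[stage]
        try:
            runner(config, genomes, psets, outdir)
            status[stage] = "ok"
        except Exception as exc:  # noqa: BLE001
            log.error("stage %s failed: %s", stage, exc)
            status[stage] = f"failed: {exc}"

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": checksums,
        "stages": status,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_composition(config, genomes, psets, outdir: Path) -> None:
    tables = [partition_composition(psets[g.id], g) for g in genomes]
    _write_tsv(pd.concat(tables, ignore_index=True), outdir / "composition.tsv")


def _stage_codons(config, genomes, psets, outdir: Path) -> None:
    summaries, longs = [], []
    for g in genomes:
        ps = psets[g.id]
        for label, genes in (("all", ps.pcgs), ("major", ps.pcgs_major),
                             ("minor", ps.pcgs_minor)):
            if not genes:
                continue
            table = count_codons(genes, label=f"{g.id}:{label}")
            row = summary_row(table)
            row["genome"] = g.id
            row["strand_class"] = label
            if label == "all":
                row["pcg_at"] = summarize("".join(x.dna for x in genes)).at_content
            summaries.append(row)
            longs.append(usage_long_table(table))
    sdf = pd.DataFrame(summaries)
    _write_tsv(sdf, outdir / "codon_summary.tsv")
    _write_tsv(pd.concat(longs, ignore_index=True), outdir / "codon_usage_long.tsv")

    rows = []
    pooled = sdf[sdf.strand_class == "all"]
    for x, y in config.correlation_pairs:
        res = correlate(pooled[x], pooled[y], x, y) if x in pooled and y in pooled else None
        if res is not None:
            rows.append({"x": x, "y": y, "n": res.n, "pearson_r": res.pearson_r,
                         "r_squared": res.r_squared, "slope": res.slope,
                         "intercept": res.intercept})
    _write_tsv(pd.DataFrame(rows), outdir / "correlations.tsv")


def _aligned_genes(genomes, names) -> dict[str, dict[str, str]]:
    """Per-gene pseudo-alignments from equal-length extracted genes."""
    out: dict[str, dict[str, str]] = {}
    for name in names:
        rows = {}
        try:
            for g in genomes:
                rows[g.id] = extract_gene(g, name).coding
        except KeyError:
            warnings.warn(f"{name}: absent from some genomes; skipped")
            continue
        if len({len(s) for s in rows.values()}) == 1:
            out[name] = rows
        else:
            warnings.warn(f"{name}: unequal lengths across genomes; supply an "
                          "alignment to include it")
    return out


def _stage_rates(config, genomes, psets, outdir: Path) -> None:
    if len(genomes) < 2:
        raise ValueError("rates stage needs at least two genomes")
    aligned = _aligned_genes(genomes, sorted(PCG_NAMES))
    aligned = {g: {t: s[: len(s) - len(s) % 3] for t, s in rows.items()}
               for g, rows in aligned.items()}
    _write_tsv(rates_table(gene_rates(aligned)), outdir / "rates.tsv")


def _stage_conservation(config, genomes, psets, outdir: Path) -> None:
    if len(genomes) < 2:
        raise ValueError("conservation stage needs at least two genomes")
    mask = default_cloverleaf_mask()
    trna_names = [t.name for t in psets[genomes[0].id].trnas]
    rrna_names = [t.name for t in psets[genomes[0].id].rrnas]
    profiles = []
    strands = {}
    for name in trna_names + rrna_names:
        rows = {g.id: extract_gene(g, name).dna for g in genomes}
        if len({len(s) for s in rows.values()}) != 1:
            warnings.warn(f"{name}: unequal lengths; supply an alignment")
            continue
        length = len(next(iter(rows.values())))
        fam_mask = mask if length == len(mask) else None
        profiles.append(score_family(AlignedFamily(name, rows, fam_mask)))
        strands[name] = genomes[0].feature(name).strand
    _write_tsv(conservation_table(profiles, strands), outdir / "conservation.tsv")
    regions = region_summary([p for p in profiles if p.per_region])
    _write_tsv(pd.DataFrame([{"region": r, "identical_fraction": v}
                             for r, v in sorted(regions.items())]),
               outdir / "conservation_regions.tsv")
    inuc = {p.gene: p.inuc for p in profiles if p.gene in strands}
    bias = strand_conservation_bias(inuc, strands)
    _write_tsv(pd.DataFrame([{
        "major_mean": bias["major_mean"], "minor_mean": bias["minor_mean"],
        "high_conservation": ",".join(bias["high"]),
        "mid_conservation": ",".join(bias["mid"]),
    }]), outdir / "conservation_strand.tsv")


def _stage_atrich(config, genomes, psets, outdir: Path) -> None:
    regions = {g.id: psets[g.id].at_rich for g in genomes
               if psets[g.id].at_rich}
    if not regions:
        raise ValueError("no AT-rich region in any genome")
    repeat_rows, stretch_rows, micro_rows, bed_frames, hairpin_rows = [], [], [], [], []
    for gid, region in regions.items():
        stretches = find_t_stretches(region, config.t_stretch_min_major,
                                     config.t_stretch_min_minor)
        micros = find_microsatellites(region, min_n=config.micro_min_n)
        repeats = find_tandem_repeats(
            region, config.repeat_min_period, config.repeat_max_period,
            config.repeat_min_identity, config.repeat_min_copies)
        for h in repeats:
            repeat_rows.append({
                "genome": gid, "id": f"{gid}_{h.id}",
                "consensus_size": h.consensus_size, "copy_number": h.copy_number,
                "position": f"{h.start}-{h.end}", "position_class": h.position_class,
                "at_percent": h.at_percent, "percent_matches": h.percent_matches,
                "consensus": h.consensus,
            })
        for h in stretches:
            stretch_rows.append({"genome": gid, "strand": h.strand,
                                 "start": h.start, "end": h.end, "length": h.length})
        for h in micros:
            micro_rows.append({"genome": gid, "motif": h.motif, "n": h.n,
                               "start": h.start, "end": h.end})
        bed_frames.append(hits_to_bed(f"{gid}:AT_rich",
                                      list(stretches) + list(micros) + list(repeats)))
        anchor = longest_stretch(stretches, "major")
        if anchor is not None and anchor.end + 4 < len(region):
            window = region[anchor.end : anchor.end + 30]
            for hp in find_hairpins(window):
                hairpin_rows.append({
                    "genome": gid, "stem": hp.stem_len, "loop": hp.loop_len,
                    "start": anchor.end + hp.start, "end": anchor.end + hp.end,
                })
    _write_tsv(pd.DataFrame(repeat_rows), outdir / "at_rich_repeats.tsv")
    _write_tsv(pd.DataFrame(stretch_rows), outdir / "at_rich_stretches.tsv")
    _write_tsv(pd.DataFrame(micro_rows), outdir / "at_rich_microsatellites.tsv")
    _write_tsv(pd.DataFrame(hairpin_rows), outdir / "at_rich_hairpins.tsv")
    pd.concat(bed_frames, ignore_index=True).to_csv(
        outdir / "at_rich_hits.bed", sep="\t", index=False, header=False)

    cons_rows = []
    for side, window in (("5'", config.flank_window_5), ("3'", config.flank_window_3)):
        for strand in ("major", "minor"):
            try:
                mc = flank_consensus(regions, side, window, config.flank_threshold,
                                     anchor_strand=strand,
                                     min_major=config.t_stretch_min_major,
                                     min_minor=config.t_stretch_min_minor)
            except ValueError:
                continue
            cons_rows.append({"anchor_strand": strand, "side": side,
                              "window": window, "consensus": mc.consensus,
                              "n_genomes": len(mc.windows)})
    _write_tsv(pd.DataFrame(cons_rows), outdir / "at_rich_flank_consensus.tsv")

    spacers = {gid: psets[gid].spacer("trnS_UCN", "ND1") for gid in regions}
    spacers = {g: s for g, s in spacers.items() if s}
    if spacers:
        rep = spacer_motif_check(spacers, config.spacer_motif)
        _write_tsv(pd.DataFrame([
            {"genome": g, "length": rep["lengths"][g],
             "motif": rep["motif"], "motif_present": rep["motif_present"][g],
             "mismatches_to_consensus": rep["mismatches"][g],
             "consensus": rep["consensus"]}
            for g in sorted(spacers)
        ]), outdir / "spacer_trnS_ND1.tsv")


def _stage_matrix(config, genomes, psets, outdir: Path) -> None:
    if len(genomes) < 2:
        raise ValueError("matrix stage needs at least two genomes")
    all_names = [f.name for f in genomes[0].features if f.kind in ("PCG", "tRNA", "rRNA")]
    aligned = _aligned_genes(genomes, all_names)
    trimmed = {}
    for gene, rows in aligned.items():
        if gene in PCG_NAMES:
            rows = {t: s[: len(s) - len(s) % 3] for t, s in rows.items()}
        trimmed[gene] = rows
    for base in ("PCG", "mtDNA"):
        ds = concatenate(trimmed, base)
        write_phylip(ds, outdir / f"{base}.phy")
        write_nexus(ds, outdir / f"{base}.nex")
        ds12 = strip_third_positions(ds)
        write_phylip(ds12, outdir / f"{ds12.name}.phy")
        write_nexus(ds12, outdir / f"{ds12.name}.nex")


_STAGE_RUNNERS = {
    "composition": _stage_composition,
    "codons": _stage_codons,
    "rates": _stage_rates,
    "conservation": _stage_conservation,
    "atrich": _stage_atrich,
    "matrix": _stage_matrix,
}
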