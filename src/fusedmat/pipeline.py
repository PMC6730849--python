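"""End-to-end characterization of a strain panel.

Given per-strain assemblies + annotations and a MAT protein reference panel,
the pipeline runs: pheromone scan -> role assignment -> STE3 typing -> MAT
locus location and allele classification -> A1-vs-A2 synteny and inversion
blocks -> window similarity -> trio dS / closest-pair / t-test -> GC and
codon-usage contrasts -> per-gene genealogies, and emits TSV/GFF3/BED/Newick
outputs plus one machine-readable summary. Identical config + seed produce
identical outputs.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import composition, divergence, genealogy, pheromones, synteny
from .align import RoleAssignment, assign_roles, type_ste3
from .io import (Annotation, Record, SequenceSet, parse_fasta, parse_gff3,
                 write_bed, write_newick)
from .locus import MatLocusReport, locate_mat

#: genes excluded from the between- vs within-mating-type dS comparison:
#: STE3 alleles diverged long before any recent suppression (trans-species
#: polymorphism) and SXI1/SXI2 are distinct genes, not alleles.
DS_EXCLUDED_ROLES = ("STE3", "SXI1", "SXI2", "HD")


@dataclass
class PipelineConfig:
    data_dir: Path
    out_dir: Path
    strains: list[str] = field(default_factory=list)  # empty: discover *.fa
    panel: Optional[Path] = None  # default: data_dir / panel.fa
    seed: int = 0
    gc_window: int = 2000
    fragment: int = 1000
    flank: int = 20_000
    similarity_max_kb: int = 20
    trio: Optional[list[str]] = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        accepted = {"data_dir", "out_dir", "strains", "panel", "seed",
                    "gc_window", "fragment", "flank", "similarity_max_kb",
                    "trio"}
        cp = configparser.ConfigParser()
        cp.read(path)
        kwargs: dict = {}
        for section in cp.sections():
            for key, value in cp.items(section):
                if key not in accepted:
                    raise ValueError(
                        f"unknown config key {key!r}; accepted: "
                        f"{sorted(accepted)}")
                if key in ("data_dir", "out_dir", "panel"):
                    kwargs[key] = Path(value)
                elif key in ("strains", "trio"):
                    kwargs[key] = [s.strip() for s in value.split(",") if s.strip()]
                else:
                    kwargs[key] = int(value)
        if "data_dir" not in kwargs or "out_dir" not in kwargs:
            raise ValueError("config must name data_dir and out_dir")
        return cls(**kwargs)


@dataclass
class StrainData:
    name: str
    assembly: SequenceSet
    annotation: Annotation
    proteome: SequenceSet
    roles: Optional[RoleAssignment] = None
    ste3_type: str = "unresolved"
    report: Optional[MatLocusReport] = None


def _load_strain(data_dir: Path, name: str) -> StrainData:
    fa = data_dir / f"{name}.fa"
    gff = data_dir / f"{name}.gff3"
    for p in (fa, gff):
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")
    assembly = parse_fasta(fa.read_text())
    annotation = parse_gff3(gff.read_text(), assembly, genome_id=name)
    proteome = SequenceSet(
        [Record(g.gene_id, g.protein(assembly)) for g in annotation
         if g.cds_parts],
        alphabet="aa")
    return StrainData(name, assembly, annotation, proteome)


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def characterize_strain(sd: StrainData, panel: SequenceSet,
                        flank: int = 20_000) -> StrainData:
    """Role assignment, STE3 typing and MAT locus report for one strain."""
    sd.roles = assign_roles(sd.proteome, panel)
    ste3_call = sd.roles.by_role.get("STE3")
    if ste3_call is not None and ste3_call.flag != "one_way":
        refs = SequenceSet([r for r in panel if "class=" in r.description],
                           alphabet="aa")
        if len(refs) >= 2:
            query = sd.proteome[ste3_call.gene_id]
            sd.ste3_type = type_ste3(query, refs).cls
    reports = locate_mat(sd.annotation, sd.roles, ste3_type=sd.ste3_type,
                         flank=flank)
    sd.report = reports[0]
    return sd


def ortholog_families(
    strains: list[StrainData],
    reference: str,
    contig: Optional[str] = None,
) -> dict[str, dict[str, Optional[str]]]:
    """Reference-pivoted ortholog families (reciprocal best hits against each
    other strain); values are CDS sequences, None where no ortholog maps."""
    by_name = {s.name: s for s in strains}
    ref = by_name[reference]
    region = (contig, 0, 10**12) if contig else None
    genes = [g for g in (ref.annotation.on_contig(contig) if contig
                         else ref.annotation) if g.cds_parts]
    fams: dict[str, dict[str, Optional[str]]] = {
        g.gene_id: {reference: g.cds_sequence(ref.assembly)} for g in genes}
    for other in strains:
        if other.name == reference:
            continue
        anchors = synteny.anchor_map(ref.annotation, ref.assembly,
                                     other.annotation, other.assembly,
                                     region_a=region)
        partner = {a.gene_a: a.gene_b for a in anchors}
        for g in genes:
            gb = partner.get(g.gene_id)
            fams[g.gene_id][other.name] = (
                other.annotation.get(gb).cds_sequence(other.assembly)
                if gb else None)
    return fams


def trio_divergence(
    fams: dict[str, dict[str, Optional[str]]],
    labels: dict[str, str],
    roles_of_gene: dict[str, Optional[str]],
    core_genes: set[str],
    seed: int = 0,
    bootstrap_B: int = 200,
):
    """Per-gene dS table, closest-pair calls, and the core-region
    between-vs-within mating-type t-test for a three-strain panel."""
    strains = sorted(labels)
    a1 = [s for s in strains if labels[s].startswith("A1")]
    a2 = [s for s in strains if labels[s].startswith("A2")]
    if len(a1) != 1 or len(a2) != 2:
        raise ValueError("trio must contain one A1-class and two A2-class strains")
    rows = []
    calls = []
    between, within = [], []
    rng = np.random.default_rng(seed)
    for gene_id in sorted(fams):
        alleles = fams[gene_id]
        call = divergence.closest_pair_calls(gene_id, alleles, labels)
        calls.append(call)
        role = roles_of_gene.get(gene_id)
        estimates = {}
        for s1, s2 in (((a1[0], a2[0])), (a1[0], a2[1]), (a2[0], a2[1])):
            if alleles.get(s1) is None or alleles.get(s2) is None:
                continue
            try:
                est = divergence.estimate_ds(
                    divergence.codon_align(alleles[s1], alleles[s2]),
                    bootstrap_B=bootstrap_B, seed=int(rng.integers(2**31)))
            except ValueError:
                continue
            pair = f"{labels[s1]}/{labels[s2]}"
            estimates[(s1, s2)] = est
            rows.append((gene_id, f"{s1}-{s2}", pair, est))
        if gene_id in core_genes and role not in DS_EXCLUDED_ROLES:
            for (s1, s2), est in estimates.items():
                if est.dS is None:
                    continue
                if labels[s1][:2] != labels[s2][:2]:
                    between.append(est.dS)
                else:
                    within.append(est.dS)
    ttest = (divergence.compare_ds_sets(between, within)
             if len(between) >= 2 and len(within) >= 2 else None)
    return rows, calls, ttest, between, within


def run_characterize(config: PipelineConfig) -> dict:
    """Run the full pipeline and write the report bundle; returns the
    machine-readable summary (also written as summary.json)."""
    data_dir = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel_path = Path(config.panel) if config.panel else data_dir / "panel.fa"
    if not panel_path.exists():
        raise FileNotFoundError(f"reference panel required: {panel_path}")
    panel = parse_fasta(panel_path.read_text(), alphabet="aa")

    names = config.strains or sorted(
        p.stem for p in data_dir.glob("*.fa") if p.stem != "panel"
        and (data_dir / f"{p.stem}.gff3").exists())
    if not names:
        raise FileNotFoundError(f"no strain FASTA/GFF3 pairs in {data_dir}")
    strains = [_load_strain(data_dir, n) for n in names]

    summary: dict = {"seed": config.seed, "strains": {}, "inputs": {}}
    log_lines = []
    for sd in strains:
        fa_text = (data_dir / f"{sd.name}.fa").read_text()
        summary["inputs"][sd.name] = _digest(fa_text)

    # --- pheromone scan --------------------------------------------------
    all_hits = {}
    for sd in strains:
        hits = pheromones.scan_genome(sd.assembly)
        all_hits[sd.name] = hits
        (out / f"{sd.name}.pheromones.gff3").write_text(
            pheromones.hits_to_gff3(hits))
        (out / f"{sd.name}.pheromones.bed").write_text(
            pheromones.hits_to_bed(hits))
        log_lines.append(f"scan-pheromones {sd.name} hits={len(hits)}")

    # --- roles, STE3 typing, MAT locus ----------------------------------
    mat_rows = ["strain\tlinked\tdistance_bp\tcore_contig\tcore_start\t"
                "core_end\thd_role\tste3_type\tallele\tcompanions\t"
                "mat_pheromone_hits"]
    bed_rows = []
    for sd in strains:
        characterize_strain(sd, panel, flank=config.flank)
        rep = sd.report
        # pheromone genes (scan hits coinciding with an annotated gene) in
        # the core region; raw candidate ORFs elsewhere are not counted
        gene_spans = {(g.contig, g.start, g.end, g.strand)
                      for g in sd.annotation}
        n_mat_ph = (sum(1 for h in all_hits[sd.name]
                        if rep.core_contig and h.contig == rep.core_contig
                        and rep.core_span
                        and h.start >= rep.core_span[0]
                        and h.end <= rep.core_span[1]
                        and (h.contig, h.start, h.end, h.strand) in gene_spans)
                    if rep.complete and rep.linked else 0)
        mat_rows.append("\t".join(map(str, [
            sd.name, rep.linked, rep.distance_bp,
            rep.core_contig, rep.core_span[0] if rep.core_span else "",
            rep.core_span[1] if rep.core_span else "", rep.hd_role,
            sd.ste3_type, rep.allele, ",".join(rep.companions), n_mat_ph])))
        if rep.core_span:
            bed_rows.append((rep.core_contig, rep.core_span[0],
                             rep.core_span[1], f"{sd.name}_coreMAT"))
        summary["strains"][sd.name] = {
            "linked": rep.linked, "distance_bp": rep.distance_bp,
            "allele": rep.allele, "hd_role": rep.hd_role,
            "ste3_type": sd.ste3_type,
            "mat_pheromone_hits": n_mat_ph,
        }
        log_lines.append(
            f"find-mat {sd.name} allele={rep.allele} linked={rep.linked}")
    (out / "mat_report.tsv").write_text("\n".join(mat_rows) + "\n")
    (out / "core_mat.bed").write_text(write_bed(bed_rows))

    # --- synteny between the first A1 / A2 pair --------------------------
    a1 = next((s for s in strains if s.report and s.report.allele.startswith("A1")), None)
    a2 = next((s for s in strains if s.report and s.report.allele.startswith("A2")), None)
    if a1 and a2 and a1.report.linked and a2.report.linked:
        anchors = synteny.anchor_map(
            a1.annotation, a1.assembly, a2.annotation, a2.assembly,
            region_a=(a1.report.core_contig, 0, 10**12),
            region_b=(a2.report.core_contig, 0, 10**12))
        blocks = synteny.detect_blocks(anchors)
        (out / "synteny_blocks.tsv").write_text(synteny.blocks_to_tsv(blocks))
        summary["synteny"] = {
            "pair": [a1.name, a2.name],
            "n_anchors": len(anchors),
            "inverted_blocks": blocks.inverted_count,
            "breakpoints": blocks.breakpoints,
        }
        log_lines.append(
            f"synteny {a1.name}x{a2.name} inverted={blocks.inverted_count}")
        # window similarity over (a slice of) the core region
        lo, hi = a1.report.core_span
        hi = min(hi, lo + config.similarity_max_kb * 1000)
        qa = a1.assembly[a1.report.core_contig][lo:hi]
        lo2, hi2 = a2.report.core_span
        tb = a2.assembly[a2.report.core_contig][lo2:hi2]
        track = synteny.window_similarity(qa, tb, fragment=config.fragment)
        lines = ["start\tend\tscore"]
        for (s, e), v in track.windows:
            lines.append(f"{s + lo}\t{e + lo}\t{v:.1f}")
        (out / "similarity_track.tsv").write_text("\n".join(lines) + "\n")

    # --- trio divergence -------------------------------------------------
    trio_names = config.trio
    if trio_names is None:
        a1s = [s.name for s in strains if s.report and s.report.allele == "A1"]
        a2s = [s.name for s in strains if s.report and s.report.allele == "A2"]
        if len(a1s) >= 1 and len(a2s) >= 2:
            trio_names = [a1s[0], a2s[0], a2s[1]]
    if trio_names:
        sd_map = {s.name: s for s in strains}
        trio = [sd_map[n] for n in trio_names]
        labels = {s.name: s.report.allele for s in trio}
        ref = trio[0]
        fams = ortholog_families(trio, ref.name, contig=ref.report.core_contig)
        role_of = {}
        for g in fams:
            role_of[g] = ref.roles.role_of(g) if ref.roles else None
        core = {g for g in fams
                if ref.annotation.get(g).start >= ref.report.core_span[0]
                and ref.annotation.get(g).end <= ref.report.core_span[1]}
        rows, calls, ttest, between, within = trio_divergence(
            fams, labels, role_of, core, seed=config.seed)
        tsv = ["gene\tpair_strains\tpair\tdS\tSE_dS\tdN\tSE_dN\tstatus"]
        for gene_id, pair_strains, pair, est in rows:
            tsv.append(f"{gene_id}\t{pair_strains}\t" +
                       divergence.ds_table_row("", pair, est).lstrip("\t"))
        (out / "ds_table.tsv").write_text("\n".join(tsv) + "\n")
        call_rows = ["gene\tmost_similar_pair\tpair_label\tmargin\tstatus"]
        for c in calls:
            call_rows.append("\t".join(map(str, [
                c.gene_id,
                "-".join(c.most_similar_pair) if c.most_similar_pair else "",
                c.pair_label or "", f"{c.margin:.1f}", c.status])))
        (out / "closest_pairs.tsv").write_text("\n".join(call_rows) + "\n")
        if ttest:
            (out / "ds_ttest.txt").write_text(
                f"between n={ttest.n1} mean={np.mean(between):.4f}\n"
                f"within n={ttest.n2} mean={np.mean(within):.4f}\n"
                f"t={ttest.t:.4f} df={ttest.df} one-sided p={ttest.p:.4g}\n")
            summary["divergence"] = {
                "trio": trio_names,
                "mean_ds_between": float(np.mean(between)),
                "mean_ds_within": float(np.mean(within)),
                "t": ttest.t, "p": ttest.p,
                "core_calls_a2a2": sum(
                    1 for c in calls if c.status == "called"
                    and c.gene_id in core and c.pair_label == "A2/A2"),
                "core_calls_total": sum(
                    1 for c in calls if c.status == "called"
                    and c.gene_id in core),
            }
        log_lines.append(f"divergence trio={','.join(trio_names)}")

    # --- composition ------------------------------------------------------
    comp_summary = {}
    if a1 and a1.report.linked:
        sd = a1
        rep = sd.report
        gc_lines = ["contig\tstart\tend\tgc_pct"]
        core_vals, bg_vals = [], []
        for rec in sd.assembly:
            track = composition.gc_windows(rec.seq, window=config.gc_window)
            for (s, e), v in track.windows:
                gc_lines.append(f"{rec.id}\t{s}\t{e}\t{v:.2f}")
                if e - s < config.gc_window:
                    continue
                if rec.id == rep.core_contig and s >= rep.core_span[0] \
                        and e <= rep.core_span[1]:
                    core_vals.append(v)
                elif rec.id != rep.core_contig:
                    bg_vals.append(v)
        (out / "gc_track.tsv").write_text("\n".join(gc_lines) + "\n")
        table = composition.cds_gc(sd.annotation, sd.assembly)
        cds_lines = ["gene\tgc_pct"]
        for g, v in sorted(table["per_gene"].items()):
            cds_lines.append(f"{g}\t{v:.2f}")
        (out / "cds_gc.tsv").write_text("\n".join(cds_lines) + "\n")
        if len(core_vals) >= 2 and len(bg_vals) >= 2:
            rs = composition.rank_sum_test(core_vals, bg_vals,
                                           alternative="less")
            comp_summary = {
                "strain": sd.name,
                "mean_gc_core": float(np.mean(core_vals)),
                "mean_gc_background": float(np.mean(bg_vals)),
                "rank_sum_p": rs.p, "method": rs.method,
            }
        core_cds, bg_cds = [], []
        for g in sd.annotation:
            if not g.cds_parts:
                continue
            cds = g.cds_sequence(sd.assembly)
            if g.contig == rep.core_contig and g.start >= rep.core_span[0] \
                    and g.end <= rep.core_span[1]:
                core_cds.append(cds)
            elif g.contig != rep.core_contig:
                bg_cds.append(cds)
        if core_cds and bg_cds:
            r_core = composition.rscu(core_cds)
            r_bg = composition.rscu(bg_cds)
            rscu_lines = ["codon\taa\tcount_mat\trscu_mat\tcount_bg\trscu_bg"]
            for codon in sorted(set(r_core.rscu) | set(r_bg.rscu)):
                from ._genetics import CODON_AA
                rscu_lines.append("\t".join(map(str, [
                    codon, CODON_AA[codon],
                    r_core.counts.get(codon, ""),
                    f"{r_core.rscu[codon]:.3f}" if codon in r_core.rscu else "",
                    r_bg.counts.get(codon, ""),
                    f"{r_bg.rscu[codon]:.3f}" if codon in r_bg.rscu else ""])))
            (out / "rscu.tsv").write_text("\n".join(rscu_lines) + "\n")
            gc3_core = r_core.gc3_mean_rscu()
            gc3_bg = r_bg.gc3_mean_rscu()
            if gc3_core is not None and gc3_bg is not None:
                comp_summary["gc_ending_rscu_mat"] = gc3_core
                comp_summary["gc_ending_rscu_background"] = gc3_bg
        summary["composition"] = comp_summary
        log_lines.append(f"composition strain={sd.name}")

    # --- genealogy --------------------------------------------------------
    if len(strains) >= 4:
        sd_map = {s.name: s for s in strains}
        linked = [s for s in strains if s.report and s.report.linked
                  and s.report.allele != "unresolved"]
        if len(linked) >= 4:
            ref = linked[0]
            fams = ortholog_families(linked, ref.name,
                                     contig=ref.report.core_contig)
            labels = {}
            for s in linked:
                species = s.name.rsplit("s", 1)[0] if "s" in s.name else s.name
                labels[s.name] = (species, s.report.allele)
            patterns = ["gene\trole\tpattern"]
            trees_dir = out / "trees"
            trees_dir.mkdir(exist_ok=True)
            n_mt = 0
            for gene_id in sorted(fams):
                seqs = {s: c for s, c in fams[gene_id].items() if c}
                # complete families only: a missing strain can leave one
                # mating type as a single tip, making the class split vacuous
                if len(seqs) < len(linked):
                    continue
                if len({len(c) for c in seqs.values()}) != 1:
                    continue  # pipeline genealogies need equal-length alleles
                dm = genealogy.pairwise_distances(seqs, model="JC")
                if dm.undefined:
                    continue
                tree = genealogy.nj_tree(dm)
                pat = genealogy.classify_clustering(
                    tree, {t: labels[t] for t in seqs})
                role = ref.roles.role_of(gene_id) if ref.roles else None
                patterns.append(f"{gene_id}\t{role or ''}\t{pat.kind}")
                (trees_dir / f"{gene_id}.nwk").write_text(
                    write_newick(tree) + "\n")
                if pat.kind == "mating_type":
                    n_mt += 1
            (out / "genealogy_patterns.tsv").write_text(
                "\n".join(patterns) + "\n")
            summary["genealogy"] = {"n_mating_type": n_mt,
                                    "n_genes": len(patterns) - 1}
            log_lines.append(f"genealogy genes={len(patterns) - 1}")

    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    summary_text = json.dumps(summary, indent=1, sort_keys=True, default=str)
    (out / "summary.json").write_text(summary_text)
    summary["digest"] = _digest(summary_text)
    return summary
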