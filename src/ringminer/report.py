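"""End-to-end orchestration: synthesize inputs, run every stage, emit one report.

``synthesize_bundle`` writes a complete synthetic input set (with truth
sidecars) to a directory; ``run_pipeline`` consumes such a directory (or any
compatible real inputs) and produces a machine-readable JSON report plus
per-stage TSVs.  ``consistency_report`` checks that every count partition sums
to its stated total and every percentage equals its ratio at printed precision.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from ringminer import io as rio
from ringminer.correlation import correlate_targets, select_correlated_candidates
from ringminer.expression import (call_expressed, deg_filter, heatmap_groups,
                                  venn_partition)
from ringminer.genome import (DupParams, chain_collinear_blocks,
                              chrom_distribution, class_counts,
                              classify_duplications, load_gene_loci,
                              mean_adjacent_distance)
from ringminer.qpcr import CtTable, count_candidates, fc_profile
from ringminer.rules import default_ruleset, parse_ruleset
from ringminer.scanner import scan_proteome, summarize_groups
from ringminer.util import percent
from ringminer.variants import (Windows, annotate_variants, distribution_summary,
                                load_gene_models, read_vcf_lite)

log = logging.getLogger("ringminer")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Input paths and thresholds for an end-to-end run."""

    out_dir: str
    proteome_fasta: Optional[str] = None
    rules_yaml: Optional[str] = None
    gff3: Optional[str] = None
    pairs_tsv: Optional[str] = None
    family_genes_json: Optional[str] = None  # family subset for dup classes
    expression_tsv: Optional[str] = None
    deg_tsv: Optional[str] = None
    ct_csv: Optional[str] = None
    vcf: Optional[str] = None
    genemodels_gff3: Optional[str] = None
    ref_fasta: Optional[str] = None
    corr_means_tsv: Optional[str] = None
    expressed_threshold: float = 0.5
    deg_min_abs_log2fc: float = 1.0
    deg_max_p: float = 0.05
    ref_gene: str = "ARF"
    control: str = "C306"
    mutants: tuple[str, ...] = ("TAC75", "TAC6")
    candidate_magnitude: float = 2.0
    candidate_min_strong_stages: int = 2
    corr_targets: tuple[str, ...] = ("GBSSI", "SBEIIa")
    corr_p_max: float = 0.05
    corr_min_r2: float = 0.60
    dup_params: DupParams = field(default_factory=DupParams)
    seed: int = 0


# Default synthetic study conditions: genome-scale pieces keep the published
# family structure; the proteome and qPCR panel are scaled-down exemplars.
VENN_SPEC = (306, 22, 3, 156, 152, 5, 54)
N_SILENT = 557
DUP_PLAN = {"singleton": 4, "dispersed": 49, "proximal": 15,
            "tandem": 90, "WGD": 1080}
# Variant plans follow the published per-category table; the two zero rows are
# dropped and the downstream counts absorb the difference between the table's
# column sums and its stated totals (457 / 667).
VARIANT_PLAN_TAC75 = {
    "3_prime_UTR": 18, "5_prime_UTR_premature_start_gain": 1, "5_prime_UTR": 21,
    "disruptive_inframe_insertion": 1,
    "disruptive_inframe_insertion&splice_region": 1, "downstream_gene": 13,
    "frameshift": 3, "intergenic": 133, "intron": 53, "missense": 18,
    "missense&splice_region": 1, "splice_acceptor&intron": 16,
    "splice_donor&intron": 7, "splice_region&intron": 19, "synonymous": 33,
    "upstream_gene": 119,
}
VARIANT_PLAN_TAC6 = {
    "3_prime_UTR": 17, "5_prime_UTR_premature_start_gain": 2, "5_prime_UTR": 4,
    "conservative_inframe_deletion": 1, "disruptive_inframe_insertion": 1,
    "downstream_gene": 58, "frameshift": 4, "frameshift&splice_region": 1,
    "intergenic": 191, "intron": 105, "missense": 24,
    "splice_acceptor&intron": 9, "splice_donor&intron": 7,
    "splice_donor&splice_region&intron": 2, "splice_region&intron": 18,
    "synonymous": 35, "upstream_gene": 188,
}

PROTEOME_PLAN = (
    [["RING-H2"]] * 38 + [["RING-H2!rbx"]] * 2 + [["RING-HC"]] * 12
    + [["RING-v"]] * 5 + [["RING-G"]] * 1
    + [["RING-H2", "RING-HC"]] + [["RING-H2"] * 3] + [["RING-H2"] * 4]
    + [["INCOMPLETE"]] * 2
)


def default_qpcr_profiles() -> dict[str, dict[str, list[float]]]:
    """36-gene fold-change plan: 8 consistent-down and 3 consistent-up
    candidates in the high-amylose comparison, the rest weak or mixed."""
    prof: dict[str, dict[str, list[float]]] = {}

    def gene(i: int) -> str:
        return f"RQ{i:03d}"

    i = 1
    for _ in range(4):  # strong late down
        prof[gene(i)] = {"TAC75": [-1.2, -1.1, -2.6, -2.9],
                         "TAC6": [0.5, 0.4, -0.2, 0.6]}
        i += 1
    for _ in range(4):  # strong early down
        prof[gene(i)] = {"TAC75": [-2.5, -2.2, -1.1, -1.0],
                         "TAC6": [0.3, -0.4, 0.2, 0.5]}
        i += 1
    for j in range(3):  # consistent up candidates
        prof[gene(i)] = {"TAC75": [2.4 + j, 2.2, 1.1, 2.8],
                         "TAC6": [-0.5, -0.3, -0.6, -0.2]}
        i += 1
    for _ in range(3):  # consistent up, too weak
        prof[gene(i)] = {"TAC75": [0.6, 0.5, 0.8, 0.9],
                         "TAC6": [0.2, 0.1, 0.4, 0.3]}
        i += 1
    for _ in range(4):  # consistent down, too weak
        prof[gene(i)] = {"TAC75": [-0.5, -0.6, -0.4, -0.7],
                         "TAC6": [-0.2, -0.1, -0.4, -0.3]}
        i += 1
    while i <= 36:  # mixed
        prof[gene(i)] = {"TAC75": [1.0, -0.8, 0.6, -0.4],
                         "TAC6": [-0.6, 0.7, -0.3, 0.2]}
        i += 1
    return prof


def synthesize_bundle(out_dir, seed: int = 0) -> PipelineConfig:
    """Write the full default synthetic input bundle and return its config."""
    from ringminer.synthetic import (gen_deg_table, gen_expression,
                                     gen_gene_map, gen_proteome, gen_qpcr,
                                     gen_correlated_means, gen_variants,
                                     toy_gene_models)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rules = default_ruleset()
    params = DupParams()

    records, truth_p = gen_proteome(rules, 80, PROTEOME_PLAN, decoy_rate=0.1,
                                    seed=seed)
    rio.write_fasta(records, out / "proteome.faa")
    gff3, pairs, truth_d = gen_gene_map(1238, 21, DUP_PLAN, params, seed=seed + 1)
    (out / "genes.gff3").write_text(gff3)
    rio.write_pairs_tsv(pairs, out / "pairs.tsv")
    (out / "family_genes.json").write_text(
        json.dumps(sorted(truth_d.dup_classes)))
    expr = gen_expression(VENN_SPEC, N_SILENT, seed=seed + 2)
    expr.to_csv(out / "expression.tsv", sep="\t")
    gen_deg_table(seed=seed + 3).to_csv(out / "deg.tsv", sep="\t", index=False)
    ct = gen_qpcr(default_qpcr_profiles(), noise_sd=0.0, seed=seed + 4)
    ct.data.to_csv(out / "ct.csv", index=False)
    models, clen = toy_gene_models(VARIANT_PLAN_TAC75)
    variants, ref, truth_v = gen_variants(models, VARIANT_PLAN_TAC75,
                                          seed=seed + 5, chrom_length=clen)
    rio.write_vcf_lite(variants, out / "variants.vcf")
    rio.write_fasta(sorted(ref.items()), out / "reference.fa")
    rio.write_gff3(
        [line for m in models for line in rio.gff3_gene_lines(
            m.gene_id, m.chromosome, m.start, m.end, m.strand, m.exons, m.cds)],
        out / "gene_models.gff3")
    means, truth_c = gen_correlated_means(36, seed=seed + 6)
    pd.DataFrame(means).T.rename_axis("gene").to_csv(out / "corr_means.tsv",
                                                     sep="\t")
    rio.write_truth_json(
        {"planted_domains": truth_p.planted_domains,
         "dup_classes": truth_d.dup_classes,
         "venn_spec": list(VENN_SPEC),
         "variant_effects": truth_v.variant_effects,
         "correlated": {k: sorted(v) for k, v in truth_c.items()}},
        out / "truth.json")
    return PipelineConfig(
        out_dir=str(out), proteome_fasta=str(out / "proteome.faa"),
        gff3=str(out / "genes.gff3"), pairs_tsv=str(out / "pairs.tsv"),
        family_genes_json=str(out / "family_genes.json"),
        expression_tsv=str(out / "expression.tsv"),
        deg_tsv=str(out / "deg.tsv"), ct_csv=str(out / "ct.csv"),
        vcf=str(out / "variants.vcf"),
        genemodels_gff3=str(out / "gene_models.gff3"),
        ref_fasta=str(out / "reference.fa"),
        corr_means_tsv=str(out / "corr_means.tsv"), seed=seed)


def _require(path: Optional[str], what: str) -> str:
    if path is None:
        raise PipelineError(f"stage {what}: no input configured")
    if not Path(path).is_file():
        raise PipelineError(f"stage {what}: missing input file {path}")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns (and writes) the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "timings_s": {}}

    def stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            report["stages"][name] = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        report["timings_s"][name] = round(dt, 3)
        log.info("stage %s finished in %.3fs", name, dt)

    def scan():
        path = _require(config.proteome_fasta, "scan")
        rules = (parse_ruleset(Path(config.rules_yaml))
                 if config.rules_yaml else default_ruleset())
        records = rio.read_fasta(path)
        hits = scan_proteome(records, rules)
        summ = summarize_groups(hits, total_proteins=len(records), ruleset=rules)
        rows = [{
            "protein_id": h.protein_id, "domain_name": h.domain_name,
            "start": h.start, "end": h.end,
            "ligand_positions": ",".join(map(str, h.ligand_positions)),
            "ligand_residues": "".join(h.ligand_residues),
            "subtype": h.subtype, "flags": ",".join(sorted(h.flags)),
        } for h in hits]
        pd.DataFrame(rows).to_csv(out / "hits.tsv", sep="\t", index=False)
        return {"subtype_counts": summ.subtype_counts,
                "subtype_percent": summ.subtype_percent,
                "total_classified": summ.total_classified,
                "incomplete_domains": summ.incomplete_domains,
                "proteins_by_domain_count": summ.proteins_by_domain_count}

    def dupclass():
        gff = _require(config.gff3, "dupclass")
        pairs = rio.read_pairs_tsv(_require(config.pairs_tsv, "dupclass"))
        loci = load_gene_loci(open(gff).read())
        family = None
        if config.family_genes_json:
            family = json.loads(Path(config.family_genes_json).read_text())
        blocks = chain_collinear_blocks(pairs, loci, config.dup_params)
        calls = classify_duplications(loci, pairs, blocks, config.dup_params,
                                      gene_ids=family)
        pd.DataFrame([{"gene_id": c.gene_id, "class": c.dup_class}
                      for c in calls]).to_csv(out / "dup_calls.tsv", sep="\t",
                                              index=False)
        fam_set = set(family) if family else None
        return {"class_counts": class_counts(calls),
                "n_blocks": len(blocks),
                "chrom_percent": {
                    k: v["percent"]
                    for k, v in chrom_distribution(loci, fam_set).items()},
                "mean_adjacent_mb": mean_adjacent_distance(loci, fam_set)}

    def expression():
        path = _require(config.expression_tsv, "expression")
        matrix = pd.read_csv(path, sep="\t", index_col=0)
        calls = call_expressed(matrix, config.expressed_threshold)
        vp = venn_partition(calls)
        expressed = matrix.loc[calls.any(axis=1)]
        groups = heatmap_groups(expressed)
        groups.rename("group").to_csv(out / "clusters.tsv", sep="\t")
        result = {"venn": vp.as_tuple(), "total_expressed": vp.total_expressed,
                  "n_silent": int(len(matrix) - vp.total_expressed),
                  "cluster_sizes": groups.value_counts().to_dict()}
        if config.deg_tsv:
            degs = pd.read_csv(_require(config.deg_tsv, "expression"), sep="\t")
            kept = deg_filter(degs, config.deg_min_abs_log2fc, config.deg_max_p)
            kept.to_csv(out / "degs_filtered.tsv", sep="\t", index=False)
            result["deg_kept"] = int(len(kept))
            result["deg_by_group"] = kept["group"].value_counts().to_dict()
        return result

    def qpcr():
        path = _require(config.ct_csv, "qpcr")
        table = CtTable(pd.read_csv(path), reference_gene=config.ref_gene)
        out_rows = []
        summary = {}
        for mutant in config.mutants:
            profiles = {}
            for gene in table.genes():
                prof = fc_profile(table, gene, mutant, config.control)
                profiles[gene] = prof["log2fc"]
                out_rows.append({"gene": gene, "mutant": mutant,
                                 **{f"log2fc_{s}": v for s, v in
                                    zip(prof["stages"], prof["log2fc"])}})
            summary[mutant] = count_candidates(
                profiles, config.candidate_magnitude,
                config.candidate_min_strong_stages)
            summary[mutant].pop("status")
        pd.DataFrame(out_rows).to_csv(out / "fc_profiles.tsv", sep="\t",
                                      index=False)
        return summary

    def variants():
        vcf = _require(config.vcf, "variants")
        gff = _require(config.genemodels_gff3, "variants")
        ref = dict(rio.read_fasta(_require(config.ref_fasta, "variants")))
        anns = annotate_variants(read_vcf_lite(open(vcf).read()),
                                 load_gene_models(open(gff).read()), ref,
                                 Windows())
        pd.DataFrame([{
            "variant_id": a.variant.variant_id, "position": a.variant.position,
            "type": a.variant.vtype, "gene": a.gene_id or ".",
            "category": a.category, "impact": a.impact,
        } for a in anns]).to_csv(out / "variant_effects.tsv", sep="\t",
                                 index=False)
        return distribution_summary(anns, ndigits=2)

    def corr():
        path = _require(config.corr_means_tsv, "corr")
        df = pd.read_csv(path, sep="\t", index_col=0)
        means = {g: list(df.loc[g]) for g in df.index}
        results = correlate_targets(means, list(config.corr_targets))
        pd.DataFrame([{
            "gene": r.gene, "target": r.target, "r": r.r, "r2": r.r_squared,
            "p": r.p, "strength": r.strength, "sign": r.sign,
        } for r in results]).to_csv(out / "correlations.tsv", sep="\t",
                                    index=False)
        return select_correlated_candidates(results, config.corr_p_max,
                                            config.corr_min_r2)

    stage("scan", scan)
    stage("dupclass", dupclass)
    stage("expression", expression)
    stage("qpcr", qpcr)
    stage("variants", variants)
    stage("corr", corr)

    checks = []
    s = report["stages"]
    checks.append({"name": "scan_partition",
                   "parts": list(s["scan"]["subtype_counts"].values())
                   + [s["scan"]["incomplete_domains"]],
                   "total": s["scan"]["total_classified"]
                   + s["scan"]["incomplete_domains"]})
    checks.append({"name": "dup_partition",
                   "parts": list(s["dupclass"]["class_counts"].values()),
                   "total": sum(s["dupclass"]["class_counts"].values())})
    checks.append({"name": "venn_partition", "parts": list(s["expression"]["venn"]),
                   "total": s["expression"]["total_expressed"]})
    checks.append({"name": "variant_partition",
                   "parts": [v["count"]
                             for v in s["variants"]["categories"].values()],
                   "total": s["variants"]["total"]})
    report["consistency"] = consistency_report(checks)
    report["config"] = {k: (asdict(v) if isinstance(v, DupParams) else v)
                        for k, v in asdict(config).items()}
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True, default=str))
    return report


def consistency_report(checks: Sequence[dict]) -> dict:
    """Verify count partitions and printed percentages.

    Each check holds ``parts`` and ``total`` (partition must sum exactly)
    and/or ``percents``: a list of (count, total, printed, ndigits) whose
    half-up rounded ratio must equal the printed value.
    """
    ledger = []
    for check in checks:
        entry = {"name": check.get("name", "unnamed"), "pass": True}
        if "parts" in check:
            got = sum(check["parts"])
            entry["sum"] = got
            entry["expected"] = check["total"]
            if got != check["total"]:
                entry["pass"] = False
                entry["delta"] = got - check["total"]
        for item in check.get("percents", []):
            count, total, printed, ndigits = item
            value = percent(count, total, ndigits)
            if value != printed:
                entry["pass"] = False
                entry.setdefault("percent_mismatches", []).append(
                    {"count": count, "total": total, "printed": printed,
                     "computed": value})
        ledger.append(entry)
    return {"checks": ledger, "all_pass": all(e["pass"] for e in ledger)}


#: The published summary arithmetic, as consistency checks.
PRINTED_CHECKS = [
    {"name": "domain_groups", "parts": [875, 323, 67, 7], "total": 1272,
     "percents": [(875, 1272, 68.79, 2), (323, 1272, 25.39, 2),
                  (67, 1272, 5.27, 2), (7, 1272, 0.55, 2)]},
    {"name": "additional_domains",
     "percents": [(885, 1255, 70.52, 2), (370, 1255, 29.48, 2)]},
    {"name": "duplication_classes", "parts": [4, 49, 15, 90, 1080],
     "total": 1238},
    {"name": "expression_venn", "parts": [306, 22, 3, 156, 152, 5, 54],
     "total": 698},
    {"name": "variant_shares",
     "percents": [(133, 457, 29.1, 1), (119, 457, 26.04, 2),
                  (191, 667, 28.64, 2), (188, 667, 28.19, 2)]},
    {"name": "candidate_union", "parts": [7, 8, -5], "total": 10},
]
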