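"""End-to-end pipeline orchestration with reproducible provenance.

``RunConfig`` gathers every input path and threshold (with the published
defaults); ``run_pipeline`` executes the stages in order — cohort
filtering, pair mining, annotation, tissue subnetworks, metastatic-marker
mining, transcriptome contrast — writing each stage's tables plus a
machine-readable manifest (input checksums, settings, seed, row counts)
into the output directory.  ``simulate`` emits a complete synthetic
dataset consumable by ``run_pipeline``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import annotate, cohort, metastasis, network, pairs
from . import expression as expr
from . import simulate as sim

logger = logging.getLogger("comutnet")

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_STAGE_FAILURE = 4


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds; published defaults where stated."""

    # inputs
    mutations: str = ""
    samples: str = ""
    driver_catalog: str = ""
    pathways_gmt: str = ""
    sl_pairs: str = ""
    network_edges: str = ""
    expression: str = ""
    out_dir: str = "comutnet_out"
    # cohort filters
    vaf_min: float = cohort.DEFAULT_VAF_MIN
    recurrence_min: int = cohort.DEFAULT_RECURRENCE_MIN
    hypermut_cutoff: int = cohort.DEFAULT_HYPERMUT_CUTOFF
    missense_only: bool = False
    # pair mining
    q_threshold: float = pairs.DEFAULT_Q_THRESHOLD
    min_joint: int = pairs.DEFAULT_MIN_JOINT
    # pathway/tissue filters
    min_pathway_tumors: int = 80
    min_pathway_rate: float = 0.10
    tissue_fraction_mode: str = "all_tumors"
    # subnetworks
    subnetwork_tissue: str = ""
    seed_fraction_threshold: float = 0.005
    pagerank_alpha: float = network.DEFAULT_ALPHA
    pagerank_iterations: int = network.DEFAULT_MAX_ITER
    score_threshold: float = network.DEFAULT_SCORE_THRESHOLD
    robustness_score_threshold: float = network.DEFAULT_ROBUSTNESS_THRESHOLD
    n_random: int = 100
    # metastasis mining
    min_support: float = 7e-5
    min_confidence: float = 0.95
    volcano_or_log_threshold: float = metastasis.DEFAULT_OR_LOG_THRESHOLD
    volcano_p_log_threshold: float = metastasis.DEFAULT_P_LOG_THRESHOLD
    # transcriptome
    fc_cut: float = expr.DEFAULT_FC_CUT
    q_cut: float = expr.DEFAULT_Q_CUT
    pseudocount: float = expr.DEFAULT_PSEUDOCOUNT
    anchor_mutations: list[str] = field(default_factory=list)
    partner_gene: str = ""
    # stage selection (cohort filtering and pair mining always run)
    stages: list[str] = field(
        default_factory=lambda: ["annotation", "subnetwork", "metastasis", "transcriptome"]
    )
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise cohort.ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate_inputs(self, require: tuple[str, ...]) -> None:
        for name in require:
            value = getattr(self, name)
            if not value:
                raise cohort.ConfigurationError(f"config field {name!r} is required")
            if not Path(value).exists():
                raise cohort.ConfigurationError(f"input file {value!r} ({name}) not found")


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate(config: dict[str, Any] | None = None, seed: int = 0, out_dir="demo_data") -> Path:
    """Emit a complete synthetic demo dataset (cohort, network, expression).

    The default configuration plants two co-existing pairs (odds ratios 9
    and 6), one mutually exclusive pair (odds ratio 0.05) and one 4x
    metastatic marker pair in a 2000-tumor, three-tissue cohort, plus a
    200-gene scale-free network with 10 pathway sets and a 60-sample
    expression matrix with ten +2 log2-effect genes.
    """
    cfg = dict(
        n_samples=2000,
        background_mutations=60,
        metastatic_fraction=0.2,
        n_genes_network=200,
        n_expression_genes=200,
    )
    cfg.update(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_cohort, s_net, s_expr = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3))

    pair_specs = [
        sim.PairSpec(
            cohort.MutationKey("KRAS", "G12D"), cohort.MutationKey("TP53", "R175H"),
            0.2, 0.2, 9.0,
        ),
        sim.PairSpec(
            cohort.MutationKey("PIK3CA", "E545K"), cohort.MutationKey("ESR1", "D538G"),
            0.1, 0.1, 6.0,
        ),
        sim.PairSpec(
            cohort.MutationKey("BRAF", "V600E"), cohort.MutationKey("NRAS", "Q61R"),
            0.15, 0.15, 0.05,
        ),
    ]
    marker_specs = [
        sim.MarkerSpec(
            (cohort.MutationKey("ESR1", "Y537S"), cohort.MutationKey("PIK3CA", "H1047R")),
            base_p=0.05, enrichment=4.0,
        )
    ]
    _, metadata, ledger = sim.generate_cohort(
        n_samples=cfg["n_samples"],
        background_mutations=cfg["background_mutations"],
        pair_specs=pair_specs,
        marker_specs=marker_specs,
        metastatic_fraction=cfg["metastatic_fraction"],
        seed=s_cohort,
        out_dir=out,
    )
    g, pathways = sim.generate_network(cfg["n_genes_network"], seed=s_net, out_dir=out)
    # graft the cohort's mutated genes onto network hubs so seeds exist
    _graft_cohort_genes(out / "network.tsv", out / "pathways.gmt", g, pathways, pair_specs)
    group1 = [f"S{i:05d}" for i in range(0, 200)]
    group2 = [f"S{i:05d}" for i in range(200, 400)]
    planted = {f"GENE{i:04d}": 2.0 for i in range(10)}
    sim.generate_expression(
        group1, group2, cfg["n_expression_genes"], planted=planted,
        seed=s_expr, out_dir=out,
    )
    return out


def _graft_cohort_genes(edges_path, gmt_path, g, pathways, pair_specs) -> None:
    """Rename the highest-degree network nodes to the cohort's driver genes
    so that pair genes are present in the network and pathway files."""
    genes = []
    for spec in pair_specs:
        genes.extend([spec.key_a.gene, spec.key_b.gene])
    genes = sorted(set(genes))
    ranked = sorted(g.nodes(), key=lambda n: -g.degree(n))
    mapping = {ranked[i]: gene for i, gene in enumerate(genes)}
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(g.edges()):
            fh.write(f"{mapping.get(u, u)}\t{mapping.get(v, v)}\n")
    with open(gmt_path, "w") as fh:
        for name in sorted(pathways):
            members = sorted(mapping.get(n, n) for n in pathways[name])
            fh.write(f"{name}\tsynthetic\t" + "\t".join(members) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage on the configured inputs; returns the output dir.

    Stage outputs: ``pairs.tsv``, ``pair_summary.tsv``,
    ``pathway_sharing.tsv``, ``tissue_fractions.tsv``, ``bubble.tsv``,
    ``sl_enrichment.tsv`` (when an SL reference is given), subnetwork SIF +
    sensitivity table (when a network is given), ``marker_tree.json`` /
    ``propensity.tsv`` / ``pair_stats.tsv``, ``de_results.tsv`` /
    ``zscores.tsv`` (when expression is given), plus ``manifest.json`` and
    the serialized config.  On stage failure a ``FAILED`` marker naming the
    stage is left in the output directory and the error re-raised.
    """
    config.validate_inputs(("mutations", "samples"))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }
    for name in ("mutations", "samples", "driver_catalog", "pathways_gmt",
                 "sl_pairs", "network_edges", "expression"):
        value = getattr(config, name)
        if value and Path(value).exists():
            manifest["inputs"][name] = {"path": value, "sha256": _checksum(value)}

    stage = "cohort"
    try:
        report = cohort.LoadReport()
        records = cohort.load_mutation_table(
            config.mutations, missense_only=config.missense_only, report=report
        )
        metadata = cohort.load_sample_metadata(
            config.samples, hypermut_cutoff=config.hypermut_cutoff
        )
        matrix = cohort.filter_cohort(
            records, metadata,
            vaf_min=config.vaf_min,
            recurrence_min=config.recurrence_min,
            hypermut_cutoff=config.hypermut_cutoff,
        )
        matrix.to_tsv(out / "cohort_matrix.tsv")
        cohort.write_provenance(
            out / "provenance.json",
            filters={
                "vaf_min": config.vaf_min,
                "recurrence_min": config.recurrence_min,
                "hypermut_cutoff": config.hypermut_cutoff,
                "missense_only": config.missense_only,
            },
            report=report,
        )
        manifest["stages"][stage] = {
            "n_samples": matrix.n_samples, "n_mutations": len(matrix.mutations)
        }

        stage = "pair_mining"
        catalog = (
            cohort.DriverCatalog.from_file(config.driver_catalog)
            if config.driver_catalog
            else cohort.DriverCatalog.from_keys([])
        )
        results = pairs.mine_pairs(
            matrix, catalog,
            q_threshold=config.q_threshold, min_joint=config.min_joint,
        )
        pairs.write_pairs_tsv(results, out / "pairs.tsv")
        pairs.summarize_pairs(results).to_csv(out / "pair_summary.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_reported_pairs": len(results)}

        stage = "annotation"
        if "annotation" in config.stages and config.pathways_gmt:
            collection = annotate.GeneSetCollection.from_gmt(config.pathways_gmt)
            annotate.pathway_sharing_table(results, collection).to_csv(
                out / "pathway_sharing.tsv", sep="\t", index=False
            )
            fractions = annotate.tissue_fractions(
                results, matrix, metadata, mode=config.tissue_fraction_mode
            )
            fractions.to_csv(out / "tissue_fractions.tsv", sep="\t", index=False, float_format="%.6g")
            bubble = annotate.pathway_tissue_bubble(results, matrix, metadata, collection)
            bubble.to_csv(out / "bubble.tsv", sep="\t", index=False, float_format="%.6g")
            annotate.pathway_tissue_filter(
                bubble, config.min_pathway_tumors, config.min_pathway_rate
            ).to_csv(out / "bubble_filtered.tsv", sep="\t", index=False, float_format="%.6g")
        if "annotation" in config.stages and config.sl_pairs:
            sl_ref = annotate.SLReference.from_tsv(config.sl_pairs)
            annotate.sl_enrichment(results, sl_ref).to_csv(
                out / "sl_enrichment.tsv", sep="\t", index=False, float_format="%.6g"
            )
        manifest["stages"][stage] = {"annotated": bool(config.pathways_gmt)}

        stage = "subnetwork"
        if ("subnetwork" in config.stages and config.network_edges
                and config.subnetwork_tissue):
            net = network.load_network(config.network_edges)
            seeds = network.select_seeds(
                results, matrix, metadata,
                tissue=config.subnetwork_tissue,
                fraction_threshold=config.seed_fraction_threshold,
                mode=config.tissue_fraction_mode,
            )
            (out / "seeds.txt").write_text("\n".join(sorted(seeds)) + "\n")
            cfg = network.PageRankConfig(
                alpha=config.pagerank_alpha,
                max_iterations=config.pagerank_iterations,
                personalization={s: 1.0 for s in seeds},
            )
            scores = network.personalized_pagerank(net, cfg)
            sub = network.extract_subnetwork(
                net, scores, config.score_threshold, seeds=sorted(seeds)
            )
            network.write_sif(sub, out / "subnetwork.sif")
            network.write_graphml(sub, out / "subnetwork.graphml")
            sens = network.alpha_sensitivity(net, sorted(seeds))
            sens.to_csv(out / "alpha_sensitivity.tsv", sep="\t", index=False, float_format="%.6g")
            if config.pathways_gmt and config.n_random > 0:
                collection = annotate.GeneSetCollection.from_gmt(config.pathways_gmt)
                robust = network.enrichment_robustness(
                    net, sorted(seeds), collection,
                    n_random=config.n_random,
                    score_threshold=config.robustness_score_threshold,
                    alpha=config.pagerank_alpha,
                    seed=config.seed,
                )
                robust.to_csv(out / "robustness.tsv", sep="\t", index=False, float_format="%.6g")
            manifest["stages"][stage] = {
                "n_seeds": len(seeds),
                "subnetwork_nodes": sub.number_of_nodes(),
                "subnetwork_edges": sub.number_of_edges(),
            }

        stage = "metastasis"
        if "metastasis" in config.stages:
            _run_metastasis_stage(config, matrix, metadata, out, manifest)

        stage = "transcriptome"
        if ("transcriptome" in config.stages and config.expression
                and config.anchor_mutations and config.partner_gene):
            _run_transcriptome_stage(config, matrix, results, out, manifest)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc!r}\n")
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _run_metastasis_stage(config, matrix, metadata, out, manifest) -> None:
    pos_matrix = cohort.collapse_to_position(matrix)
    db = metastasis.TransactionDB.from_matrix(pos_matrix, metadata)
    itemsets = metastasis.fp_growth(db, config.min_support)
    rules = metastasis.association_rules(itemsets, db, config.min_confidence)
    tree = metastasis.build_marker_tree(
        rules, itemsets, min_confidence=config.min_confidence
    )
    tree.to_json(out / "marker_tree.json")
    tree.to_dot(out / "marker_tree.dot")
    freq = metastasis.pair_frequency_comparison(pos_matrix, metadata)
    freq.to_csv(out / "propensity.tsv", sep="\t", index=False, float_format="%.6g")
    met_ids = [s for s in pos_matrix.samples if metadata[s].sample_type == "metastatic"]
    stats = metastasis.cohort_pair_stats(pos_matrix.subset_samples(met_ids))
    stats["volcano_class"] = [
        metastasis.volcano_classify(
            row.odds_ratio, row.fisher_p,
            config.volcano_or_log_threshold, config.volcano_p_log_threshold,
            table=pairs.ContingencyTable(row.a, row.b, row.c, row.d),
        )[0]
        for row in stats.itertuples(index=False)
    ]
    stats.to_csv(out / "pair_stats.tsv", sep="\t", index=False, float_format="%.6g")
    manifest["stages"]["metastasis"] = {
        "n_itemsets": len(itemsets), "n_rules": len(rules),
        "tree_nodes": len(tree.nodes), "tree_edges": len(tree.edges),
    }


def _run_transcriptome_stage(config, matrix, results, out, manifest) -> None:
    tpm = expr.read_expression(config.expression)
    pattern = expr.PairPattern(
        anchor=frozenset(cohort.parse_key(k) for k in config.anchor_mutations),
        partner_gene=config.partner_gene,
    )
    group1, group2 = expr.assign_groups(results, matrix, pattern)
    group1 = [s for s in group1 if s in tpm.columns]
    group2 = [s for s in group2 if s in tpm.columns]
    de = expr.differential_expression(
        tpm, group1, group2,
        fc_cut=config.fc_cut, q_cut=config.q_cut,
        pseudocount=config.pseudocount,
    )
    de.to_csv(out / "de_results.tsv", sep="\t", float_format="%.6g")
    degs = de[de["status"] != expr.NS].sort_values("log2fc", ascending=False)
    if len(degs):
        z = expr.zscore_matrix(tpm, list(degs.index), group1, group2)
        z.to_csv(out / "zscores.tsv", sep="\t", float_format="%.6g")
    manifest["stages"]["transcriptome"] = {
        "n_group1": len(group1), "n_group2": len(group2),
        "n_up": int((de["status"] == expr.UP).sum()),
        "n_down": int((de["status"] == expr.DOWN).sum()),
    }
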