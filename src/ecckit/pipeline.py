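"""End-to-end pipeline orchestration with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ecckit import architecture, classify, interactome, qtl, seqio, simulate

log = logging.getLogger("ecckit")


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run.

    Every threshold default matches the package-wide default; None input
    paths switch the corresponding stage off.
    """

    fasta: str | None = None
    matings: str | None = None
    phenotypes: str | None = None
    geno: str | None = None
    gmap: str | None = None
    pheno: str | None = None
    out_dir: str = "ecckit_out"
    seed: int = 0
    # thresholds (defaults mirror the module constants)
    min_support: int = interactome.MIN_SUPPORT
    theta_polar: int = architecture.THETA_POLAR
    theta_helix: float = architecture.THETA_HELIX
    theta_rpw8: float = classify.THETA_RPW8
    max_mismatch: int = 0
    alpha: float = 0.05
    n_perm: int = 1000
    lod_max: float = qtl.LOD_MAX
    drop: float = 1.5
    rpw8_consensus: str = simulate.RPW8_SIGNATURE

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """annotate -> classify -> (optional) network stats -> (optional) QTL.

    Writes every stage output under ``config.out_dir`` plus a manifest
    (config hash, seed, input checksums, per-stage outputs).  Identical
    config and inputs give byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "applied_defaults": {
            "min_support": config.min_support,
            "theta_polar": config.theta_polar,
            "theta_helix": config.theta_helix,
            "theta_rpw8": config.theta_rpw8,
            "lod_drop": config.drop,
        },
    }
    for key in ("fasta", "matings", "phenotypes", "geno", "gmap", "pheno"):
        path = getattr(config, key)
        if path:
            if not Path(path).exists():
                raise FileNotFoundError(f"{key} input not found: {path}")
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    groups = {}
    if config.fasta:
        log.info("stage annotate: %s", config.fasta)
        records = seqio.read_fasta(config.fasta)
        annotations = [
            architecture.annotate_ecc(
                r,
                max_mismatch=config.max_mismatch,
                theta_polar=config.theta_polar,
                theta_helix=config.theta_helix,
            )
            for r in records
        ]
        for ann in annotations:
            classify.classify_group(
                ann, rpw8_profile=config.rpw8_consensus, theta_rpw8=config.theta_rpw8
            )
            groups[ann.record.id] = ann.group.group
        gff = out / "annotations.gff3"
        gff.write_text(architecture.annotation_to_gff3(annotations))
        table = out / "annotations.tsv"
        architecture.annotation_table(annotations).to_csv(table, sep="\t", index=False)
        manifest["outputs"]["annotations"] = [str(gff), str(table)]

    if config.matings:
        log.info("stage network: %s", config.matings)
        matings = interactome.read_matings(config.matings)
        edges = interactome.call_interactions(matings, min_support=config.min_support)
        nodes = sorted({m.bait for m in matings} | {m.prey for m in matings})
        net = interactome.build_network(nodes, edges)
        summary = interactome.network_summary(net)
        edge_path = out / "network_edges.tsv"
        interactome.network_to_edge_table(net).to_csv(edge_path, sep="\t", index=False)
        graphml_path = out / "network.graphml"
        interactome.write_graphml(net, graphml_path)
        stats = {
            "n_nodes": summary.n_nodes,
            "n_self": summary.n_self,
            "n_hetero": summary.n_hetero,
            "n_nodes_with_hetero": summary.n_nodes_with_hetero,
            "higher_affinity": sorted(interactome.higher_affinity_partners(net)),
        }
        if config.phenotypes:
            phenos = seqio.read_phenotypes(config.phenotypes)
            try:
                r, p = interactome.degree_phenotype_correlation(net, phenos)
                stats["degree_phenotype_r"] = r
                stats["degree_phenotype_p"] = p
            except ValueError as exc:
                stats["degree_phenotype_error"] = str(exc)
        stats_path = out / "network_stats.json"
        stats_path.write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
        manifest["outputs"]["network"] = [str(edge_path), str(stats_path)]

    if config.geno and config.gmap and config.pheno:
        log.info("stage qtl: %s", config.geno)
        pop = qtl_read(config.geno, config.gmap, config.pheno)
        scan = qtl.scan_with_threshold(
            pop, n_perm=config.n_perm, alpha=config.alpha,
            seed=config.seed, drop=config.drop,
        )
        marker_info = {m[0]: (m[1], m[2]) for m in pop.gmap.markers}
        scan_path = out / "qtl_scan.tsv"
        rows = [
            {"marker": m, "chrom": marker_info[m][0], "cm": marker_info[m][1],
             "lod": scan.lod[m]}
            for m in pop.gmap.names
        ]
        import pandas as pd

        pd.DataFrame(rows).to_csv(scan_path, sep="\t", index=False)
        summary_path = out / "qtl_summary.json"
        summary_path.write_text(
            json.dumps(
                {
                    "threshold": scan.threshold,
                    "peaks": scan.peaks,
                    "support_intervals": scan.support_intervals,
                    "model": "single-marker regression (additive + dominance)",
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        manifest["outputs"]["qtl"] = [str(scan_path), str(summary_path)]

    if groups:
        groups_path = out / "groups.tsv"
        with open(groups_path, "w", encoding="utf-8") as fh:
            fh.write("id\tgroup\n")
            for rid in sorted(groups):
                fh.write(f"{rid}\t{groups[rid]}\n")
        manifest["outputs"]["groups"] = [str(groups_path)]

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def qtl_read(geno_path, map_path, pheno_path) -> qtl.F2Population:
    """Assemble an F2 population from genotype/map/phenotype CSV files."""
    import pandas as pd

    map_df = pd.read_csv(map_path)
    markers = tuple(
        (str(r.marker), str(r.chromosome), float(r.cm)) for r in map_df.itertuples()
    )
    gmap = qtl.GeneticMap(markers=markers)
    geno = pd.read_csv(geno_path)
    geno = geno[gmap.names]
    pheno = pd.read_csv(pheno_path)["phenotype"].to_numpy(dtype=float)
    return qtl.F2Population(gmap=gmap, genotypes=geno, phenotype=pheno)


def qtl_write(pop: qtl.F2Population, geno_path, map_path, pheno_path) -> None:
    import pandas as pd

    pop.genotypes.to_csv(geno_path, index=False)
    pd.DataFrame(
        [{"marker": m, "chromosome": c, "cm": p} for m, c, p in pop.gmap.markers]
    ).to_csv(map_path, index=False)
    pd.DataFrame({"phenotype": pop.phenotype}).to_csv(pheno_path, index=False)
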