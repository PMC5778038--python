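"""Annotation and exoproteome overlays, comparison tables, and the run report.

Joins three layers of evidence onto networks and clusters: CAZy
(carbohydrate-active enzyme) class/family labels per gene, secreted-protein
detections per species × condition, and differential-expression calls.
Produces the per-region Venn tables, CAZy family distributions, and a
single machine-readable run report whose every count is recomputable from
the artifacts it summarises.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import pandas as pd

from coregnet.coexpression import CoexpressionNetwork, network_stats
from coregnet.diffexpr import de_summary, venn
from coregnet.hcca import ClusterAssignment
from coregnet.preprocessing import FilterReport, InputError

logger = logging.getLogger(__name__)

CAZY_CLASSES = ("GH", "AA", "GT", "CBM", "CE")


def _class_of_family(family: str) -> str:
    for cls in sorted(CAZY_CLASSES, key=len, reverse=True):
        if family.startswith(cls):
            return cls
    raise InputError(f"CAZy family {family!r} has no recognised class prefix")


@dataclass
class AnnotationSet:
    """Gene → CAZy class/family plus secreted flags per species × condition.

    ``cazy`` is indexed by gene ID with columns ``cazy_class`` and
    ``cazy_family``; ``secreted`` has one row per flagged
    (gene_id, species, condition) cell.
    """

    cazy: pd.DataFrame
    secreted: pd.DataFrame

    def __post_init__(self) -> None:
        if self.cazy.empty:
            self.cazy = pd.DataFrame(columns=["cazy_class", "cazy_family"])
        if self.secreted.empty:
            self.secreted = pd.DataFrame(columns=["gene_id", "species", "condition"])
        for gene, row in self.cazy.iterrows():
            if _class_of_family(str(row["cazy_family"])) != row["cazy_class"]:
                raise InputError(
                    f"gene {gene!r}: family {row['cazy_family']!r} does not match "
                    f"class {row['cazy_class']!r}"
                )

    @property
    def cazy_genes(self) -> set[str]:
        return set(self.cazy.index)

    def class_of(self, gene: str) -> str | None:
        if gene in self.cazy.index:
            return str(self.cazy.loc[gene, "cazy_class"])
        return None

    def family_of(self, gene: str) -> str | None:
        if gene in self.cazy.index:
            return str(self.cazy.loc[gene, "cazy_family"])
        return None

    def secreted_genes(self, species: str | None = None, condition: str | None = None) -> set[str]:
        """Genes flagged secreted, optionally restricted to a species/condition."""
        t = self.secreted
        if species is not None:
            t = t[t["species"] == species]
        if condition is not None:
            t = t[t["condition"] == condition]
        return set(t["gene_id"])

    def to_tsv(self, cazy_path, secreted_path) -> None:
        self.cazy.to_csv(cazy_path, sep="\t", index_label="gene_id")
        self.secreted.to_csv(secreted_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, cazy_path, secreted_path=None) -> "AnnotationSet":
        cazy = pd.read_csv(cazy_path, sep="\t", index_col=0, dtype=str)
        cazy.index = cazy.index.astype(str)
        if secreted_path is not None:
            secreted = pd.read_csv(secreted_path, sep="\t", dtype=str)
        else:
            secreted = pd.DataFrame(columns=["gene_id", "species", "condition"])
        return cls(cazy=cazy, secreted=secreted)


@dataclass
class ProteomeTable:
    """Detected proteins with their mapped gene IDs per species × condition.

    Columns: protein_id, gene_id (empty string when the protein has no
    mapped gene), species, condition, detected (bool). The combination
    (protein_id, species, condition) is unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"protein_id", "gene_id", "species", "condition", "detected"}
        missing = required - set(self.table.columns)
        if missing:
            raise InputError(f"proteome table missing columns: {sorted(missing)}")
        key = self.table[["protein_id", "species", "condition"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise InputError(f"duplicate proteome row for {tuple(dup)}")

    def detected(self, species: str | None = None, condition: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["detected"].astype(bool)]
        if species is not None:
            t = t[t["species"] == species]
        if condition is not None:
            t = t[t["condition"] == condition]
        return t

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProteomeTable":
        t = pd.read_csv(
            path, sep="\t",
            dtype={"protein_id": str, "gene_id": str, "species": str, "condition": str},
            keep_default_na=False,
        )
        t["detected"] = t["detected"].astype(str).str.lower().isin(("true", "1", "yes"))
        return cls(t)


def flag_secreted_nodes(
    net: CoexpressionNetwork, prot: ProteomeTable, species: str
) -> CoexpressionNetwork:
    """Mark network genes encoding secreted proteins detected for a species.

    A node gets ``secreted=True`` iff any detected protein maps to it for
    the given species, in any condition. Detections whose gene ID is
    missing or absent from the network are ignored and counted in the log.
    """
    g = net.graph.copy()
    detected = prot.detected(species=species)
    unmapped = 0
    for gene in detected["gene_id"]:
        if gene and gene in g:
            g.nodes[gene]["secreted"] = True
        else:
            unmapped += 1
    if unmapped:
        logger.info(
            "flag_secreted_nodes(%s): %d detections without a resolvable gene", species, unmapped
        )
    return CoexpressionNetwork(g)


def protein_venn(prot: ProteomeTable) -> dict[tuple[str, ...], set]:
    """Venn regions over per-species detected-protein sets."""
    per_species = {
        sp: set(prot.detected(species=sp)["protein_id"]) for sp in prot.species
    }
    if len(per_species) < 2:
        raise InputError(f"protein_venn needs ≥2 species, got {len(per_species)}")
    return venn(per_species)


def family_distribution(genes: set[str], ann: AnnotationSet) -> dict:
    """CAZy class and family counts over a gene set; unannotated counted as none.

    Class counts are the sums of their family counts, and
    ``sum(classes) + none == len(genes)``.
    """
    classes: dict[str, int] = {}
    families: dict[str, int] = {}
    unannotated = 0
    for g in genes:
        fam = ann.family_of(g)
        if fam is None:
            unannotated += 1
            continue
        cls = ann.class_of(g)
        classes[cls] = classes.get(cls, 0) + 1
        families[fam] = families.get(fam, 0) + 1
    return {
        "classes": dict(sorted(classes.items())),
        "families": dict(sorted(families.items())),
        "none": unannotated,
    }


@dataclass
class RunReport:
    """Structured run summary: one section per pipeline stage.

    ``sections`` maps a section name to a flat dict of keys → scalars or
    embedded tables (list-of-rows). Serialised as diffable structured text.
    """

    sections: dict = field(default_factory=dict)

    def to_text(self) -> str:
        buf = io.StringIO()
        for name, content in self.sections.items():
            buf.write(f"[{name}]\n")
            for key, value in content.items():
                if isinstance(value, list):
                    buf.write(f"{key}:\n")
                    for row in value:
                        buf.write("\t" + "\t".join(str(x) for x in row) + "\n")
                else:
                    buf.write(f"{key}={value}\n")
            buf.write("\n")
        return buf.getvalue()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())


def _cluster_rows(clusters: ClusterAssignment, ann: AnnotationSet, secreted: set[str]):
    rows = []
    for k, members in enumerate(clusters.clusters):
        dist = family_distribution(members, ann)
        families = ",".join(f"{fam}:{n}" for fam, n in dist["families"].items())
        rows.append(
            (
                k,
                len(members),
                sum(dist["classes"].values()),
                families or "-",
                len(members & secreted),
                round(clusters.scores[k], 4),
            )
        )
    return rows


def build_report(
    filter_report: FilterReport,
    de_table,
    presence: dict[tuple[str, str], set[str]],
    full_net: CoexpressionNetwork,
    cazy_net: CoexpressionNetwork,
    clusters: ClusterAssignment,
    ann: AnnotationSet,
) -> RunReport:
    """Assemble the machine-readable run report from the pipeline artifacts.

    Raises when the artifacts disagree about the gene universe: the network
    must be built on (a subset of) the kept genes and the clustering must
    cover exactly the network's nodes.
    """
    kept = set(filter_report.kept)
    net_nodes = set(full_net.graph.nodes)
    stray = net_nodes - kept
    if stray:
        raise InputError(f"network genes absent from kept set: {sorted(stray)[:5]}")
    cluster_universe = set().union(*clusters.clusters, clusters.unassigned)
    if cluster_universe != net_nodes:
        diff = cluster_universe ^ net_nodes
        raise InputError(f"cluster/network gene universes differ: {sorted(diff)[:5]}")

    secreted_nodes = {
        g for g, d in full_net.graph.nodes(data=True) if d.get("secreted", False)
    }
    presence_regions = venn(
        {f"{sp}_{cond}": s for (sp, cond), s in presence.items()}
    ) if 2 <= len(presence) <= 4 else None

    report = RunReport()
    report.sections["filter"] = {
        "n_input": len(filter_report.kept) + len(filter_report.removed),
        "n_kept": len(filter_report.kept),
        "n_removed": len(filter_report.removed),
        "rule": filter_report.rule,
    }
    summary = de_summary(de_table)
    report.sections["differential_expression"] = {
        "contrast": f"{de_table.contrast[0]} vs {de_table.contrast[1]}",
        "n_up_in_A": summary["up_in_A"],
        "n_up_in_B": summary["up_in_B"],
        "n_none": summary["none"],
    }
    pres = {"cells": [(sp, cond, len(s)) for (sp, cond), s in sorted(presence.items())]}
    if presence_regions is not None:
        pres["venn"] = [
            ("&".join(sig), len(members))
            for sig, members in sorted(presence_regions.items())
        ]
    report.sections["presence"] = pres
    full_stats = network_stats(full_net)
    cazy_stats = network_stats(cazy_net)
    report.sections["network"] = {
        "full_nodes": full_stats["nodes"],
        "full_edges": full_stats["edges"],
        "full_components": full_stats["components"],
        "full_max_degree": full_stats["max_degree"],
        "cazy_nodes": cazy_stats["nodes"],
        "cazy_edges": cazy_stats["edges"],
        "cazy_components": cazy_stats["components"],
    }
    report.sections["clusters"] = {
        "n_clusters": len(clusters.clusters),
        "n_clustered": clusters.n_clustered,
        "n_unassigned": len(clusters.unassigned),
        "table": [("cluster_id", "n_genes", "n_cazy", "families", "n_secreted", "score")]
        + _cluster_rows(clusters, ann, secreted_nodes),
    }
    report.sections["secreted"] = {
        "n_flagged_in_network": len(secreted_nodes),
        "n_flagged_cazy": len(secreted_nodes & ann.cazy_genes),
    }
    return report


def audit_report(
    report: RunReport,
    filter_report: FilterReport,
    de_table,
    presence: dict[tuple[str, str], set[str]],
    full_net: CoexpressionNetwork,
    cazy_net: CoexpressionNetwork,
    clusters: ClusterAssignment,
    ann: AnnotationSet,
) -> list[str]:
    """Recompute every report count from the artifacts; return discrepancies.

    An empty list means the report round-trips: each number it states can
    be reproduced from the objects it cites.
    """
    problems: list[str] = []

    def check(section: str, key: str, expected) -> None:
        actual = report.sections.get(section, {}).get(key)
        if actual != expected:
            problems.append(f"{section}.{key}: report={actual!r} recomputed={expected!r}")

    check("filter", "n_kept", len(filter_report.kept))
    check("filter", "n_removed", len(filter_report.removed))
    check("filter", "n_input", len(filter_report.kept) + len(filter_report.removed))
    summary = de_summary(de_table)
    check("differential_expression", "n_up_in_A", summary["up_in_A"])
    check("differential_expression", "n_up_in_B", summary["up_in_B"])
    check("differential_expression", "n_none", summary["none"])
    check("network", "full_nodes", full_net.graph.number_of_nodes())
    check("network", "full_edges", full_net.graph.number_of_edges())
    check("network", "cazy_nodes", cazy_net.graph.number_of_nodes())
    check("network", "cazy_edges", cazy_net.graph.number_of_edges())
    check("clusters", "n_clusters", len(clusters.clusters))
    check("clusters", "n_clustered", clusters.n_clustered)
    check("clusters", "n_unassigned", len(clusters.unassigned))
    if clusters.n_clustered + len(clusters.unassigned) != full_net.graph.number_of_nodes():
        problems.append("clusters: sizes + unassigned != network nodes")
    secreted_nodes = {
        g for g, d in full_net.graph.nodes(data=True) if d.get("secreted", False)
    }
    check("secreted", "n_flagged_in_network", len(secreted_nodes))
    cells = report.sections.get("presence", {}).get("cells", [])
    for sp, cond, n in cells:
        if len(presence.get((sp, cond), set())) != n:
            problems.append(f"presence.{sp}_{cond}: report={n}")
    return problems
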