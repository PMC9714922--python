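"""End-to-end orchestration: cluster → annotate → build DAG → evaluate → report.

Every stage is a plain function over in-memory objects with a TSV/JSON
serialisation, so the monolithic :func:`run_pipeline` and the CLI
subcommands compose the same code paths and produce identical files.
All thresholds sit in :class:`PipelineConfig`, whose defaults are the
analysis's canonical values (b > 1, 90 % identity / 90 % length, > 75 %
interface overlap, 5 Å contacts, 1.4 Å probe, 5 % surface RASA, 500
bootstrap resamples at 90 % confidence).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .clustering import ClusterRecord, cluster_chains, read_cluster_tsv, write_cluster_tsv
from .disorder import high_b_set, normalize_b
from .hierarchy import (AssemblyDAG, StructureAnnotation, build_edges,
                        dag_to_dot, group_nodes, partner_signature)
from .interfaces import nucleic_interface, protein_interface, surface_residues
from .stats import (PredictionRecord, aggregate, evaluate_cluster,
                    fraction_above_diagonal, records_frame)
from .structures import ComplexRecord, load_manifest_structures

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with canonical defaults."""

    manifest: str | Path = ""
    outdir: str | Path = "softhier_out"
    clusters_tsv: str | Path | None = None   # external clustering hook
    b_threshold: float = 1.0
    overlap_threshold: float = 0.75
    contact_cutoff: float = 5.0      # Å
    probe: float = 1.4               # Å
    sasa_points: int = 300
    rasa_cutoff: float = 5.0         # %, surface definition
    identity_min: float = 90.0       # %
    length_ratio_min: float = 0.9
    tests: tuple[str, ...] = ("edge", "k_shell", "all_shell")
    restrictions: tuple[str, ...] = ("C_all", "C_minus_IR", "S_all", "S_minus_IR")
    bootstrap_n: int = 500
    bootstrap_level: float = 90.0
    seed: int = 0
    dot: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tests", "restrictions"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @property
    def needs_surface(self) -> bool:
        return any(r.startswith("S") for r in self.restrictions)


def _split_structure_id(structure_id: str) -> tuple[str, str]:
    entry, chain = structure_id.rsplit("_", 1)
    return entry, chain


def stage_cluster(structures: list[ComplexRecord],
                  cfg: PipelineConfig) -> list[ClusterRecord]:
    chains = [c for s in structures for c in s.chains]
    metadata = {c.structure_id: (s.resolution, s.r_value)
                for s in structures for c in s.chains}
    if cfg.clusters_tsv:
        return read_cluster_tsv(cfg.clusters_tsv,
                                {c.structure_id: c for c in chains})
    return cluster_chains(chains, metadata,
                          identity_min=cfg.identity_min,
                          length_ratio_min=cfg.length_ratio_min)


def stage_annotate(
    structures: list[ComplexRecord],
    clusters: list[ClusterRecord],
    cfg: PipelineConfig,
) -> dict[str, dict]:
    """Per cluster: representative length plus mapped member annotations."""
    by_entry = {s.entry_id: s for s in structures}
    cluster_of = {mid: cl.representative_id
                  for cl in clusters for mid in cl.member_ids}
    out: dict[str, dict] = {}
    for cl in clusters:
        rep_entry, rep_chain = _split_structure_id(cl.representative_id)
        rep = by_entry[rep_entry].chain(rep_chain)
        annotations: list[StructureAnnotation] = []
        for mid in cl.member_ids:
            entry, chain_name = _split_structure_id(mid)
            cx = by_entry[entry]
            ch = cx.chain(chain_name)
            if len(ch.observed_positions()) < 2:
                logger.warning("%s: fewer than 2 observed residues, skipped", mid)
                continue
            pi = protein_interface(cx, chain_name, cutoff=cfg.contact_cutoff)
            ni = nucleic_interface(cx, chain_name, probe=cfg.probe,
                                   n_points=cfg.sasa_points)
            sig = partner_signature(cx, chain_name, cluster_of, pi, ni)
            profile = normalize_b(ch)
            high = high_b_set(profile, cfg.b_threshold)
            mapping = cl.maps.get(mid, {})
            remap = lambda s: {mapping[p] for p in s if p in mapping}  # noqa: E731
            annotations.append(StructureAnnotation(
                structure_id=mid, entry_id=entry, signature=sig,
                ir_protein=remap(pi.union()),
                ir_nucleic=remap(ni.union()),
                high_b=remap(high),
                missing=remap(ch.missing_positions()),
                observed=remap(ch.observed_positions()),
            ))
        if annotations:
            out[cl.representative_id] = {
                "rep_length": len(rep.sequence),
                "annotations": annotations,
            }
    return out


def stage_dag(annotated: dict[str, dict],
              cfg: PipelineConfig) -> dict[str, AssemblyDAG]:
    dags = {}
    for rep_id, payload in annotated.items():
        nodes = group_nodes(payload["annotations"],
                            overlap_min=cfg.overlap_threshold)
        dags[rep_id] = build_edges(nodes, overlap_min=cfg.overlap_threshold)
    return dags


def stage_surfaces(
    structures: list[ComplexRecord],
    clusters: list[ClusterRecord],
    dags: dict[str, AssemblyDAG],
    cfg: PipelineConfig,
) -> dict[str, dict[str, set[int]]]:
    """Surface set per non-leaf node: the first member's full parent complex,
    RASA above the cutoff, mapped to representative coordinates."""
    by_entry = {s.entry_id: s for s in structures}
    cluster_by_rep = {cl.representative_id: cl for cl in clusters}
    out: dict[str, dict[str, set[int]]] = {}
    for rep_id, dag in dags.items():
        cl = cluster_by_rep.get(rep_id)
        per_node: dict[str, set[int]] = {}
        for nid in sorted(dag.nodes):
            node = dag.nodes[nid]
            if not dag.graph.out_degree(nid) or not node.members:
                continue
            first = node.members[0]
            entry, chain_name = _split_structure_id(first.structure_id)
            surf = surface_residues(by_entry[entry], chain_name,
                                    rasa_cutoff=cfg.rasa_cutoff,
                                    probe=cfg.probe, n_points=cfg.sasa_points)
            mapping = cl.maps.get(first.structure_id, {}) if cl else {}
            per_node[nid] = {mapping[p] for p in surf if p in mapping}
        out[rep_id] = per_node
    return out


def stage_evaluate(
    annotated: dict[str, dict],
    dags: dict[str, AssemblyDAG],
    surfaces: dict[str, dict[str, set[int]]],
    cfg: PipelineConfig,
) -> list[PredictionRecord]:
    records: list[PredictionRecord] = []
    for rep_id in sorted(dags):
        records.extend(evaluate_cluster(
            dags[rep_id],
            rep_length=annotated[rep_id]["rep_length"],
            cluster_id=rep_id,
            tests=cfg.tests,
            restrictions=cfg.restrictions,
            surface_by_node=surfaces.get(rep_id),
        ))
    return records


def stage_report(records: list[PredictionRecord], dags: dict[str, AssemblyDAG],
                 cfg: PipelineConfig) -> tuple[dict, dict]:
    aggregates = {
        group_by: aggregate(records, group_by=group_by,
                            n_resamples=cfg.bootstrap_n,
                            level=cfg.bootstrap_level, seed=cfg.seed)
        for group_by in ("all", "K", "plus_k")
    }
    edge_hist: dict[str, int] = {}
    n_edges = 0
    for dag in dags.values():
        for u, v, k in dag.edges():
            key = f"K{dag.nodes[u].K}+{k}"
            edge_hist[key] = edge_hist.get(key, 0) + 1
            n_edges += 1
    summary = {
        "n_clusters": len(dags),
        "n_nodes": sum(len(d.nodes) for d in dags.values()),
        "n_edges": n_edges,
        "edges_by_K_plus_k": dict(sorted(edge_hist.items())),
        "n_records": len(records),
        "fraction_above_diagonal": fraction_above_diagonal(records),
    }
    return aggregates, summary


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle into ``cfg.outdir``.

    Returns a dict with the in-memory results (clusters, dags, records,
    aggregates, summary).  Fully deterministic given ``cfg.seed``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failure_marker = outdir / "FAILED"
    try:
        structures = load_manifest_structures(cfg.manifest)
        clusters = stage_cluster(structures, cfg)
        write_cluster_tsv(clusters, outdir / "clusters.tsv")
        annotated = stage_annotate(structures, clusters, cfg)
        write_annotations_json(annotated, outdir / "annotations.json")
        dags = stage_dag(annotated, cfg)
        write_all_dags(dags, outdir, dot=cfg.dot)
        surfaces = (stage_surfaces(structures, clusters, dags, cfg)
                    if cfg.needs_surface else {})
        records = stage_evaluate(annotated, dags, surfaces, cfg)
        df = records_frame(records)
        df.to_csv(outdir / "predictions.tsv", sep="\t", index=False,
                  float_format=FLOAT_FMT)
        # aggregate from the serialised table so that a stepwise CLI run
        # (which reloads predictions.tsv) reproduces this output exactly
        records = read_predictions_tsv(outdir / "predictions.tsv")
        aggregates, summary = stage_report(records, dags, cfg)
        for group_by, adf in aggregates.items():
            adf.to_csv(outdir / f"aggregates_{group_by}.tsv", sep="\t",
                       index=False, float_format=FLOAT_FMT)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n")
    except Exception:
        failure_marker.write_text("pipeline failed; partial outputs preserved\n")
        raise
    if failure_marker.exists():
        failure_marker.unlink()
    return {"structures": structures, "clusters": clusters,
            "annotated": annotated, "dags": dags, "records": records,
            "aggregates": aggregates, "summary": summary}


# ---------------------------------------------------------------------------
# serialisation helpers shared by run_pipeline and the CLI subcommands

def read_predictions_tsv(path: str | Path) -> list[PredictionRecord]:
    import pandas as pd

    from .stats import ConfusionCounts, MetricSet

    df = pd.read_csv(path, sep="\t")
    records: list[PredictionRecord] = []
    for row in df.itertuples(index=False):
        counts = ConfusionCounts(TP=int(row.TP), FP=int(row.FP),
                                 FN=int(row.FN), TN=int(row.TN))
        metric = MetricSet(Sen=row.Sen, Spe=row.Spe, Acc=row.Acc,
                           PPV=row.PPV, NPV=row.NPV,
                           r_D=row.Sen_r, r_I=row.PPV_r)
        child = row.child_node if isinstance(row.child_node, str) else None
        records.append(PredictionRecord(
            cluster=row.cluster, parent_node=row.parent_node,
            test=row.test, restriction=row.restriction,
            K=int(row.K), plus_k=int(row.plus_k),
            counts=counts, metrics=metric, child_node=child))
    return records


def write_annotations_json(annotated: dict[str, dict], path: str | Path) -> None:
    payload = {}
    for rep_id, entry in annotated.items():
        payload[rep_id] = {
            "rep_length": entry["rep_length"],
            "annotations": [{
                "structure_id": a.structure_id,
                "entry_id": a.entry_id,
                "signature": list(a.signature),
                "ir_protein": sorted(a.ir_protein),
                "ir_nucleic": sorted(a.ir_nucleic),
                "high_b": sorted(a.high_b),
                "missing": sorted(a.missing),
                "observed": sorted(a.observed),
            } for a in entry["annotations"]],
        }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_annotations_json(path: str | Path) -> dict[str, dict]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for rep_id, entry in payload.items():
        out[rep_id] = {
            "rep_length": entry["rep_length"],
            "annotations": [StructureAnnotation(
                structure_id=a["structure_id"],
                entry_id=a["entry_id"],
                signature=tuple(a["signature"]),
                ir_protein=set(a["ir_protein"]),
                ir_nucleic=set(a["ir_nucleic"]),
                high_b=set(a["high_b"]),
                missing=set(a["missing"]),
                observed=set(a["observed"]),
            ) for a in entry["annotations"]],
        }
    return out


def write_all_dags(dags: dict[str, AssemblyDAG], outdir: Path,
                   dot: bool = False) -> None:
    nodes_path = outdir / "nodes.tsv"
    edges_path = outdir / "edges.tsv"
    with open(nodes_path, "w") as nf, open(edges_path, "w") as ef:
        nf.write("cluster\tnode_id\tK\tsignature\tmembers\n")
        ef.write("cluster\tparent\tchild\tk\n")
        for rep_id in sorted(dags):
            dag = dags[rep_id]
            for nid in sorted(dag.nodes):
                n = dag.nodes[nid]
                nf.write(f"{rep_id}\t{nid}\t{n.K}\t{','.join(n.signature)}\t"
                         f"{','.join(n.member_ids)}\n")
            for u, v, k in dag.edges():
                ef.write(f"{rep_id}\t{u}\t{v}\t{k}\n")
    if dot:
        for rep_id in sorted(dags):
            (outdir / f"dag_{rep_id}.dot").write_text(dag_to_dot(dags[rep_id]))
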