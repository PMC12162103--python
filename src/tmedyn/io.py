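"""Serialization: networks to/from GraphML and JSON, registries to/from
YAML/JSON config files."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import yaml

from .core import EdgeSpec, NetworkSpec, NodeSpec, ParameterSet

__all__ = [
    "network_to_json", "network_from_json",
    "network_to_graphml", "network_from_graphml",
    "params_to_yaml", "params_from_yaml",
    "params_to_json", "params_from_json",
]


def _edge_dict(edge: EdgeSpec) -> dict:
    d = {"kind": edge.kind, "target": edge.target,
         "parameter_keys": list(edge.parameter_keys)}
    if edge.source is not None:
        d["source"] = edge.source
    if edge.modulators:
        d["modulators"] = [list(m) for m in edge.modulators]
    if edge.kind == "regulatory_inhibition":
        d["applies_to"] = edge.applies_to
    return d


def network_to_json(network: NetworkSpec, path=None) -> str:
    doc = {
        "name": network.name,
        "nodes": [
            {"name": n.name, "role": n.role, "compartment": n.compartment,
             "family": n.family}
            for n in network.nodes
        ],
        "edges": [_edge_dict(e) for e in network.edges],
        "groups": {g: list(m) for g, m in network.groups.items()},
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def _is_path(source) -> bool:
    if isinstance(source, Path):
        return True
    return (
        isinstance(source, str)
        and "\n" not in source
        and len(source) < 4096
        and Path(source).exists()
    )


def network_from_json(source) -> NetworkSpec:
    doc = json.loads(Path(source).read_text() if _is_path(source) else source)
    nodes = [
        NodeSpec(n["name"], n["role"], n.get("compartment", "global"),
                 n.get("family"))
        for n in doc["nodes"]
    ]
    edges = [
        EdgeSpec(
            e["kind"], e["target"], e.get("source"),
            tuple(e.get("parameter_keys", ())),
            tuple(tuple(m) for m in e.get("modulators", ())),
            e.get("applies_to", "proliferation"),
        )
        for e in doc["edges"]
    ]
    return NetworkSpec(nodes, edges, groups={
        g: tuple(m) for g, m in doc.get("groups", {}).items()
    }, name=doc.get("name", ""))


def network_to_graphml(network: NetworkSpec, path) -> None:
    """Write the atlas as GraphML.

    Pooled (family/group) edge endpoints are expanded to their member nodes;
    each expanded copy carries the original endpoint names and a shared
    ``eid`` so :func:`network_from_graphml` can collapse them again.
    Source-free edges (proliferation, death, degradation) become self-loops.
    """
    g = nx.MultiDiGraph(name=network.name)
    g.graph["groups"] = json.dumps({k: list(v) for k, v in network.groups.items()})
    for node in network.nodes:
        g.add_node(node.name, role=node.role, compartment=node.compartment,
                   family=node.family or "")
    for eid, edge in enumerate(network.edges):
        attrs = {
            "eid": eid,
            "kind": edge.kind,
            "orig_source": edge.source or "",
            "orig_target": edge.target,
            "parameter_keys": ",".join(edge.parameter_keys),
            "modulators": json.dumps([list(m) for m in edge.modulators]),
            "applies_to": edge.applies_to,
        }
        sources = network.members(edge.source) if edge.source else None
        targets = network.members(edge.target)
        for tgt in targets:
            if sources is None:
                g.add_edge(tgt, tgt, **attrs)
            else:
                for src in sources:
                    g.add_edge(src, tgt, **attrs)
    nx.write_graphml(g, path)


def network_from_graphml(path) -> NetworkSpec:
    g = nx.read_graphml(path, force_multigraph=True)
    nodes = [
        NodeSpec(name, data["role"], data.get("compartment", "global"),
                 data.get("family") or None)
        for name, data in g.nodes(data=True)
    ]
    seen: dict[int, EdgeSpec] = {}
    for _, _, data in g.edges(data=True):
        eid = int(data["eid"])
        if eid in seen:
            continue
        keys = tuple(k for k in data.get("parameter_keys", "").split(",") if k)
        modulators = tuple(
            tuple(m) for m in json.loads(data.get("modulators", "[]"))
        )
        seen[eid] = EdgeSpec(
            data["kind"], data["orig_target"], data["orig_source"] or None,
            keys, modulators, data.get("applies_to", "proliferation"),
        )
    edges = [seen[eid] for eid in sorted(seen)]
    groups = {
        k: tuple(v) for k, v in json.loads(g.graph.get("groups", "{}")).items()
    }
    return NetworkSpec(nodes, edges, groups=groups, name=g.graph.get("name", ""))


def params_to_yaml(params: ParameterSet, path=None) -> str:
    text = yaml.safe_dump(params.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_yaml(source) -> ParameterSet:
    if _is_path(source):
        source = Path(source).read_text()
    return ParameterSet(yaml.safe_load(source))


def params_to_json(params: ParameterSet, path=None) -> str:
    text = json.dumps(params.to_dict(), indent=1, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_json(source) -> ParameterSet:
    if _is_path(source):
        source = Path(source).read_text()
    return ParameterSet(json.loads(source))
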