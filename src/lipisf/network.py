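"""Molecular-network export of annotation groups.

Each candidate lipid becomes a star graph: a parent node for the lipid at
the center, one node per matched ion form (adduct or in-source fragment),
and an edge carrying the transform name, the mass error and the ion image's
correlation to the group's best-matching form. Exports are static GraphML /
edge-list CSV consumable by Cytoscape or Gephi.
"""

from __future__ import annotations

from typing import Iterable, List

import networkx as nx
import pandas as pd

from .annotate import LipidAnnotationGroup, spatial_correlation
from .peakmatrix import PeakMatrix

EDGE_CSV_COLUMNS = [
    "parent", "ion_label", "transform", "kind", "observed_mz",
    "ppm_error", "correlation",
]


def build_network(
    groups: Iterable[LipidAnnotationGroup],
    pm: PeakMatrix = None,
) -> nx.Graph:
    """One star subgraph per scored group; pure function of its inputs.

    With ``pm`` given, each edge carries the Pearson correlation between
    that ion image and the group's reference form (the lowest-|ppm| match);
    without it the correlation attribute is 0.
    """
    g = nx.Graph()
    for grp in groups:
        parent = grp.lipid.name
        g.add_node(parent, role="parent", lipid_class=grp.lipid.lipid_class,
                   LO=grp.LO, C=grp.C, S=grp.S)
        ref = min(grp.matches, key=lambda m: abs(m.ppm_error))
        for m in grp.matches:
            label = f"{parent} {m.transform.name}"
            corr = 0.0
            if pm is not None and m.peak_index != ref.peak_index:
                corr = spatial_correlation(pm, [ref.peak_index, m.peak_index])
            elif pm is not None:
                corr = 1.0
            g.add_node(label, role=m.transform.kind, observed_mz=m.observed_mz)
            g.add_edge(parent, label, transform=m.transform.name,
                       kind=m.transform.kind, observed_mz=m.observed_mz,
                       ppm_error=m.ppm_error, correlation=corr)
    return g


def export_network(net: nx.Graph, path, format: str = "graphml") -> None:
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edge_csv":
        rows = []
        for u, v, data in net.edges(data=True):
            parent, ion = (u, v) if net.nodes[u].get("role") == "parent" else (v, u)
            rows.append(dict(
                parent=parent, ion_label=ion, transform=data["transform"],
                kind=data["kind"], observed_mz=data["observed_mz"],
                ppm_error=data["ppm_error"], correlation=data["correlation"],
            ))
        pd.DataFrame(rows, columns=EDGE_CSV_COLUMNS).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format {format!r}")
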