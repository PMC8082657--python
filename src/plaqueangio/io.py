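"""Serialization of domains, networks and run artifacts.

Formats: PNG label masks with JSON sidecars for segmented domains, GraphML
and JSON for vessel networks (node grid coordinates; per-segment length,
radius and flows when available), CSV for per-stage metric tables and field
matrices, and a compressed ``.npz`` archive per run for the full grids.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
from PIL import Image

from .angiogenesis import VesselNetwork
from .geometry import PlaqueDomain

_PALETTE = {  # region code -> RGB for the label PNG
    0: (30, 30, 30), 1: (200, 30, 30), 2: (240, 220, 90),
    3: (90, 160, 240), 4: (120, 220, 120), 5: (180, 120, 200),
}


def save_domain(domain: PlaqueDomain, out_dir) -> None:
    """Write the region-label mask as PNG plus a JSON geometry sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lab = domain.region_label
    img = Image.fromarray(lab.astype(np.uint8), mode="P")
    palette = []
    for code in range(6):
        palette.extend(_PALETTE[code])
    img.putpalette(palette)
    img.save(out / "region_labels.png")
    sidecar = {
        "nx": domain.nx,
        "ny": domain.ny,
        "grid_spacing_um": domain.h_cm * 1.0e4,
        "lumen_center": domain.lumen_center.tolist(),
        "shoulder_centers": domain.shoulder_centers.tolist(),
        "sprout_seeds": domain.sprout_seeds.tolist(),
        "region_codes": {
            "OUTSIDE": 0, "LUMEN": 1, "NC": 2, "SA": 3, "FC": 4, "MEDIA": 5
        },
    }
    (out / "domain.json").write_text(json.dumps(sidecar, indent=2))


def network_to_graph(network: VesselNetwork, hemo=None) -> nx.Graph:
    """Vessel network as a graph; hemodynamic results attached if given."""
    G = nx.Graph()
    for i in range(network.n_segments):
        a, b = network.seg_a[i], network.seg_b[i]
        attrs = {"dl_cm": network.seg_len[i], "R_cm": network.seg_R[i]}
        if hemo is not None:
            attrs.update(
                Q_V=float(hemo.Q_V[i]), Q_t=float(hemo.Q_t[i]),
                U_V=float(hemo.U_V[i]),
            )
        G.add_edge(a, b, **attrs)
    if hemo is not None:
        for i, (x, y) in enumerate(hemo.node_xy):
            if (x, y) in G:
                G.nodes[(x, y)]["P_V"] = float(hemo.P_V_nodes[i])
    for node in G.nodes:
        G.nodes[node]["x"], G.nodes[node]["y"] = int(node[0]), int(node[1])
    return G


def save_network(network: VesselNetwork, out_dir, hemo=None, stem="network") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    G = network_to_graph(network, hemo)
    H = nx.relabel_nodes(G, {n: f"{n[0]},{n[1]}" for n in G.nodes})
    nx.write_graphml(H, out / f"{stem}.graphml")
    payload = {
        "nodes": [
            {"id": f"{x},{y}", "x": int(x), "y": int(y),
             **{k: v for k, v in G.nodes[(x, y)].items() if k not in ("x", "y")}}
            for (x, y) in G.nodes
        ],
        "edges": [
            {"source": f"{u[0]},{u[1]}", "target": f"{v[0]},{v[1]}", **d}
            for u, v, d in G.edges(data=True)
        ],
        "roots": network.roots.tolist() if network.roots is not None else [],
    }
    (out / f"{stem}.json").write_text(json.dumps(payload, indent=2))


def save_field_csv(field: np.ndarray, path) -> None:
    np.savetxt(path, field, delimiter=",", fmt="%.8g")


def save_run(result, out_dir) -> None:
    """Serialize a pipeline run: config, summary, tables, fields, networks."""
    from .pipeline import summary_to_json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    summary_to_json(result.summary, out / "summary.json")
    result.stage_records.to_csv(out / "stages.csv", index=False)
    save_domain(result.domain, out)

    final = result.history.snapshots[-1]
    t_end = result.history.termination_stage
    hemo = result.hemo_stages.get(t_end)
    save_network(final.network, out, hemo=hemo, stem=f"network_T{t_end:02d}")

    grids = {
        "c": final.chem.c, "f": final.chem.f, "m": final.chem.m,
        "A": final.network.A.astype(np.uint8),
        "S_IPH": result.iph.S,
    }
    if result.iph.mask is not None:
        grids["iph_mask"] = result.iph.mask.astype(np.uint8)
        mask_img = Image.fromarray((result.iph.mask * 255).astype(np.uint8))
        mask_img.save(out / "iph_mask.png")
    if hemo is not None:
        grids["P_i"] = hemo.P_i
        grids["U_i"] = hemo.U_i
        save_field_csv(hemo.P_i, out / f"P_i_T{t_end:02d}.csv")
    save_field_csv(result.iph.S, out / "S_IPH.csv")
    np.savez_compressed(out / "fields.npz", **grids)
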