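"""Readers and writers for the pipeline's plain-text formats.

Counts are TSV with taxa as rows and a header row of sample IDs; metadata is
TSV (sample_id, treatment, replicate); N2O rates TSV (sample_id, rate);
trees newick; networks GraphML plus an edge-list TSV; ground truth and run
reports JSON. An optional BIOM 2.1 reader is available when the ``biom``
package is importable.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CountTable, N2OMeasurements


def write_counts(table: CountTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "taxon"
    df.to_csv(path, sep="\t")


def write_metadata(table: CountTable, path) -> None:
    md = table.metadata.copy()
    md.index.name = "sample_id"
    md.to_csv(path, sep="\t")


def write_n2o(n2o: N2OMeasurements, path) -> None:
    df = n2o.rates.rename("rate").to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_counts(counts_path, metadata_path, kingdom: str | None = None) -> CountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = [s for s in counts.columns if s not in metadata.index]
    if missing:
        raise FileNotFoundError(
            f"metadata {metadata_path} lacks samples: {missing}"
        )
    k = pd.Series(kingdom, index=counts.index) if kingdom else None
    return CountTable(counts, metadata, k)


def read_n2o(path) -> N2OMeasurements:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return N2OMeasurements(df["rate"])


def read_biom(path, metadata_path, kingdom: str | None = None) -> CountTable:
    """Optional BIOM 2.1 reader (requires the ``biom`` package)."""
    try:
        import biom
    except ImportError as exc:  # pragma: no cover
        raise ImportError("BIOM input requires the 'biom' package") from exc
    bt = biom.load_table(str(path))
    counts = bt.to_dataframe(dense=True)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    k = pd.Series(kingdom, index=counts.index) if kingdom else None
    return CountTable(counts, metadata, k)


def write_network(net: nx.Graph, graphml_path, edgelist_path) -> None:
    g = net.copy()
    # GraphML cannot carry None graph attributes
    g.graph = {k: v for k, v in net.graph.items() if v is not None}
    nx.write_graphml(g, graphml_path)
    rows = [
        {"source": a, "target": b, "rho": d.get("weight"), "sign": d.get("sign")}
        for a, b, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "sign"]).to_csv(
        edgelist_path, sep="\t", index=False
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isnan(f):
            return None
        if math.isinf(f):
            return "inf" if f > 0 else "-inf"
        return f
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj: dict, path) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(obj), sort_keys=True, indent=2) + "\n"
    )
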