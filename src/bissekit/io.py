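"""File formats: Newick trees, tip-state tables, and results files.

Trees are plain Newick (unquoted labels, decimal branch lengths, one tree
per line for batches); tip states live in a sidecar two-column TSV
(tip_id, state). Results are JSON (single objects) or CSV (grids), each
with a small metadata header carrying the package version, seed and a
config hash so outputs are traceable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import dendropy
import numpy as np

from . import __version__
from .trees import PhyloTree, TreeValidationError


class FormatError(ValueError):
    """Malformed input file."""


def read_newick(path) -> PhyloTree:
    """Parse a rooted bifurcating Newick tree with branch lengths.

    Tip states are initialised to 0; attach real states with
    :func:`read_states` /  ``BisseModel.from_files``.
    """
    text = Path(path).read_text().strip()
    return parse_newick(text)


def parse_newick(text: str) -> PhyloTree:
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as err:  # dendropy raises several parse error types
        raise FormatError(f"malformed Newick: {err}") from err

    leaves = [lf for lf in dtree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(lab is None for lab in labels):
        raise FormatError("every tip needs a label")
    if len(set(labels)) != len(labels):
        dup = [l for l in labels if labels.count(l) > 1][0]
        raise FormatError(f"duplicate tip label: {dup!r}")

    n = len(leaves)
    tip_index = {id(lf): i for i, lf in enumerate(leaves)}
    children_rows: list[list[int]] = []
    lengths = np.zeros(2 * n - 1)

    root = dtree.seed_node
    # tolerate a knuckle above the root produced by some writers
    while len(root.child_nodes()) == 1:
        root = root.child_nodes()[0]

    def set_len(node, i):
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else "an internal node"
            raise FormatError(f"missing branch length above {name}")
        lengths[i] = float(node.edge.length)

    def build(node) -> int:
        kids = node.child_nodes()
        if not kids:
            i = tip_index[id(node)]
            set_len(node, i)
            return i
        if len(kids) != 2:
            raise FormatError(
                f"polytomy (node with {len(kids)} children) is not supported")
        left = build(kids[0])
        right = build(kids[1])
        children_rows.append([left, right])
        i = n + len(children_rows) - 1
        if node is not root:
            set_len(node, i)
        return i

    build(root)
    try:
        return PhyloTree(n_tips=n, children=np.asarray(children_rows),
                         lengths=lengths, tip_states=np.zeros(n, dtype=int),
                         tip_labels=[str(l) for l in labels])
    except TreeValidationError as err:
        raise FormatError(str(err)) from err


def read_states(path) -> dict[str, int]:
    """Two-column TSV (tip_id, state in {0,1}); '#' lines are comments."""
    states: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise FormatError(f"line {ln}: expected 'tip_id<TAB>state'")
        tip, state = parts
        if state not in ("0", "1"):
            raise FormatError(f"line {ln}: state must be 0 or 1, got {state!r}")
        if tip in states:
            raise FormatError(f"line {ln}: duplicate tip {tip!r}")
        states[tip] = int(state)
    return states


def attach_states(tree: PhyloTree, states: Mapping[str, int]) -> PhyloTree:
    missing = [lab for lab in tree.tip_labels if lab not in states]
    if missing:
        raise FormatError(f"missing tip state: {missing[0]}")
    extra = sorted(set(states) - set(tree.tip_labels))
    if extra:
        raise FormatError(f"state table has unknown tip: {extra[0]}")
    tree.tip_states = np.array([states[lab] for lab in tree.tip_labels],
                               dtype=np.int64)
    tree.validate()
    return tree


def write_tree(tree: PhyloTree, tree_path, states_path=None) -> None:
    Path(tree_path).write_text(tree.to_newick() + "\n")
    if states_path is not None:
        write_states(tree, states_path)


def write_states(tree: PhyloTree, path) -> None:
    lines = [f"{lab}\t{int(s)}"
             for lab, s in zip(tree.tip_labels, tree.tip_states)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------


def _round12(obj: Any) -> Any:
    """Normalise floats to 12 significant digits for stable output."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round12(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return _round12(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def config_hash(config: Mapping[str, Any] | None) -> str:
    payload = json.dumps(_round12(dict(config or {})), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _metadata(seed, config) -> dict:
    return {
        "package": f"bissekit {__version__}",
        "seed": seed,
        "config_hash": config_hash(config),
    }


def write_results(objects: Any, path, format: str = "json",
                  seed: int | None = None,
                  config: Mapping[str, Any] | None = None) -> None:
    """Write results with a metadata header.

    JSON: a single object ``{"metadata": ..., "results": ...}``.
    CSV: '#'-prefixed metadata lines followed by the table (accepts a
    pandas DataFrame or a list of records).
    """
    path = Path(path)
    meta = _metadata(seed, config)
    if format == "json":
        doc = {"metadata": meta, "results": _round12(_plain(objects))}
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    elif format == "csv":
        import pandas as pd

        df = objects if isinstance(objects, pd.DataFrame) else pd.DataFrame(objects)
        header = "".join(f"# {k}: {v}\n" for k, v in meta.items())
        body = df.to_csv(index=False, float_format="%.12g")
        path.write_text(header + body)
    else:
        raise ValueError(f"unknown format {format!r}")


def _plain(obj: Any) -> Any:
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
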