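"""Network serialization (JSON) and pipeline plumbing.

One JSON dialect for networks, versioned with a ``format_version`` field:

    {
      "format_version": 1,
      "variables": [{"name": ..., "states": [...]}, ...],
      "arcs": [["parent", "child"], ...],
      "cpts": [
        {"child": ..., "parents": [...],
         "rows": [{"given": ["state", ...], "p": [...]}, ...]},
        ...
      ]
    }

Rows are written in lexicographic parent-configuration order so a
save -> load -> save round trip is byte-identical. Loading validates the
network and refuses invalid ones; rows whose sum is off by at most 1e-6
are renormalized with a warning, anything worse is a validation failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from .bn_core import (
    ROW_RENORM_TOL,
    ROW_SUM_TOL,
    BayesianNetwork,
    CategoricalVariable,
    ConditionalProbabilityTable,
    DagStructure,
    NetworkValidationError,
    parent_configurations,
)

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

__all__ = ["load_network", "save_network", "network_to_dict", "network_from_dict"]


def network_to_dict(net: BayesianNetwork) -> dict:
    structure = net.structure
    cpts = []
    for name in structure.variable_names:
        cpt = net.cpt(name)
        rows = [
            {"given": list(config), "p": list(cpt.row(config))}
            for config in parent_configurations(structure, cpt.parents)
        ]
        cpts.append(
            {"child": name, "parents": list(cpt.parents), "rows": rows}
        )
    return {
        "format_version": FORMAT_VERSION,
        "variables": [
            {"name": v.name, "states": list(v.states)}
            for v in structure.variables
        ],
        "arcs": [list(a) for a in structure.arcs],
        "cpts": cpts,
    }


def network_from_dict(doc: dict) -> BayesianNetwork:
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"unsupported network format_version {version!r} "
            f"(this build reads version {FORMAT_VERSION})"
        )
    variables = tuple(
        CategoricalVariable(v["name"], tuple(v["states"]))
        for v in doc["variables"]
    )
    arcs = tuple((a[0], a[1]) for a in doc["arcs"])
    structure = DagStructure(variables, arcs)
    cpts = {}
    for entry in doc["cpts"]:
        rows = {}
        for row in entry["rows"]:
            p = [float(x) for x in row["p"]]
            total = sum(p)
            if abs(total - 1.0) > ROW_SUM_TOL and abs(total - 1.0) <= ROW_RENORM_TOL:
                logger.warning(
                    "renormalizing CPT row %r for %r (sum %.9f)",
                    row["given"],
                    entry["child"],
                    total,
                )
                p = [x / total for x in p]
            rows[tuple(row["given"])] = tuple(p)
        cpts[entry["child"]] = ConditionalProbabilityTable(
            entry["child"], tuple(entry["parents"]), rows
        )
    return BayesianNetwork(structure, cpts)


def load_network(path: str | Path) -> BayesianNetwork:
    """Load and validate a network; invalid networks are refused with an
    itemized report."""
    path = Path(path)
    try:
        with path.open() as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"malformed JSON in {path} at line {exc.lineno}, column "
            f"{exc.colno}: {exc.msg}"
        ) from exc
    net = network_from_dict(doc)
    try:
        net.require_valid()
    except NetworkValidationError as exc:
        raise NetworkValidationError(f"{path}: {exc}") from None
    return net


def save_network(net: BayesianNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        json.dump(network_to_dict(net), fh, indent=2)
        fh.write("\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
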