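"""Readers and writers for the package's three text formats.

* Interaction tables: SIF-like TSV with header ``source effect target
  [and_group]``; effect keywords ``activate``/``inhibit`` (case-insensitive)
  or ``+``/``-``; ``#`` comments; UTF-8.  Node identifiers are verbatim
  case-sensitive strings (gene symbols like ``NKX3.1`` or ``AKT/mTOR``
  pass through untouched apart from surrounding-whitespace strip).
* Rule files: BoolNet-style ``target, expression`` lines over ``& | !``,
  parentheses and constants 0/1.  Nodes referenced but never defined get
  the identity rule (free input).
* Annotation CSV: ``gene,level`` with level in {0, 1, unknown}.

Writers emit canonically ordered output (nodes sorted, expressions in
truth-table-canonical form) so that files are diffable and two models
with equal truth tables serialize identically.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

from .expr import ParseError, Var, canonical_dnf, parse_expression
from .model import BooleanModel
from .network import ExpressionAnnotation, NetworkValidationError, SignedEdge, SignedNetwork

__all__ = [
    "read_network", "write_network", "read_rules", "write_rules",
    "read_annotation", "write_annotation", "NetworkParseError",
]

logger = logging.getLogger(__name__)

_EFFECTS = {"activate": 1, "+": 1, "inhibit": -1, "-": -1}


class NetworkParseError(ValueError):
    """Malformed input file; message carries the line number."""


def _data_lines(path: Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].rstrip("\n")
            if line.strip():
                yield lineno, line


def read_network(path: str | Path) -> SignedNetwork:
    """Read a signed interaction TSV.

    The header row ``source<TAB>effect<TAB>target[<TAB>and_group]`` is
    required.  A special row ``node<TAB>.<TAB>.`` declares an isolated
    node (needed for degenerate edge-free networks).  Node order is
    first-appearance order, deterministic for a fixed file.
    """
    path = Path(path)
    nodes: list[str] = []
    node_seen: set[str] = set()
    edges: list[SignedEdge] = []

    def add_node(name: str):
        if name not in node_seen:
            node_seen.add(name)
            nodes.append(name)

    lines = _data_lines(path)
    try:
        _, header = next(lines)
    except StopIteration:
        raise NetworkParseError(f"{path}: empty file") from None
    head = [c.strip().lower() for c in header.split("\t")]
    if head[:3] != ["source", "effect", "target"]:
        raise NetworkParseError(
            f"{path}:1: expected header 'source<TAB>effect<TAB>target', got {header!r}")

    for lineno, line in lines:
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) == 3 and cells[1] == "." and cells[2] == ".":
            add_node(cells[0])
            continue
        if len(cells) not in (3, 4) or not all(cells[:3]):
            raise NetworkParseError(
                f"{path}:{lineno}: expected 3 or 4 tab-separated fields, got {line!r}")
        source, effect, target = cells[:3]
        and_group = cells[3] if len(cells) == 4 and cells[3] else None
        try:
            sign = _EFFECTS[effect.lower()]
        except KeyError:
            raise NetworkParseError(
                f"{path}:{lineno}: unknown effect {effect!r} "
                f"(expected activate/inhibit/+/-)") from None
        add_node(source)
        add_node(target)
        edges.append(SignedEdge(source, target, sign, and_group))

    try:
        net = SignedNetwork(nodes, edges)
    except NetworkValidationError as exc:
        raise NetworkParseError(f"{path}: {exc}") from exc
    logger.info("read network %s: %d nodes, %d edges", path, net.n_nodes, net.n_edges)
    return net


def write_network(net: SignedNetwork, path: str | Path) -> None:
    """Write a network TSV with nodes and edges in sorted order."""
    path = Path(path)
    targets = {e.target for e in net.edges}
    sources = {e.source for e in net.edges}
    isolated = [n for n in sorted(net.nodes) if n not in targets and n not in sources]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\teffect\ttarget\tand_group\n")
        for n in isolated:
            fh.write(f"{n}\t.\t.\n")
        for e in sorted(net.edges,
                        key=lambda e: (e.source, e.target, -e.sign, e.and_group or "")):
            effect = "activate" if e.sign == 1 else "inhibit"
            group = e.and_group or ""
            row = f"{e.source}\t{effect}\t{e.target}"
            fh.write(row + (f"\t{group}\n" if group else "\n"))


def read_rules(path: str | Path, strict: bool = False) -> BooleanModel:
    """Read a BoolNet-style rule file: one ``target, expression`` per line.

    An optional ``targets, factors`` header is tolerated.  Symbols that
    appear in expressions but have no rule line of their own become free
    inputs (identity rule) unless ``strict`` is set, in which case they
    raise.
    """
    path = Path(path)
    functions = {}
    order: list[str] = []
    for lineno, line in _data_lines(path):
        left, sep, right = line.partition(",")
        target = left.strip()
        if not sep or not target or not right.strip():
            raise NetworkParseError(
                f"{path}:{lineno}: expected 'target, expression', got {line!r}")
        if (target.lower(), right.strip().lower()) == ("targets", "factors"):
            continue
        if target in functions:
            raise NetworkParseError(f"{path}:{lineno}: duplicate rule for {target!r}")
        try:
            expr = parse_expression(right)
        except ParseError as exc:
            raise NetworkParseError(f"{path}:{lineno}: {exc}") from exc
        functions[target] = expr
        order.append(target)

    referenced: set[str] = set()
    for expr in functions.values():
        referenced |= expr.support()
    undefined = sorted(referenced - set(order))
    if undefined and strict:
        raise NetworkParseError(
            f"{path}: undeclared symbols referenced: {undefined}")
    for name in undefined:
        functions[name] = Var(name)  # free input
        order.append(name)
    if not order:
        raise NetworkParseError(f"{path}: no rules found")
    logger.info("read rules %s: %d nodes (%d free inputs added)",
                path, len(order), len(undefined))
    return BooleanModel(order, functions)


def write_rules(model: BooleanModel, path: str | Path) -> None:
    """Write rules with sorted nodes and truth-table-canonical expressions,
    so models equal as truth tables produce byte-identical files."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("targets, factors\n")
        for node in sorted(model.nodes):
            fh.write(f"{node}, {canonical_dnf(model.functions[node])!r}\n")


def read_annotation(path: str | Path) -> ExpressionAnnotation:
    """Read a ``gene,level`` CSV; level is 0, 1 or ``unknown``."""
    path = Path(path)
    annot = ExpressionAnnotation()
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].startswith("#"):
                continue
            if [c.strip().lower() for c in row[:2]] == ["gene", "level"]:
                continue
            if len(row) < 2:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 'gene,level', got {row!r}")
            gene, level = row[0].strip(), row[1].strip().lower()
            if level in ("0", "1"):
                annot[gene] = int(level)
            elif level in ("unknown", "na", ""):
                annot[gene] = None
            else:
                raise NetworkParseError(
                    f"{path}:{lineno}: level must be 0, 1 or unknown, got {level!r}")
    return annot


def write_annotation(annot: ExpressionAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene,level\n")
        for gene in sorted(annot):
            level = annot[gene]
            fh.write(f"{gene},{'unknown' if level is None else level}\n")
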