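"""Rooted label hierarchy of cancer categories.

The prediction target is a node in a rooted tree of OncoTree-style cancer
categories.  Depth-1 nodes are "major" categories (organ/lineage groups);
deeper nodes are subcategories.  One multi-class network is trained per
*branch* — an internal node with at least two children — and per-node scores
are obtained by multiplying branch outputs down the tree, so the hierarchy
object is the single source of truth for branch enumeration, subtree
membership, and root-excluded label paths used by metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

#: Sentinel returned by :func:`map_diagnosis` for cancer-of-unknown-primary
#: submissions.  Cohort tables use the same string in ``submitted_label``.
CUP_MARKER = "CUP"

#: Sentinel for a submitted diagnosis string that could not be mapped.
UNMAPPED = "<unmapped>"


class HierarchyError(ValueError):
    """Base class for hierarchy validation failures."""


class DuplicateCodeError(HierarchyError):
    pass


class OrphanParentError(HierarchyError):
    pass


class CycleError(HierarchyError):
    pass


class RootError(HierarchyError):
    """Zero roots, or more than one root."""


class UnknownCodeError(HierarchyError, KeyError):
    pass


@dataclass(frozen=True)
class LabelNode:
    code: str
    display_name: str
    parent_code: str | None  # None marks the root
    depth: int
    reportable: bool


@dataclass(frozen=True)
class BranchSpec:
    """An internal node with >= 2 children; one classifier is trained per branch.

    ``child_codes`` are exactly the children of ``parent_code`` in
    lexicographic order, so branch output vectors have a deterministic layout.
    """

    parent_code: str
    child_codes: tuple[str, ...]


class LabelHierarchy:
    """Validated rooted tree of :class:`LabelNode`.

    Construct via :meth:`from_records`, :meth:`load` (JSON document) or
    :meth:`default` (the shipped 90-label configuration).
    """

    def __init__(self, nodes: Mapping[str, LabelNode], root_code: str):
        self.nodes: dict[str, LabelNode] = dict(nodes)
        self.root_code = root_code
        self._children: dict[str, tuple[str, ...]] = {c: () for c in self.nodes}
        kids: dict[str, list[str]] = {c: [] for c in self.nodes}
        for node in self.nodes.values():
            if node.parent_code is not None:
                kids[node.parent_code].append(node.code)
        for code, lst in kids.items():
            self._children[code] = tuple(sorted(lst))

    # ------------------------------------------------------------------ build

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "LabelHierarchy":
        """Build and validate from ``{code, name, parent, reportable}`` records.

        ``parent`` is ``None`` for the root.  Raises a specific
        :class:`HierarchyError` subclass for duplicate codes, orphan parents,
        cycles, and zero/multiple roots.
        """
        raw: dict[str, dict] = {}
        for rec in records:
            code = str(rec["code"])
            if code in raw:
                raise DuplicateCodeError(f"duplicate node code {code!r}")
            raw[code] = {
                "name": str(rec.get("name", code)),
                "parent": rec.get("parent"),
                "reportable": bool(rec.get("reportable", True)),
            }
        roots = [c for c, r in raw.items() if r["parent"] is None]
        if len(roots) == 0:
            raise RootError("no root node (exactly one node must have parent=null)")
        if len(roots) > 1:
            raise RootError(f"multiple roots: {sorted(roots)}")
        root = roots[0]
        for code, rec in raw.items():
            p = rec["parent"]
            if p is not None and p not in raw:
                raise OrphanParentError(f"node {code!r} references missing parent {p!r}")

        # Depth assignment doubles as cycle/connectivity detection: walk each
        # node's parent chain; a chain that revisits a node or exceeds the node
        # count is cyclic (and therefore unreachable from the root).
        depth: dict[str, int] = {root: 0}

        def resolve(code: str) -> int:
            if code in depth:
                return depth[code]
            chain = []
            cur = code
            seen = set()
            while cur not in depth:
                if cur in seen:
                    raise CycleError(f"cycle detected through node {cur!r}")
                seen.add(cur)
                chain.append(cur)
                cur = raw[cur]["parent"]
            d = depth[cur]
            for c in reversed(chain):
                d += 1
                depth[c] = d
            return depth[code]

        for code in raw:
            resolve(code)

        nodes = {
            code: LabelNode(
                code=code,
                display_name=rec["name"],
                parent_code=rec["parent"],
                depth=depth[code],
                reportable=rec["reportable"] and code != root,
            )
            for code, rec in raw.items()
        }
        return cls(nodes, root)

    @classmethod
    def load(cls, source) -> "LabelHierarchy":
        """Load from a JSON document: a path, file object, or parsed list."""
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                doc = json.load(fh)
        elif hasattr(source, "read"):
            doc = json.load(source)
        else:
            doc = source
        if isinstance(doc, Mapping) and "nodes" in doc:
            doc = doc["nodes"]
        return cls.from_records(doc)

    @classmethod
    def default(cls) -> "LabelHierarchy":
        """The shipped configuration: 26 major categories, 64 subcategories,
        90 reportable labels, 20 branches.  Category membership is
        illustrative; every algorithm in the package is topology-generic."""
        ref = resources.files("oncotoc.data").joinpath("default_hierarchy.json")
        return cls.load(json.loads(ref.read_text()))

    def to_records(self) -> list[dict]:
        out = []
        for code in sorted(self.nodes):
            n = self.nodes[code]
            out.append(
                {
                    "code": n.code,
                    "name": n.display_name,
                    "parent": n.parent_code,
                    "reportable": n.reportable,
                }
            )
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_records(), fh, indent=1)

    # ----------------------------------------------------------------- access

    def __contains__(self, code: str) -> bool:
        return code in self.nodes

    def node(self, code: str) -> LabelNode:
        try:
            return self.nodes[code]
        except KeyError:
            raise UnknownCodeError(f"unknown hierarchy code {code!r}") from None

    def children(self, code: str) -> tuple[str, ...]:
        self.node(code)
        return self._children[code]

    @property
    def majors(self) -> tuple[str, ...]:
        return self.children(self.root_code)

    @property
    def terminals(self) -> tuple[str, ...]:
        return tuple(c for c in sorted(self.nodes) if not self._children[c])

    @property
    def reportable_codes(self) -> tuple[str, ...]:
        return tuple(c for c in sorted(self.nodes) if self.nodes[c].reportable)

    def path_to_root(self, code: str) -> list[str]:
        """Ordered codes from the depth-1 ancestor down to ``code``.

        The root is excluded (it carries no diagnostic information and is not
        counted by the hierarchical metrics), so the root itself maps to an
        empty path and the path length always equals the node depth.
        """
        node = self.node(code)
        path: list[str] = []
        while node.parent_code is not None:
            path.append(node.code)
            node = self.nodes[node.parent_code]
        path.reverse()
        return path

    def subtree(self, code: str) -> set[str]:
        """All codes in the subtree rooted at ``code``, inclusive."""
        self.node(code)
        out = {code}
        stack = [code]
        while stack:
            for c in self._children[stack.pop()]:
                out.add(c)
                stack.append(c)
        return out

    def descendants(self, code: str) -> set[str]:
        return self.subtree(code) - {code}

    def branches(self) -> list[BranchSpec]:
        """One :class:`BranchSpec` per internal node with >= 2 children,
        ordered root-first (by depth) then lexicographically.  Single-child
        internal nodes yield no branch: a softmax over one label is constant,
        so the child simply inherits the parent score during propagation."""
        specs = [
            BranchSpec(code, self._children[code])
            for code in self.nodes
            if len(self._children[code]) >= 2
        ]
        specs.sort(key=lambda b: (self.nodes[b.parent_code].depth, b.parent_code))
        return specs

    def single_child_nodes(self) -> list[str]:
        return sorted(c for c in self.nodes if len(self._children[c]) == 1)


def map_diagnosis(
    h: LabelHierarchy,
    submitted: str,
    mapping: Mapping[str, str] | None = None,
) -> str:
    """Map a submitted diagnosis string to a hierarchy code.

    Returns the mapped code, :data:`CUP_MARKER` for unknown-primary
    submissions, or :data:`UNMAPPED`.  Never raises on unmappable input: a
    case must not be silently dropped, only explicitly marked.
    """
    s = submitted.strip()
    if s.upper() == CUP_MARKER or s.lower() in {
        "cancer of unknown primary",
        "unknown primary",
        "occult primary",
    }:
        return CUP_MARKER
    if mapping and s in mapping:
        code = mapping[s]
        return code if code in h else UNMAPPED
    if s in h and s != h.root_code:
        return s
    return UNMAPPED


def load_diagnosis_mapping(path) -> dict[str, str]:
    """Read a two-column TSV (submitted_string <tab> code) into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "submitted_string":  # optional header
                continue
            if len(parts) != 2:
                raise ValueError(f"mapping rows need 2 columns, got {line!r}")
            out[parts[0]] = parts[1]
    return out
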