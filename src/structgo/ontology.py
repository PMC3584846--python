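"""Gene Ontology DAG handling.

Each GO namespace (molecular function, biological process, cellular
component) is a rooted directed acyclic graph over terms.  Annotation sets
must be closed upward: whenever a term annotates a protein, so do all of its
ancestors.  This module parses OBO files, answers ancestor/depth queries and
closes term sets under the hierarchy.

Conventions adopted here and relied on elsewhere in the package:

* only ``is_a`` edges are parent edges by default (``part_of`` and other
  relations can be requested explicitly);
* the namespace root is *excluded* from closed labels and indicator
  vectors — it belongs to every protein and would only add a constant to
  every output-kernel value;
* term depth is the length of the *longest* directed path to the root;
* each namespace is handled independently of the others.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Iterable, Mapping, Sequence

import obonet
import pandas as pd

from .errors import OboParseError, ValidationError

logger = logging.getLogger(__name__)

#: OBO namespace names mapped to the short codes used throughout the package.
NAMESPACE_CODES = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}
NAMESPACE_NAMES = {code: name for name, code in NAMESPACE_CODES.items()}

DEFAULT_RELATIONS = frozenset({"is_a"})


class GeneOntology:
    """A validated, namespace-separated GO DAG.

    Parameters
    ----------
    namespace_of:
        Mapping of term id to namespace code (``MF``/``BP``/``CC`` for real
        GO; arbitrary strings are accepted for synthetic ontologies).
    parents_of:
        Mapping of term id to the set of its direct parents.  Terms without
        parents are namespace roots; exactly one root per namespace is
        required.
    """

    def __init__(
        self,
        namespace_of: Mapping[str, str],
        parents_of: Mapping[str, Iterable[str]],
    ) -> None:
        self.namespace_of: dict[str, str] = dict(namespace_of)
        self.parents_of: dict[str, frozenset[str]] = {
            t: frozenset(parents_of.get(t, ())) for t in self.namespace_of
        }
        self._validate_edges()
        self.root_of: dict[str, str] = self._find_roots()
        self._depth: dict[str, int] = self._compute_depths()
        self._vocab: dict[str, tuple[str, ...]] = {}
        self._ancestors_cache: dict[str, frozenset[str]] = {}

    # -- construction helpers ------------------------------------------------

    def _validate_edges(self) -> None:
        for term, parents in self.parents_of.items():
            for p in parents:
                if p not in self.namespace_of:
                    raise ValidationError(
                        f"term {term!r} has unknown parent {p!r}"
                    )
                if self.namespace_of[p] != self.namespace_of[term]:
                    raise ValidationError(
                        f"edge {term!r} -> {p!r} crosses namespaces "
                        f"({self.namespace_of[term]} vs {self.namespace_of[p]})"
                    )

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, list[str]] = {}
        for term, parents in self.parents_of.items():
            if not parents:
                roots.setdefault(self.namespace_of[term], []).append(term)
        out: dict[str, str] = {}
        for ns in sorted({self.namespace_of[t] for t in self.namespace_of}):
            found = sorted(roots.get(ns, []))
            if len(found) != 1:
                raise ValidationError(
                    f"namespace {ns!r} must have exactly one parentless root "
                    f"term, found {found!r}"
                )
            out[ns] = found[0]
        return out

    def _compute_depths(self) -> dict[str, int]:
        """Longest-path depth via Kahn topological order; detects cycles."""
        children: dict[str, list[str]] = {t: [] for t in self.namespace_of}
        indeg = {t: len(self.parents_of[t]) for t in self.namespace_of}
        for term, parents in self.parents_of.items():
            for p in parents:
                children[p].append(term)
        queue = deque(sorted(t for t, d in indeg.items() if d == 0))
        depth: dict[str, int] = {}
        while queue:
            t = queue.popleft()
            parents = self.parents_of[t]
            depth[t] = 1 + max(depth[p] for p in parents) if parents else 0
            for c in children[t]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(depth) != len(self.namespace_of):
            stuck = sorted(set(self.namespace_of) - set(depth))[:5]
            raise ValidationError(
                f"parent graph contains a cycle involving terms near {stuck!r}"
            )
        return depth

    # -- queries -------------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.namespace_of)

    def __contains__(self, term: str) -> bool:
        return term in self.namespace_of

    def __len__(self) -> int:
        return len(self.namespace_of)

    def namespaces(self) -> tuple[str, ...]:
        return tuple(sorted(self.root_of))

    def vocabulary(self, namespace: str) -> tuple[str, ...]:
        """Sorted non-root terms of a namespace (indicator-vector order)."""
        if namespace not in self.root_of:
            raise KeyError(f"unknown namespace {namespace!r}")
        if namespace not in self._vocab:
            root = self.root_of[namespace]
            self._vocab[namespace] = tuple(
                sorted(
                    t
                    for t, ns in self.namespace_of.items()
                    if ns == namespace and t != root
                )
            )
        return self._vocab[namespace]

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable via parent edges, excluding ``term`` itself."""
        if term not in self.namespace_of:
            raise KeyError(f"unknown term {term!r}")
        cached = self._ancestors_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents_of[term])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents_of[p])
        result = frozenset(out)
        self._ancestors_cache[term] = result
        return result

    def term_depth(self, term: str) -> int:
        """Number of edges on the longest path from ``term`` to its root."""
        if term not in self._depth:
            raise KeyError(f"unknown term {term!r}")
        return self._depth[term]

    def close_label(self, terms: Iterable[str]) -> frozenset[str]:
        """Union of ``terms`` with all ancestors; the namespace root removed.

        Idempotent.  Raises :class:`ValidationError` if the terms span more
        than one namespace.
        """
        terms = set(terms)
        if not terms:
            return frozenset()
        spaces = set()
        for t in terms:
            if t not in self.namespace_of:
                raise KeyError(f"unknown term {t!r}")
            spaces.add(self.namespace_of[t])
        if len(spaces) > 1:
            raise ValidationError(
                f"terms span multiple namespaces: {sorted(spaces)!r}"
            )
        root = self.root_of[spaces.pop()]
        closed = set(terms)
        for t in terms:
            closed |= self.ancestors(t)
        closed.discard(root)
        return frozenset(closed)

    def is_closed(self, terms: Iterable[str]) -> bool:
        """True if the set is hierarchically consistent (root-free closure)."""
        s = frozenset(terms)
        return not s or self.close_label(s) == s

    def to_table(self) -> pd.DataFrame:
        """Term table with namespace and longest-path depth."""
        rows = [
            (t, self.namespace_of[t], self._depth[t])
            for t in sorted(self.namespace_of)
        ]
        return pd.DataFrame(rows, columns=["term", "namespace", "depth"])


def load_obo(
    path,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> GeneOntology:
    """Parse an OBO 1.2/1.4 file into a :class:`GeneOntology`.

    Obsolete terms are dropped.  Only the requested ``relations`` (default:
    ``is_a`` only) become parent edges; other relationship lines are ignored.
    """
    relations = frozenset(relations)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - message pass-through
        raise OboParseError(f"failed to parse OBO file {path}: {exc}") from exc

    default_ns = graph.graph.get("default-namespace")
    if isinstance(default_ns, (list, tuple)):
        default_ns = default_ns[0] if default_ns else None

    namespace_of: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace", default_ns)
        if ns is None:
            raise OboParseError(
                f"term stanza {term!r} has no namespace and the file declares "
                "no default-namespace"
            )
        namespace_of[term] = NAMESPACE_CODES.get(ns, ns)

    parents_of: dict[str, set[str]] = {t: set() for t in namespace_of}
    # obonet edges run child -> parent with the relation as the edge key
    for child, parent, rel in graph.edges(keys=True):
        if rel in relations:
            parents_of[child].add(parent)
    return GeneOntology(namespace_of, parents_of)


def write_terms_tsv(go: GeneOntology, path) -> None:
    go.to_table().to_csv(path, sep="\t", index=False)
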