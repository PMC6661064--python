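"""Deterministic patient linkage: derive a consolidated patient key (ID0).

The claims database carries two hashed person identifiers, ID1 and ID2.
Neither alone tracks an individual reliably — an insurer change rewrites ID1
while ID2 persists (and vice versa) — so claims of one person can arrive under
several identifier pairs.  We consolidate them by transitive closure: build
the bipartite graph whose nodes are identifier values (ID1 values and ID2
values kept in separate namespaces) and whose edges are claims, and give every
claim in a connected component the same patient key.

The key is derived from the lexicographically smallest identifier node in the
component, so keys are stable across runs and invariant to claim order.  The
closure is computed with a union-find (disjoint-set) structure; the linkage
function is a pluggable interface and can be swapped for a stricter matcher.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import ClaimRecord

__all__ = ["LinkageResult", "assign_patient_keys"]


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        parent = self.parent
        if x not in parent:
            parent[x] = x
            return x
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic orientation: smaller string becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


@dataclass
class LinkageResult:
    keys: dict[str, str] = field(default_factory=dict)  # claim_id -> id0
    rejects: list[tuple[str, str]] = field(default_factory=list)  # (claim_id, reason)

    @property
    def n_patients(self) -> int:
        return len(set(self.keys.values()))


def assign_patient_keys(claims: list[ClaimRecord]) -> LinkageResult:
    """Assign one patient key per connected component of the ID1/ID2 graph.

    Two claims get the same key iff their identifier values are connected
    through a chain of claims sharing an ID1 or an ID2.  Claims with an empty
    identifier are rejected row-wise, never merged by the empty string.  The
    returned keys are ``"P:" + smallest node`` of the component, hence
    deterministic and order-independent.
    """
    uf = _UnionFind()
    edges: list[tuple[str, str, str]] = []  # (claim_id, node1, node2)
    result = LinkageResult()
    for claim in claims:
        if not claim.id1 or not claim.id2:
            result.rejects.append((claim.claim_id, "empty identifier"))
            continue
        n1, n2 = f"1:{claim.id1}", f"2:{claim.id2}"
        uf.union(n1, n2)
        edges.append((claim.claim_id, n1, n2))

    # second pass: map each component root to its smallest member
    smallest: dict[str, str] = {}
    for node in list(uf.parent):
        root = uf.find(node)
        if root not in smallest or node < smallest[root]:
            smallest[root] = node
    for claim_id, n1, _ in edges:
        result.keys[claim_id] = "P:" + smallest[uf.find(n1)]
    return result
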