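"""Brute-force reference implementations used for validation.

These recompute disjunct common ancestors by exhaustively enumerating every
directed child->parent path in the DAG, instead of the reachability search
used by the production code.  They are deliberately slow and only suitable
for small ontologies (tens of terms); the test suite checks that the fast
implementation agrees with them exactly.
"""

from __future__ import annotations

from collections.abc import Mapping

from .ontology import Ontology


def enumerate_paths(ont: Ontology, term: str) -> dict[str, list[frozenset[str]]]:
    """All directed paths from ``term`` to each of its ancestors.

    Returns ancestor -> list of path node-sets (each set includes both
    endpoints).  The trivial path [term] is included under ``term`` itself.
    """
    paths: dict[str, list[frozenset[str]]] = {}

    def walk(node: str, visited: tuple[str, ...]) -> None:
        paths.setdefault(node, []).append(frozenset(visited))
        for parent in ont.parents(node):
            walk(parent, visited + (parent,))

    walk(term, (term,))
    return paths


def disjunctive_common_ancestors_bruteforce(
    t1: str,
    t2: str,
    ont: Ontology,
    ic: Mapping[str, float],
) -> set[str]:
    """Disjunct common ancestors via exhaustive path enumeration.

    Applies the same greedy decreasing-IC acceptance rule as the production
    implementation, but decides path-avoidance by scanning every enumerated
    path for one disjoint from the accepted set.
    """
    paths1 = enumerate_paths(ont, t1)
    paths2 = enumerate_paths(ont, t2)
    common = set(paths1) & set(paths2)
    if not common:
        return set()
    order = sorted(common, key=lambda t: (-ic.get(t, float("-inf")), t))
    accepted: list[str] = [order[0]]

    def has_free_path(paths: list[frozenset[str]], blocked: set[str]) -> bool:
        return any(not (p & blocked) for p in paths)

    for cand in order[1:]:
        blocked = set(accepted)
        if has_free_path(paths1[cand], blocked) and has_free_path(
            paths2[cand], blocked
        ):
            accepted.append(cand)
    return set(accepted)


def resnik_grasm_bruteforce(
    t1: str,
    t2: str,
    ont: Ontology,
    ic: Mapping[str, float],
) -> float:
    dca = disjunctive_common_ancestors_bruteforce(t1, t2, ont, ic)
    vals = [ic[t] for t in sorted(dca) if t in ic]
    if not vals:
        return 0.0
    return sum(vals) / len(vals)
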