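"""Brute-force exact solvers, used as ground truth in tests.

Both functions enumerate every matching among the link edges (with simple
branch pruning) and evaluate it directly against the cover definition, so
they are independent of all dynamic-programming machinery.  A size guard
keeps them honest: they are oracles for small instances, not solvers.
"""

from __future__ import annotations

from typing import Iterator, Optional

from .model import Cover, ScaffoldGraph, classify_selection, edge_key

SIZE_GUARD = 25


def iter_link_matchings(sg: ScaffoldGraph) -> Iterator[frozenset]:
    """All subsets of the links that form a matching in G - M."""
    links = sorted(sg.links)
    if len(links) > SIZE_GUARD:
        raise ValueError(f"too many links for brute force ({len(links)} > {SIZE_GUARD})")

    def rec(i: int, used: set[str], chosen: list):
        if i == len(links):
            yield frozenset(chosen)
            return
        u, v = links[i]
        yield from rec(i + 1, used, chosen)
        if u not in used and v not in used:
            used |= {u, v}
            chosen.append((u, v))
            yield from rec(i + 1, used, chosen)
            chosen.pop()
            used -= {u, v}

    yield from rec(0, set(), [])


def brute_force_all(sg: ScaffoldGraph) -> dict[tuple[int, int], tuple[int, Cover]]:
    """Optimum weight and witness per (n_paths, n_cycles) combination."""
    best: dict[tuple[int, int], tuple[int, Cover]] = {}
    for S in iter_link_matchings(sg):
        cover = classify_selection(sg, S)
        key = (cover.n_paths, cover.n_cycles)
        if key not in best or cover.weight > best[key][0]:
            best[key] = (cover.weight, cover)
    return best


def brute_force_sca(
    sg: ScaffoldGraph, sigma_p: int, sigma_c: int
) -> tuple[Optional[int], Optional[Cover]]:
    """Exact optimum for given path/cycle counts; (None, None) if infeasible."""
    res = brute_force_all(sg).get((sigma_p, sigma_c))
    return res if res is not None else (None, None)


def brute_force_rsca(instance) -> tuple[bool, Optional[frozenset]]:
    """Decision for the restricted problem, with a witnessing link set.

    A yes requires sigma_p paths of exactly ell_p edges and sigma_c cycles
    of exactly ell_c edges, all alternating, of kept weight >= k.  Two
    necessary conditions prune the enumeration: the vertex-count identity
    sigma_p*(ell_p+1) + sigma_c*ell_c = |V|, and the fact that every cover
    with those component counts selects exactly |M| - sigma_p links.
    """
    sg = instance.graph
    if instance.sigma_p * (instance.ell_p + 1) + instance.sigma_c * instance.ell_c != sg.n_vertices:
        return False, None
    links = sorted(sg.links)
    if len(links) > SIZE_GUARD:
        raise ValueError(f"too many links for brute force ({len(links)} > {SIZE_GUARD})")
    target = len(sg.matching) - instance.sigma_p
    if target < 0:
        return False, None
    partner = {v: sg.partner(v) for v in sg.vertices}
    weights = {e: sg.weight(*e) for e in links}

    found: list[frozenset] = []

    def shapes_ok(chosen: list) -> bool:
        nbr: dict[str, list[str]] = {}
        for u, v in chosen:
            nbr.setdefault(u, []).append(v)
            nbr.setdefault(v, []).append(u)
        seen: set[str] = set()
        n_paths = n_cycles = 0
        for s in partner:
            if s in seen:
                continue
            # walk the component alternating contig / selected-link steps
            comp = {s}
            frontier = [s]
            edges = 0
            while frontier:
                x = frontier.pop()
                for y in [partner[x]] + nbr.get(x, []):
                    if y not in comp:
                        comp.add(y)
                        frontier.append(y)
            seen |= comp
            deg = {x: 1 + len(nbr.get(x, [])) for x in comp}
            edges = (sum(deg.values())) // 2
            if all(d == 2 for d in deg.values()):
                if edges != instance.ell_c:
                    return False
                n_cycles += 1
            else:
                if edges != instance.ell_p:
                    return False
                n_paths += 1
        return n_paths == instance.sigma_p and n_cycles == instance.sigma_c

    def rec(i: int, used: set[str], chosen: list, weight: int) -> bool:
        if len(chosen) == target:
            if weight >= instance.k and shapes_ok(chosen):
                found.append(frozenset(chosen))
                return True
            return False
        if len(chosen) + (len(links) - i) < target:
            return False
        if i == len(links):
            return False
        u, v = links[i]
        if u not in used and v not in used:
            used |= {u, v}
            chosen.append((u, v))
            if rec(i + 1, used, chosen, weight + weights[(u, v)]):
                return True
            chosen.pop()
            used -= {u, v}
        return rec(i + 1, used, chosen, weight)

    if rec(0, set(), [], 0):
        return True, found[0]
    return False, None
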