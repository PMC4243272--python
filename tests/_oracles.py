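"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the library code paths they are used to check."""

from ligannot.matcher import perceive_bonds


def exhaustive_match(component, cdef):
    """Enumerate every element-compatible assignment of observed heavy atoms
    to dictionary heavy atoms such that each perceived bond maps onto a
    dictionary bond, by plain depth-first search (no isomorphism library).

    Observed atoms are visited in breadth-first order over the perceived
    bond graph, which prunes the search without sacrificing completeness.
    Returns all complete assignments whose unmapped dictionary atoms are
    exclusively leaving atoms."""
    obs = [(i, a) for i, a in enumerate(component.atoms) if not a.is_hydrogen]
    dict_heavy = cdef.heavy_atoms()
    dict_bonds = {frozenset((b.atom_id_1, b.atom_id_2)) for b in cdef.bonds}
    obs_bonds = {frozenset(p) for p in perceive_bonds(component)}

    # BFS ordering over the observed bond graph
    adj = {i: set() for i, _ in obs}
    for pair in obs_bonds:
        i, j = tuple(pair)
        if i in adj and j in adj:
            adj[i].add(j)
            adj[j].add(i)
    order = []
    seen = set()
    for start, _ in obs:
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        while queue:
            node = queue.pop(0)
            order.append(node)
            for nxt in sorted(adj[node]):
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
    atom_at = dict(obs)

    solutions = []

    def extend(pos, assigned):
        if pos == len(order):
            solutions.append(dict(assigned))
            return
        idx = order[pos]
        atom = atom_at[idx]
        for cand in dict_heavy:
            if cand.element != atom.element or cand.atom_id in assigned.values():
                continue
            ok = True
            for prev_idx, prev_id in assigned.items():
                if frozenset((idx, prev_idx)) in obs_bonds and (
                    frozenset((cand.atom_id, prev_id)) not in dict_bonds
                ):
                    ok = False
                    break
            if ok:
                assigned[idx] = cand.atom_id
                extend(pos + 1, assigned)
                del assigned[idx]

    extend(0, {})
    full = []
    for sol in solutions:
        missing = {a.atom_id for a in dict_heavy} - set(sol.values())
        if all(cdef.atom(m).leaving for m in missing):
            full.append(sol)
    return full
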