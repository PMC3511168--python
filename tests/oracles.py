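"""Independent brute-force oracles used by the unit and acceptance
tests.  Deliberately naive: full enumeration, no seeding shortcuts."""

from __future__ import annotations

from snoleca.guides import GuideSearchParams


def _greedy_dedup(wins):
    kept = []
    for w in sorted(wins, key=lambda t: (-t[3], t[0], -(t[1] - t[0]), t[2])):
        if all(w[1] <= k[0] or k[1] <= w[0] for k in kept):
            kept.append(w)
    kept.sort(key=lambda t: t[0])
    return kept


def brute_force_guide_windows(query: str, rrna: str, p: GuideSearchParams):
    """All ungapped antisense windows (every diagonal, every start,
    length ≥ min) that pass the length/identity thresholds, begin and
    end on a match, and contain an exact word seed — deduplicated
    best-score-first exactly like the search contract."""
    n, m = len(query), len(rrna)
    wins = []
    for d in range(-(n - p.min_length), m - p.min_length + 1):
        qlo, qhi = max(0, -d), min(n, m - d)
        L = qhi - qlo
        if L < p.min_length:
            continue
        match = [query[qlo + i] == rrna[qlo + d + i] for i in range(L)]
        for s in range(L):
            for e in range(s + p.min_length, L + 1):
                if not (match[s] and match[e - 1]):
                    continue
                mt = sum(match[s:e])
                if mt / (e - s) + 1e-12 < p.min_identity:
                    continue
                run = best = 0
                for v in match[s:e]:
                    run = run + 1 if v else 0
                    best = max(best, run)
                if best < p.word_size:
                    continue
                score = mt * p.match_score + (e - s - mt) * p.mismatch_score
                wins.append((qlo + s + d, qlo + e + d, qlo + s, score, mt))
    return _greedy_dedup(wins)


def transitive_closure_components(values: list[int], tolerance: int) -> list[frozenset[int]]:
    """Connected components of the |Δ| ≤ tolerance relation, by direct
    pairwise adjacency and breadth-first search."""
    n = len(values)
    adj = [[j for j in range(n) if j != i and abs(values[i] - values[j]) <= tolerance] for i in range(n)]
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k])
        seen |= comp
        comps.append(frozenset(comp))
    return comps
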